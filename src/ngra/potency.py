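"""Tier 2: relative potencies and the common-mode-of-action decision.

Within each tissue or gene category the chemicals' indicator values (mean
AC50, ADI or NOAEL — all "smaller is more toxic") are normalised to the most
potent chemical:

    rp(chemical) = min(values) / value(chemical)          in (0, 1]

so the most potent chemical scores exactly 1 and ties at the minimum share
it.  Chemicals with no value in a category are carried as zero potency for
charting, but stay blank in reported tables.  Comparing two relative-potency
tables (e.g. bioactivity vs NOAEL) over their shared (category, chemical)
pairs gives a correlation and a fraction-within-fold statistic from which
the common-mode-of-action hypothesis is accepted or rejected.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Iterable, Literal, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .bioactivity import BioactivityIndicator

ReferenceKind = Literal["ADI", "NOAEL"]


@dataclass(frozen=True)
class ReferenceValue:
    """A regulatory reference dose (mg/kg bw/d) for one chemical and endpoint."""

    chemical_id: str
    kind: ReferenceKind
    endpoint: str
    value: float | None = None

    def __post_init__(self) -> None:
        if self.value is not None and not self.value > 0:
            raise ValueError("reference value must be positive when present")


def round_half_up(x: float, decimals: int = 2) -> float:
    """Round half away from zero (reported tables use this, internal math never)."""
    factor = 10.0**decimals
    return math.copysign(math.floor(abs(x) * factor + 0.5) / factor, x)


@dataclass
class RelativePotencyTable:
    """Per-category mapping chemical → relative potency in (0, 1].

    ``entries`` holds only chemicals with a present value; ``dense`` fills
    the zero-potency chemicals in explicitly.
    """

    category_kind: str
    entries: dict[str, dict[str, float]]

    @property
    def categories(self) -> list[str]:
        return list(self.entries)

    @property
    def chemicals(self) -> list[str]:
        seen: dict[str, None] = {}
        for mapping in self.entries.values():
            for chem in mapping:
                seen.setdefault(chem)
        return list(seen)

    def dense(self, chemicals: Sequence[str] | None = None) -> "RelativePotencyTable":
        chems = list(chemicals) if chemicals is not None else self.chemicals
        return RelativePotencyTable(
            category_kind=self.category_kind,
            entries={
                cat: {c: mapping.get(c, 0.0) for c in chems}
                for cat, mapping in self.entries.items()
            },
        )

    def rounded(self, decimals: int = 2) -> "RelativePotencyTable":
        return RelativePotencyTable(
            category_kind=self.category_kind,
            entries={
                cat: {c: round_half_up(v, decimals) for c, v in mapping.items()}
                for cat, mapping in self.entries.items()
            },
        )

    def to_frame(self) -> pd.DataFrame:
        frame = pd.DataFrame.from_dict(self.entries, orient="index")
        frame.index.name = "category"
        return frame.reindex(columns=self.chemicals)


def relative_potency(values: Mapping[str, float | None]) -> dict[str, float]:
    """Eq.-style normalisation: most potent (minimum) value over each value.

    Absent (None) entries receive relative potency 0; ties at the minimum
    all receive exactly 1.0.
    """
    present = {c: float(v) for c, v in values.items() if v is not None}
    if not present:
        raise ValueError("relative_potency needs at least one present value")
    if any(not v > 0 for v in present.values()):
        raise ValueError("values must be positive")
    best = min(present.values())
    out: dict[str, float] = {}
    for chem, value in values.items():
        out[chem] = best / present[chem] if chem in present else 0.0
    return out


def potency_table(
    inputs: Iterable[BioactivityIndicator] | Iterable[ReferenceValue],
    kind: str | None = None,
) -> RelativePotencyTable:
    """Group indicator or reference values by category and normalise each group.

    For :class:`BioactivityIndicator` inputs the category is the tissue/gene
    label; for :class:`ReferenceValue` inputs it is the endpoint and the
    resulting table has ``category_kind="reference"``.
    """
    items = list(inputs)
    if not items:
        return RelativePotencyTable(category_kind=kind or "empty", entries={})
    grouped: dict[str, dict[str, float]] = {}
    if isinstance(items[0], BioactivityIndicator):
        inferred = items[0].category_kind
        for ind in items:
            grouped.setdefault(ind.category, {})[ind.chemical_id] = ind.mean_ac50
    else:
        inferred = "reference"
        for ref in items:
            if ref.value is None:
                continue
            grouped.setdefault(ref.endpoint, {})[ref.chemical_id] = ref.value
    entries = {
        cat: relative_potency(values) for cat, values in grouped.items() if values
    }
    return RelativePotencyTable(category_kind=kind or inferred, entries=entries)


@dataclass(frozen=True)
class ConcordanceThresholds:
    """Operational thresholds for the mode-of-action decision.

    Both statistics must pass for ``common_moa``; the defaults make the
    traditionally visual equipotency-scatter judgement explicit.
    """

    min_correlation: float = 0.8
    fold: float = 3.0
    min_fraction_within_fold: float = 0.8
    correlation_method: Literal["pearson", "spearman"] = "pearson"


@dataclass
class ConcordanceReport:
    paired_points: list[tuple[str, str, float, float]]
    correlation: float
    fraction_within_fold: float
    decision: Literal["common_moa", "reject_common_moa"]
    thresholds: ConcordanceThresholds = field(default_factory=ConcordanceThresholds)

    def to_dict(self) -> dict:
        return {
            "n_pairs": len(self.paired_points),
            "correlation": self.correlation,
            "fraction_within_fold": self.fraction_within_fold,
            "fold": self.thresholds.fold,
            "correlation_method": self.thresholds.correlation_method,
            "decision": self.decision,
            "paired_points": [
                {"category": c, "chemical": ch, "rp_a": a, "rp_b": b}
                for c, ch, a, b in self.paired_points
            ],
        }


def equipotency_assessment(
    rp_a: RelativePotencyTable,
    rp_b: RelativePotencyTable,
    thresholds: ConcordanceThresholds | None = None,
    category_map: Mapping[str, str] | None = None,
) -> ConcordanceReport:
    """Pair two relative-potency tables and decide the common-MoA question.

    ``category_map`` maps categories of ``rp_a`` onto categories of ``rp_b``
    (e.g. tissue "Brain" onto endpoint "brain_neuro_repeated"); identity by
    default.  Only pairs with both relative potencies present (i.e. derived
    from an actual value, not the zero-potency fill) enter the statistics.
    """
    thresholds = thresholds or ConcordanceThresholds()
    pairs: list[tuple[str, str, float, float]] = []
    for cat_a, mapping_a in rp_a.entries.items():
        cat_b = category_map.get(cat_a, cat_a) if category_map else cat_a
        mapping_b = rp_b.entries.get(cat_b)
        if mapping_b is None:
            continue
        for chem, a in mapping_a.items():
            b = mapping_b.get(chem)
            if b is None or a == 0.0 or b == 0.0:
                continue
            pairs.append((cat_a, chem, a, b))
    if len(pairs) < 3:
        raise ValueError(
            f"insufficient overlap: {len(pairs)} shared (category, chemical) pairs"
        )
    a = np.array([p[2] for p in pairs])
    b = np.array([p[3] for p in pairs])
    if np.allclose(a, a[0]) and np.allclose(b, b[0]):
        corr = 1.0 if np.allclose(a, b) else 0.0  # degenerate constant tables
    elif thresholds.correlation_method == "pearson":
        corr = float(stats.pearsonr(a, b).statistic)
    else:
        corr = float(stats.spearmanr(a, b).statistic)
    ratio = a / b
    fold = thresholds.fold
    frac = float(np.mean((ratio >= 1.0 / fold) & (ratio <= fold)))
    decision = (
        "common_moa"
        if corr >= thresholds.min_correlation
        and frac >= thresholds.min_fraction_within_fold
        else "reject_common_moa"
    )
    return ConcordanceReport(
        paired_points=pairs,
        correlation=corr,
        fraction_within_fold=frac,
        decision=decision,
        thresholds=thresholds,
    )


def radial_coordinates(
    table: RelativePotencyTable, chemicals: Sequence[str] | None = None
) -> pd.DataFrame:
    """Chart-ready spoke coordinates: one spoke per category, radius = rp.

    Zero-potency (absent) chemicals are plotted at radius 0.
    """
    if not table.entries:
        raise ValueError("empty relative-potency table")
    dense = table.dense(chemicals)
    categories = dense.categories
    n = len(categories)
    rows = []
    for i, cat in enumerate(categories):
        angle = 360.0 * i / n
        for chem, radius in dense.entries[cat].items():
            rows.append(
                {"category": cat, "chemical_id": chem, "angle_deg": angle, "radius": radius}
            )
    return pd.DataFrame(rows)
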