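"""Seeded synthetic data: assay tables with known ground truth and
plausible chemical parameter sets.

The assay generator emulates a high-throughput bioactivity export: for
every (chemical, category) with a true mean AC50 it draws
``assays_per_category`` records with multiplicative log-normal scatter
(mean-preserving, so arithmetic averaging is unbiased) and marks a fixed
fraction inactive.  The chemical generator samples parameter sets uniformly
(log-uniformly for solubility, permeability and dose) inside the spans of
the packaged six-pyrethroid parameter table.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Mapping

import numpy as np

from .bioactivity import AssayRecord, CategoryKind
from .pbpk import ChemicalParameters


@dataclass
class TruthSpec:
    """Ground truth for a synthetic assay table.

    ``true_means`` maps (chemical, category) → mean AC50 in µM, or None for
    an inactive pair.  ``lognormal_sd`` is the standard deviation of the
    natural-log AC50 scatter; 0 reproduces the true means exactly.
    """

    chemicals: tuple[str, ...]
    categories: tuple[str, ...]
    true_means: dict[tuple[str, str], float | None]
    category_kind: CategoryKind = "tissue"
    assays_per_category: int = 10
    lognormal_sd: float = 0.5
    inactive_rate: float = 0.1
    seed: int = 0

    def __post_init__(self) -> None:
        if self.assays_per_category < 1:
            raise ValueError("assays_per_category must be >= 1")
        if not 0.0 <= self.inactive_rate <= 1.0:
            raise ValueError("inactive_rate must lie in [0, 1]")
        if self.lognormal_sd < 0:
            raise ValueError("lognormal_sd must be non-negative")
        for key, value in self.true_means.items():
            if value is not None and not value > 0:
                raise ValueError(f"true mean for {key} must be positive")

    @property
    def active_pairs(self) -> list[tuple[str, str]]:
        return [
            (c, cat)
            for c in self.chemicals
            for cat in self.categories
            if self.true_means.get((c, cat)) is not None
        ]

    def expected_record_count(self) -> int:
        """Manifest count: records the generator will emit."""
        return len(self.active_pairs) * self.assays_per_category


def generate_assay_table(spec: TruthSpec) -> list[AssayRecord]:
    """Deterministic (seeded) synthetic assay table matching ``spec``.

    AC50s are drawn as ``mean · exp(σZ − σ²/2)`` so their expectation is
    the true mean; a fraction ``inactive_rate`` of records is inactive
    (no AC50).
    """
    rng = np.random.default_rng(spec.seed)
    sd = spec.lognormal_sd
    records: list[AssayRecord] = []
    for chem, cat in spec.active_pairs:
        mean = spec.true_means[(chem, cat)]
        for j in range(spec.assays_per_category):
            assay_id = f"{chem}_{cat}_{j:03d}".replace(" ", "_")
            inactive = rng.random() < spec.inactive_rate
            labels = {
                "tissue_category" if spec.category_kind == "tissue" else "gene_category": cat
            }
            if inactive:
                records.append(
                    AssayRecord(chemical_id=chem, assay_id=assay_id, active=False, **labels)
                )
                continue
            ac50 = mean * math.exp(sd * rng.standard_normal() - sd * sd / 2.0)
            records.append(
                AssayRecord(
                    chemical_id=chem, assay_id=assay_id, active=True, ac50=ac50, **labels
                )
            )
    return records


def truth_spec_from_means(
    means: Mapping[str, Mapping[str, float | None]],
    category_kind: CategoryKind = "tissue",
    **kwargs,
) -> TruthSpec:
    """Build a TruthSpec from a category → chemical → mean mapping (NaN/None
    = inactive), e.g. straight from a packaged indicator table."""
    categories = tuple(means)
    chemicals: tuple[str, ...] = tuple(
        dict.fromkeys(c for row in means.values() for c in row)
    )
    true_means: dict[tuple[str, str], float | None] = {}
    for cat, row in means.items():
        for chem, value in row.items():
            ok = value is not None and not (isinstance(value, float) and math.isnan(value))
            true_means[(chem, cat)] = float(value) if ok else None
    return TruthSpec(
        chemicals=chemicals,
        categories=categories,
        true_means=true_means,
        category_kind=category_kind,
        **kwargs,
    )


#: sampling spans for synthetic chemicals: (low, high, log-uniform?)
DEFAULT_CHEMICAL_RANGES: dict[str, tuple[float, float, bool]] = {
    "molecular_weight": (391.3, 505.2, False),
    "water_solubility": (1.3e-6, 5e-3, True),
    "fraction_unbound": (0.10, 0.10, False),
    "log_p": (5.5, 6.24, False),
    "pka": (-7.1, 10.65, False),
    "intestinal_permeability": (1.04e-4, 4.4e-4, True),
    "km": (0.62, 41.34, False),
    "kcat": (9.1, 160.0, False),
    "oral_dose": (1.12e-4, 1.14e-3, True),
}


def generate_chemical(
    ranges: Mapping[str, tuple[float, float, bool]] | None = None,
    seed: int = 0,
    chemical_id: str | None = None,
) -> ChemicalParameters:
    """One synthetic parameter set, uniform (or log-uniform) within ranges.

    Degenerate ranges (low == high) pin the field exactly; deterministic
    under a fixed seed.
    """
    spans = dict(DEFAULT_CHEMICAL_RANGES)
    if ranges:
        spans.update(ranges)
    rng = np.random.default_rng(seed)
    values: dict[str, float] = {}
    for name, (low, high, log_scale) in spans.items():
        if high < low:
            raise ValueError(f"range for {name} is inverted")
        if low == high:
            values[name] = low
        elif log_scale:
            values[name] = float(np.exp(rng.uniform(np.log(low), np.log(high))))
        else:
            values[name] = float(rng.uniform(low, high))
    return ChemicalParameters(
        chemical_id=chemical_id or f"synthetic_{seed}", **values
    )
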