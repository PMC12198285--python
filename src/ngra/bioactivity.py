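"""Tier 1: ingestion of assay-level bioactivity tables and aggregation into
tissue- and gene-category bioactivity indicators.

An *indicator* is the average AC50 (µM) of all active, quality-controlled
assays a chemical has in one tissue or gene category.  It serves as the
in-vitro point of departure for the later risk tiers.  (Chemical, category)
pairs without any qualifying assay produce no indicator at all — a blank
cell, never a zero.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field
from typing import Iterable, Literal, Mapping, Sequence

import pandas as pd

log = logging.getLogger(__name__)

QUALITY_FLAGS = ("ok", "insufficient", "inconsistent")

CategoryKind = Literal["tissue", "gene"]

#: default column names expected in an assay table
DEFAULT_COLUMNS = {
    "chemical_id": "chemical_id",
    "assay_id": "assay_id",
    "ac50": "ac50",
    "tissue_category": "tissue_category",
    "gene_category": "gene_category",
    "active": "active",
    "quality_flag": "quality_flag",
}

MANDATORY = ("chemical_id", "assay_id", "active")


class AssayTableError(ValueError):
    """Raised when an assay table cannot be parsed at all."""


@dataclass(frozen=True)
class AssayRecord:
    """One in-vitro assay result for one chemical.

    ``ac50`` is in µM and must be present and positive for active records;
    inactive records carry ``ac50=None``.  At least one of the category
    labels must be present for the record to be aggregatable.
    """

    chemical_id: str
    assay_id: str
    active: bool
    ac50: float | None = None
    tissue_category: str | None = None
    gene_category: str | None = None
    quality_flag: str = "ok"

    def __post_init__(self) -> None:
        if self.quality_flag not in QUALITY_FLAGS:
            raise ValueError(f"unknown quality_flag {self.quality_flag!r}")
        if self.active and (self.ac50 is None or not self.ac50 > 0):
            raise ValueError(
                f"active record {self.chemical_id}/{self.assay_id} needs ac50 > 0"
            )

    def category(self, kind: CategoryKind) -> str | None:
        return self.tissue_category if kind == "tissue" else self.gene_category


@dataclass(frozen=True)
class BioactivityIndicator:
    """Per (chemical, category) mean AC50 — the Tier-1 bioactivity indicator."""

    chemical_id: str
    category_kind: CategoryKind
    category: str
    mean_ac50: float
    n_assays: int = 1

    def __post_init__(self) -> None:
        if self.n_assays < 1:
            raise ValueError("n_assays must be >= 1")
        if not self.mean_ac50 > 0:
            raise ValueError("mean_ac50 must be positive")


@dataclass
class TableLoadResult:
    """Parsed assay records plus a row-indexed report of rejected rows."""

    records: list[AssayRecord]
    rejected: list[tuple[int, str]] = field(default_factory=list)

    def __iter__(self):
        return iter(self.records)

    def __len__(self) -> int:
        return len(self.records)


def _clean(value) -> str | None:
    if value is None or (isinstance(value, float) and math.isnan(value)):
        return None
    s = str(value).strip()
    return s or None


def _parse_bool(value) -> bool:
    if isinstance(value, bool):
        return value
    s = str(value).strip().lower()
    if s in ("true", "1", "yes", "active"):
        return True
    if s in ("false", "0", "no", "inactive"):
        return False
    raise ValueError(f"cannot interpret {value!r} as a boolean activity flag")


def load_assay_table(
    source,
    column_map: Mapping[str, str] | None = None,
    *,
    sep: str | None = None,
) -> TableLoadResult:
    """Read a delimited assay table into :class:`AssayRecord` objects.

    ``column_map`` maps the canonical field names (keys of
    :data:`DEFAULT_COLUMNS`) to the column names used in the file.  Rows
    missing a mandatory field, or claiming activity without an AC50, are
    rejected individually and reported with their row index.
    """
    columns = dict(DEFAULT_COLUMNS)
    if column_map:
        columns.update(column_map)
    try:
        frame = pd.read_csv(source, sep=sep, engine="python")
    except Exception as exc:  # malformed file, not malformed rows
        raise AssayTableError(f"could not parse assay table: {exc}") from exc

    missing_mandatory = [columns[k] for k in MANDATORY if columns[k] not in frame.columns]
    if missing_mandatory:
        raise AssayTableError(f"assay table lacks mandatory columns {missing_mandatory}")

    records: list[AssayRecord] = []
    rejected: list[tuple[int, str]] = []
    for idx, row in frame.iterrows():
        try:
            ac50 = row.get(columns["ac50"])
            ac50 = None if ac50 is None or pd.isna(ac50) else float(ac50)
            quality = _clean(row.get(columns["quality_flag"])) or "ok"
            rec = AssayRecord(
                chemical_id=_req(row, columns["chemical_id"], "chemical_id"),
                assay_id=_req(row, columns["assay_id"], "assay_id"),
                active=_parse_bool(row[columns["active"]]),
                ac50=ac50,
                tissue_category=_clean(row.get(columns["tissue_category"])),
                gene_category=_clean(row.get(columns["gene_category"])),
                quality_flag=quality,
            )
        except (ValueError, KeyError) as exc:
            rejected.append((int(idx), str(exc)))
            continue
        records.append(rec)
    if rejected:
        log.warning("rejected %d assay rows: %s", len(rejected), rejected[:5])
    return TableLoadResult(records=records, rejected=rejected)


def _req(row, col: str, name: str) -> str:
    value = _clean(row.get(col))
    if value is None:
        raise ValueError(f"missing mandatory field {name!r}")
    return value


def aggregate_indicators(
    records: Iterable[AssayRecord],
    category_kind: CategoryKind = "tissue",
    *,
    mean: Literal["arithmetic", "geometric"] = "arithmetic",
) -> list[BioactivityIndicator]:
    """Average AC50s per (chemical, category) over active, quality-ok records.

    Inactive records and records flagged ``insufficient``/``inconsistent``
    are excluded; groups with no qualifying record yield no indicator.
    Duplicated (chemical, assay) pairs are kept and averaged.
    """
    records = list(records)
    if not records:
        log.warning("aggregate_indicators called with no records")
        return []
    groups: dict[tuple[str, str], list[float]] = {}
    for rec in records:
        cat = rec.category(category_kind)
        if cat is None or not rec.active or rec.quality_flag != "ok":
            continue
        groups.setdefault((rec.chemical_id, cat), []).append(float(rec.ac50))
    indicators = []
    for (chem, cat), values in sorted(groups.items()):
        if mean == "arithmetic":
            m = sum(values) / len(values)
        elif mean == "geometric":
            m = math.exp(sum(math.log(v) for v in values) / len(values))
        else:
            raise ValueError(f"unknown mean type {mean!r}")
        indicators.append(
            BioactivityIndicator(
                chemical_id=chem,
                category_kind=category_kind,
                category=cat,
                mean_ac50=m,
                n_assays=len(values),
            )
        )
    return indicators


def indicators_to_frame(indicators: Sequence[BioactivityIndicator]) -> pd.DataFrame:
    """Wide chemical × category table of mean AC50s; blanks stay NaN."""
    if not indicators:
        return pd.DataFrame()
    tidy = pd.DataFrame(
        {
            "category": [i.category for i in indicators],
            "chemical_id": [i.chemical_id for i in indicators],
            "mean_ac50": [i.mean_ac50 for i in indicators],
        }
    )
    return tidy.pivot(index="category", columns="chemical_id", values="mean_ac50")


def frame_to_indicators(
    frame: pd.DataFrame, category_kind: CategoryKind
) -> list[BioactivityIndicator]:
    """Inverse of :func:`indicators_to_frame` for category × chemical tables
    (n_assays is not recoverable from a mean table and defaults to 1)."""
    out = []
    for category, row in frame.iterrows():
        for chem, value in row.items():
            if pd.isna(value):
                continue
            out.append(
                BioactivityIndicator(
                    chemical_id=str(chem),
                    category_kind=category_kind,
                    category=str(category),
                    mean_ac50=float(value),
                )
            )
    return out
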