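"""In-vitro disposition mass balance (Tier-4 refinement) and IVIVE bands.

A nominal assay concentration C_nom applies to the whole well, but the
chemical equilibrates between the aqueous medium, serum protein, medium
lipid, and the cells' water, protein and membrane-lipid phases.  The model
is a linear equilibrium mass balance: each sorptive phase holds
``K_phase × C_free`` per unit phase volume, with protein phases governed by
the albumin–water distribution ratio ``10^log_d_bsa_w`` and lipid phases by
the lipid–water ratio ``10^log_d_lip_w`` (both at pH 7.4, 37 °C).  Outputs
are the freely dissolved (C_free), cell-associated (C_cell) and
membrane-bound (C_mem) concentrations and exact per-phase mass fractions.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from .bioactivity import BioactivityIndicator

log = logging.getLogger(__name__)

PROTEIN_DENSITY = 1360.0  # g/L, serum albumin phase density
LIPID_DENSITY = 1000.0  # g/L


@dataclass(frozen=True)
class InVitroSystem:
    """Geometry and composition of one in-vitro assay well.

    Defaults approximate a reporter-gene bioassay well: 40 µL medium with
    10 % serum, ~23 g/L albumin in the serum, trace medium lipid, and 5000
    cells of 2 pL each.
    """

    medium_volume: float = 40e-6  # L
    serum_volume_fraction: float = 0.10
    serum_albumin_conc: float = 23.0  # g/L of serum
    medium_lipid_conc: float = 0.025  # g/L of whole medium
    cell_count: float = 5000
    cell_volume: float = 2e-12  # L per cell
    cell_lipid_fraction: float = 0.05
    cell_protein_fraction: float = 0.20
    temperature: float = 37.0  # °C
    ph: float = 7.4

    def __post_init__(self) -> None:
        for name in ("medium_volume", "serum_albumin_conc", "medium_lipid_conc",
                     "cell_count", "cell_volume"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be non-negative")
        for name in ("serum_volume_fraction", "cell_lipid_fraction",
                     "cell_protein_fraction"):
            if not 0.0 <= getattr(self, name) <= 1.0:
                raise ValueError(f"{name} must lie in [0, 1]")
        if self.cell_lipid_fraction + self.cell_protein_fraction > 1.0:
            raise ValueError("cell lipid + protein fractions exceed 1")

    # phase volumes (L)
    @property
    def v_serum_protein(self) -> float:
        mass = self.medium_volume * self.serum_volume_fraction * self.serum_albumin_conc
        return mass / PROTEIN_DENSITY

    @property
    def v_medium_lipid(self) -> float:
        return self.medium_lipid_conc * self.medium_volume / LIPID_DENSITY

    @property
    def v_cells(self) -> float:
        return self.cell_count * self.cell_volume

    @property
    def v_cell_lipid(self) -> float:
        return self.v_cells * self.cell_lipid_fraction

    @property
    def v_cell_protein(self) -> float:
        return self.v_cells * self.cell_protein_fraction

    @property
    def v_cell_water(self) -> float:
        return self.v_cells * (1.0 - self.cell_lipid_fraction - self.cell_protein_fraction)

    @property
    def v_aqueous_medium(self) -> float:
        return self.medium_volume - self.v_serum_protein - self.v_medium_lipid

    @property
    def v_total(self) -> float:
        return self.medium_volume + self.v_cells


@dataclass(frozen=True)
class PartitionSet:
    """Albumin–water and lipid–water distribution ratios (log10 L/L) for one
    chemical at pH 7.4 and 37 °C."""

    chemical_id: str
    log_d_bsa_w: float
    log_d_lip_w: float
    source: str = "lser"  # "lser" (direct prediction) or "extrapolated"

    def __post_init__(self) -> None:
        if not (np.isfinite(self.log_d_bsa_w) and np.isfinite(self.log_d_lip_w)):
            raise ValueError("partition coefficients must be finite")


@dataclass(frozen=True)
class PartitionCalibration:
    """log_p → log D regression lines: log_d = slope · log_p + intercept.

    Defaults are the single-parameter hydrophobicity regressions commonly
    used for neutral organics — liposome–water log K ≈ 1.01·logP + 0.12 and
    BSA–water log K ≈ 0.71·logP + 0.42.
    """

    lip_slope: float = 1.01
    lip_intercept: float = 0.12
    bsa_slope: float = 0.71
    bsa_intercept: float = 0.42


def fit_partition_calibration(
    reference: Iterable[PartitionSet], log_p: Mapping[str, float]
) -> PartitionCalibration:
    """Least-squares calibration from chemicals with direct (LSER) values."""
    refs = [r for r in reference if r.chemical_id in log_p]
    if len(refs) < 2:
        raise ValueError("need at least two reference chemicals with log P to calibrate")
    x = np.array([log_p[r.chemical_id] for r in refs])
    lip = np.polyfit(x, [r.log_d_lip_w for r in refs], 1)
    bsa = np.polyfit(x, [r.log_d_bsa_w for r in refs], 1)
    return PartitionCalibration(
        lip_slope=float(lip[0]),
        lip_intercept=float(lip[1]),
        bsa_slope=float(bsa[0]),
        bsa_intercept=float(bsa[1]),
    )


def extrapolate_partition_set(
    chemical_id: str,
    log_p: float,
    calibration: PartitionCalibration | None = None,
) -> PartitionSet:
    """Partition set extrapolated from logP via the calibration lines."""
    cal = calibration or PartitionCalibration()
    return PartitionSet(
        chemical_id=chemical_id,
        log_d_lip_w=cal.lip_slope * log_p + cal.lip_intercept,
        log_d_bsa_w=cal.bsa_slope * log_p + cal.bsa_intercept,
        source="extrapolated",
    )


@dataclass
class DispositionResult:
    """Equilibrium partition of a nominal concentration (all µmol/L)."""

    c_nom: float
    c_free: float
    c_cell: float
    c_mem: float
    mass_fractions: dict[str, float]

    def __post_init__(self) -> None:
        total = sum(self.mass_fractions.values())
        if abs(total - 1.0) > 1e-9:
            raise ValueError(f"mass fractions sum to {total}, not 1")


def partition_nominal(
    c_nom: float, system: InVitroSystem, parts: PartitionSet
) -> DispositionResult:
    """Distribute ``c_nom × V_total`` over the well's phases at equilibrium.

    Linear in ``c_nom`` by construction (concentration-independent ratios).
    """
    if system.v_total <= 0:
        raise ValueError("system has zero total volume")
    if c_nom < 0:
        raise ValueError("c_nom must be non-negative")
    k_bsa = 10.0**parts.log_d_bsa_w
    k_lip = 10.0**parts.log_d_lip_w
    volumes = {
        "aqueous_medium": system.v_aqueous_medium,
        "serum_protein": system.v_serum_protein,
        "medium_lipid": system.v_medium_lipid,
        "cell_water": system.v_cell_water,
        "cell_protein": system.v_cell_protein,
        "cell_membrane_lipid": system.v_cell_lipid,
    }
    affinity = {
        "aqueous_medium": 1.0,
        "serum_protein": k_bsa,
        "medium_lipid": k_lip,
        "cell_water": 1.0,
        "cell_protein": k_bsa,
        "cell_membrane_lipid": k_lip,
    }
    capacity = {p: volumes[p] * affinity[p] for p in volumes}
    denom = sum(capacity.values())
    total_amount = c_nom * system.v_total
    c_free = total_amount / denom if denom > 0 else 0.0
    amounts = {p: c_free * cap for p, cap in capacity.items()}
    if total_amount > 0:
        fractions = {p: a / total_amount for p, a in amounts.items()}
        # exact renormalisation against accumulated FP error
        s = sum(fractions.values())
        fractions = {p: f / s for p, f in fractions.items()}
    else:
        fractions = {p: (1.0 if p == "aqueous_medium" else 0.0) for p in amounts}
    cell_amount = amounts["cell_water"] + amounts["cell_protein"] + amounts["cell_membrane_lipid"]
    c_cell = cell_amount / system.v_cells if system.v_cells > 0 else 0.0
    c_mem = k_lip * c_free
    return DispositionResult(
        c_nom=c_nom,
        c_free=c_free,
        c_cell=c_cell,
        c_mem=c_mem,
        mass_fractions=fractions,
    )


def refine_indicators(
    indicators: Iterable[BioactivityIndicator],
    system: InVitroSystem,
    parts: Mapping[str, PartitionSet],
) -> pd.DataFrame:
    """Refined indicator table: nominal AC50 → free/cell/membrane levels.

    One row per (chemical, tissue); chemicals without a partition set are
    skipped with a log entry.
    """
    rows = []
    for ind in indicators:
        ps = parts.get(ind.chemical_id)
        if ps is None:
            log.warning("no partition set for %s; skipped", ind.chemical_id)
            continue
        res = partition_nominal(ind.mean_ac50, system, ps)
        rows.append(
            {
                "chemical_id": ind.chemical_id,
                "tissue": ind.category,
                "c_nom": ind.mean_ac50,
                "c_free": res.c_free,
                "c_cell": res.c_cell,
                "c_mem": res.c_mem,
            }
        )
    return pd.DataFrame(rows)


@dataclass
class IviveClassification:
    """Fold-band classification of paired in-vitro vs in-vivo concentrations."""

    records: pd.DataFrame  # chemical_id, tissue, in_vitro, in_vivo, ratio, band
    excluded: list[tuple[str, str, str]]

    def band_counts(self) -> pd.DataFrame:
        return (
            self.records.groupby(["chemical_id", "band"], sort=True)
            .size()
            .rename("n")
            .reset_index()
        )


def ivive_comparison(
    in_vitro: Mapping[tuple[str, str], float],
    in_vivo: Mapping[tuple[str, str], float],
    folds: Sequence[float] = (10.0, 100.0),
) -> IviveClassification:
    """Label each shared (chemical, tissue) pair by the smallest fold band
    containing the in-vitro / in-vivo ratio.

    Bands are nested: a pair within 10× is by construction within 100×; the
    reported label is the tightest band.  Non-positive values exclude the
    pair with a log entry.
    """
    folds = sorted(folds)
    rows = []
    excluded: list[tuple[str, str, str]] = []
    for key in sorted(set(in_vitro) & set(in_vivo)):
        a, b = in_vitro[key], in_vivo[key]
        if not (a > 0 and b > 0):
            excluded.append((key[0], key[1], "non-positive value"))
            log.warning("IVIVE pair %s excluded: non-positive value", key)
            continue
        ratio = a / b
        band = "beyond"
        for f in folds:
            if 1.0 / f <= ratio <= f:
                band = f"within {f:g}x"
                break
        rows.append(
            {
                "chemical_id": key[0],
                "tissue": key[1],
                "in_vitro": a,
                "in_vivo": b,
                "ratio": ratio,
                "band": band,
            }
        )
    return IviveClassification(records=pd.DataFrame(rows), excluded=excluded)
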