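"""Margins of exposure, concern bins, prioritization and mixture MOET
(Tiers 3 and 5).

MoE = point of departure / internal exposure (both µmol/L).  The screening
tier divides nominal tissue AC50s by the simulated Cmax in the matching
compartment; the refined tier divides free/cellular refined indicators by
interstitial/intracellular Cmax; the parallel in-vivo track divides
Cmax-at-NOAEL by Cmax-at-realistic-dose.  The mixture total,
MOET = 1 / Σ(1/MoE), is the reciprocal-sum combination, never larger than
the smallest contributing MoE.
"""

from __future__ import annotations

import logging
from bisect import bisect_right
from dataclasses import dataclass, field
from typing import Iterable, Literal, Mapping, Sequence

import pandas as pd

from .bioactivity import BioactivityIndicator
from .pbpk import ENDPOINT_ORGANS, NoaelSimulations, PKResult

log = logging.getLogger(__name__)

ABSENT_POD_NOTE = "Exposure range not calculated due to the lack of AC50 bioactivity values"
ABSENT_NOAEL_NOTE = "Exposure range not calculated due to the lack of NOAELs"

#: bioactivity tissue category → PBPK organ.  Categories with no simulated
#: organ (systemic in-vitro models) read the plasma Cmax for both
#: compartments, matching how peripheral concentrations stand in for
#: vascular/immune tissue in the case study.
DEFAULT_TISSUE_ORGANS: dict[str, str | None] = {
    "Brain": "brain",
    "Kidney": "kidney",
    "Liver": "liver",
    "Lung": "lung",
    "Skin": "skin",
    "Intestine": "gut",
    "Vascular system": None,
    "Immune system": None,
    "Breast": None,
    "Ovary": None,
    "Pancreas": None,
    "Prostate function": None,
}

#: tissue category → reference-dose endpoint for the in-vivo/in-vivo track
DEFAULT_TISSUE_ENDPOINTS: dict[str, str] = {
    "Brain": "brain_neuro_repeated",
    "Kidney": "kidney_long_term",
    "Liver": "liver_long_term",
    "Lung": "lung_long_term",
    "Skin": "skin_short_term",
}
DEFAULT_TISSUE_ENDPOINTS.update(
    {t: "peripheral_general" for t, o in DEFAULT_TISSUE_ORGANS.items() if o is None}
)
DEFAULT_TISSUE_ENDPOINTS["Intestine"] = "peripheral_general"


@dataclass(frozen=True)
class BinScheme:
    """Ordered concern bins over MoE values.

    ``boundaries`` are strictly increasing; values land in half-open
    intervals with a boundary value belonging to the upper (less
    concerning) bin.
    """

    name: str
    boundaries: tuple[float, ...]
    labels: tuple[str, ...]
    colors: tuple[str, ...]

    def __post_init__(self) -> None:
        if any(b <= 0 for b in self.boundaries):
            raise ValueError("boundaries must be positive")
        if list(self.boundaries) != sorted(set(self.boundaries)):
            raise ValueError("boundaries must be strictly increasing")
        if len(self.labels) != len(self.boundaries) + 1:
            raise ValueError("need exactly len(boundaries)+1 labels")
        if len(self.colors) != len(self.labels):
            raise ValueError("need one color per label")


TIER3_SCHEME = BinScheme(
    name="screening",
    boundaries=(100.0, 1000.0, 100000.0),
    labels=("<100 (higher concern)", "100-1000", "1000-100,000", ">100,000 (lowest concern)"),
    colors=("red", "orange", "yellow", "green"),
)

TIER5_SCHEME = BinScheme(
    name="refined",
    boundaries=(1.0, 10.0, 100.0),
    labels=("<1 (likely bioactivation)", "1-10", "10-100", ">100"),
    colors=("red", "orange", "yellow", "green"),
)


def bin_moe(moe: float, scheme: BinScheme) -> str:
    """Concern label for one MoE under a bin scheme."""
    if not moe > 0:
        raise ValueError("MoE must be positive")
    return scheme.labels[bisect_right(scheme.boundaries, moe)]


def bin_color(moe: float, scheme: BinScheme) -> str:
    return scheme.colors[bisect_right(scheme.boundaries, moe)]


def margin_of_exposure(pod: float | None, cmax: float) -> float | None:
    """pod / cmax; ``None`` pod propagates as an absent (flagged) result."""
    if pod is None:
        return None
    if not pod > 0:
        raise ValueError("point of departure must be positive")
    if not cmax > 0:
        raise ValueError("MoE undefined for non-positive exposure")
    return pod / cmax


def combined_moe(moes: Iterable[float]) -> float:
    """Mixture total margin of exposure, MOET = 1 / Σ(1/MoE)."""
    values = list(moes)
    if not values:
        raise ValueError("combined_moe needs at least one MoE")
    if any(not m > 0 for m in values):
        raise ValueError("all MoEs must be positive")
    return 1.0 / sum(1.0 / m for m in values)


Compartment = Literal["interstitial", "intracellular"]


@dataclass(frozen=True)
class MoEResult:
    chemical_id: str
    tissue: str
    compartment: Compartment
    pod_basis: str
    pod: float | None
    exposure_cmax: float | None
    moe: float | None
    bin: str | None
    color: str | None = None
    note: str | None = None

    @property
    def flagged_absent(self) -> bool:
        return self.moe is None


@dataclass
class CombinedMoE:
    tissue: str
    compartment: Compartment
    contributing: list[tuple[str, float]]
    moet: float

    def __post_init__(self) -> None:
        if self.contributing:
            smallest = min(m for _, m in self.contributing)
            if self.moet > smallest * (1 + 1e-12):
                raise ValueError("MOET cannot exceed the smallest contributing MoE")


def results_to_frame(results: Sequence[MoEResult]) -> pd.DataFrame:
    return pd.DataFrame(
        [
            {
                "chemical_id": r.chemical_id,
                "tissue": r.tissue,
                "compartment": r.compartment,
                "pod_basis": r.pod_basis,
                "pod": r.pod,
                "exposure_cmax": r.exposure_cmax,
                "moe": r.moe,
                "bin": r.bin,
                "color": r.color,
                "note": r.note,
            }
            for r in results
        ]
    )


def _compartment_cmax(
    pk: PKResult, tissue: str, compartment: Compartment, tissue_organs: Mapping[str, str | None]
) -> float:
    organ = tissue_organs.get(tissue)
    if organ is None:
        return pk.cmax("plasma")
    return pk.cmax(f"{organ}:{compartment}")


def screening_table(
    indicators: Iterable[BioactivityIndicator],
    pk_results: Mapping[str, PKResult],
    scheme: BinScheme = TIER3_SCHEME,
    tissue_organs: Mapping[str, str | None] | None = None,
) -> list[MoEResult]:
    """Tier-3 screening: nominal AC50 ÷ compartment Cmax per chemical ×
    tissue × compartment.  Missing AC50s yield flagged absent cells."""
    tissue_organs = dict(tissue_organs or DEFAULT_TISSUE_ORGANS)
    inds = {(i.chemical_id, i.category): i for i in indicators}
    tissues = sorted({t for (_, t) in inds})
    chemicals = [c for c in pk_results if any((c, t) in inds for t in tissues)]
    if not chemicals:
        raise ValueError("no overlap between indicators and PK results")
    results: list[MoEResult] = []
    for chem in chemicals:
        pk = pk_results[chem]
        for tissue in tissues:
            if tissue not in tissue_organs:
                log.warning("tissue %r has no organ mapping; using plasma", tissue)
                tissue_organs[tissue] = None
            ind = inds.get((chem, tissue))
            for compartment in ("interstitial", "intracellular"):
                cmax = _compartment_cmax(pk, tissue, compartment, tissue_organs)
                if ind is None:
                    results.append(
                        MoEResult(chem, tissue, compartment, "nominal_ac50",
                                  None, cmax, None, None, None, ABSENT_POD_NOTE)
                    )
                    continue
                moe = margin_of_exposure(ind.mean_ac50, cmax)
                results.append(
                    MoEResult(chem, tissue, compartment, "nominal_ac50",
                              ind.mean_ac50, cmax, moe,
                              bin_moe(moe, scheme), bin_color(moe, scheme))
                )
    return results


@dataclass(frozen=True)
class PrioritizedTarget:
    chemical_id: str
    tissue: str
    min_moe: float
    gene_indicators: tuple[BioactivityIndicator, ...] = ()


def prioritize(
    results: Iterable[MoEResult],
    threshold: float = 100.0,
    gene_indicators: Iterable[BioactivityIndicator] | None = None,
) -> list[PrioritizedTarget]:
    """(chemical, tissue) pairs with any MoE below threshold, ascending by
    MoE, each carrying the chemical's gene-category indicators to support
    the mechanistic drill-down."""
    results = list(results)
    if not results:
        raise ValueError("no MoE results to prioritize")
    genes: dict[str, list[BioactivityIndicator]] = {}
    for g in gene_indicators or ():
        genes.setdefault(g.chemical_id, []).append(g)
    worst: dict[tuple[str, str], float] = {}
    for r in results:
        if r.moe is not None and r.moe < threshold:
            key = (r.chemical_id, r.tissue)
            worst[key] = min(worst.get(key, float("inf")), r.moe)
    ordered = sorted(worst.items(), key=lambda kv: kv[1])
    return [
        PrioritizedTarget(chem, tissue, moe, tuple(genes.get(chem, ())))
        for (chem, tissue), moe in ordered
    ]


def _combined_by_group(results: Sequence[MoEResult]) -> list[CombinedMoE]:
    groups: dict[tuple[str, str], list[tuple[str, float]]] = {}
    for r in results:
        if r.moe is None:
            continue
        groups.setdefault((r.tissue, r.compartment), []).append((r.chemical_id, r.moe))
    return [
        CombinedMoE(tissue=t, compartment=c, contributing=members,
                    moet=combined_moe(m for _, m in members))
        for (t, c), members in sorted(groups.items())
    ]


def refined_risk_table(
    refined_indicators: pd.DataFrame | None,
    pk_results: Mapping[str, PKResult],
    scheme: BinScheme = TIER5_SCHEME,
    track: Literal["nam", "in_vivo"] = "nam",
    noael_results: Mapping[str, NoaelSimulations] | None = None,
    tissue_organs: Mapping[str, str | None] | None = None,
    tissue_endpoints: Mapping[str, str] | None = None,
    tissues: Sequence[str] | None = None,
) -> tuple[list[MoEResult], list[CombinedMoE]]:
    """Tier-5 risk characterization.

    ``track="nam"`` pairs refined free concentrations with interstitial
    Cmax and refined cellular concentrations with intracellular Cmax;
    ``track="in_vivo"`` uses Cmax-at-NOAEL over Cmax-at-realistic-dose per
    compartment, flagging tissues whose endpoint lacks a NOAEL.  Also
    returns the per-(tissue, compartment) combined MoE across chemicals.
    """
    tissue_organs = dict(tissue_organs or DEFAULT_TISSUE_ORGANS)
    tissue_endpoints = dict(tissue_endpoints or DEFAULT_TISSUE_ENDPOINTS)
    results: list[MoEResult] = []

    if track == "nam":
        if refined_indicators is None or refined_indicators.empty:
            raise ValueError("nam track requires refined indicators")
        pairing = {"interstitial": "c_free", "intracellular": "c_cell"}
        basis = {"interstitial": "refined_free", "intracellular": "refined_cell"}
        for _, row in refined_indicators.iterrows():
            chem, tissue = row["chemical_id"], row["tissue"]
            pk = pk_results.get(chem)
            if pk is None:
                continue
            for compartment, column in pairing.items():
                cmax = _compartment_cmax(pk, tissue, compartment, tissue_organs)
                moe = margin_of_exposure(float(row[column]), cmax)
                results.append(
                    MoEResult(chem, tissue, compartment, basis[compartment],
                              float(row[column]), cmax, moe,
                              bin_moe(moe, scheme), bin_color(moe, scheme))
                )
    elif track == "in_vivo":
        if noael_results is None:
            raise ValueError("in_vivo track requires NOAEL simulations")
        wanted = list(tissues) if tissues is not None else sorted(
            t for t, e in tissue_endpoints.items() if e != "peripheral_general"
        )
        for chem, pk in pk_results.items():
            sims = noael_results.get(chem)
            if sims is None:
                continue
            for tissue in wanted:
                endpoint = tissue_endpoints.get(tissue)
                for compartment in ("interstitial", "intracellular"):
                    exposure = _compartment_cmax(pk, tissue, compartment, tissue_organs)
                    pk_noael = sims.results.get(endpoint) if endpoint else None
                    if pk_noael is None:
                        results.append(
                            MoEResult(chem, tissue, compartment, "noael_internal",
                                      None, exposure, None, None, None,
                                      ABSENT_NOAEL_NOTE)
                        )
                        continue
                    organ = ENDPOINT_ORGANS.get(endpoint)
                    if organ is None:
                        pod = pk_noael.cmax("plasma")
                    else:
                        pod = pk_noael.cmax(f"{organ}:{compartment}")
                    moe = margin_of_exposure(pod, exposure)
                    results.append(
                        MoEResult(chem, tissue, compartment, "noael_internal",
                                  pod, exposure, moe,
                                  bin_moe(moe, scheme), bin_color(moe, scheme))
                    )
    else:
        raise ValueError(f"unknown track {track!r}")

    return results, _combined_by_group(results)
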