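"""Generic whole-body, perfusion-limited PBPK engine (Tiers 3–4).

The model simulates repeated oral dosing of a lipophilic chemical in a
reference adult: gut lumen with first-order, permeability-derived
absorption into the portal circulation, venous and arterial blood, a lung
compartment in series, and perfusion-limited organs each carrying derived
interstitial and intracellular concentrations.  Elimination is hepatic
(Michaelis–Menten when an enzymatic turnover number is available, linear
intrinsic clearance otherwise) plus renal filtration of the free plasma
fraction.

Distribution follows the free-drug hypothesis: at perfusion equilibrium the
interstitial concentration equals ``fu × C_plasma`` and the intracellular
concentration ``Kp_cell × fu × C_plasma`` with a lipid-fraction partition
rule ``Kp_cell = f_lipid · 10^(a·logP) + (1 − f_lipid)`` where ``a`` is a
membrane-affinity adjustment (< 1) accounting for membrane lipids sorbing
less than octanol for very hydrophobic solutes.  Each organ is integrated
as a single perfusion-limited state; sub-compartment concentrations are
derived algebraically, so mass balance is exact up to solver tolerance.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field
from typing import Iterable, Literal, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy.integrate import solve_ivp

from .physiology import PhysiologyConfig, build_physiology
from .potency import ReferenceValue

log = logging.getLogger(__name__)

#: organ simulated for each reference-dose endpoint; None means the plasma
#: (peripheral) concentration is the readout.
ENDPOINT_ORGANS: dict[str, str | None] = {
    "peripheral_general": None,
    "brain_neuro_repeated": "brain",
    "kidney_long_term": "kidney",
    "liver_long_term": "liver",
    "lung_long_term": "lung",
    "skin_short_term": "skin",
}


@dataclass(frozen=True)
class ChemicalParameters:
    """Physicochemical/ADME parameter set for one chemical.

    Units: molecular_weight g/mol; water_solubility mg/mL; fraction_unbound
    (0, 1]; intestinal_permeability cm/s; km µM; kcat 1/h (None → linear
    hepatic clearance fallback); oral_dose mg/kg bw/d.
    """

    chemical_id: str
    molecular_weight: float
    water_solubility: float
    fraction_unbound: float
    log_p: float
    intestinal_permeability: float
    km: float
    oral_dose: float
    pka: float | None = None
    kcat: float | None = None

    def __post_init__(self) -> None:
        for name in (
            "molecular_weight",
            "water_solubility",
            "intestinal_permeability",
            "km",
        ):
            if not getattr(self, name) > 0:
                raise ValueError(f"{name} must be positive")
        if not 0 < self.fraction_unbound <= 1:
            raise ValueError("fraction_unbound must lie in (0, 1]")
        if self.oral_dose < 0:
            raise ValueError("oral_dose must be non-negative")
        if self.kcat is not None and self.kcat <= 0:
            raise ValueError("kcat must be positive when present")


@dataclass(frozen=True)
class DoseRegimen:
    """Repeated oral dosing: one dose every ``interval`` hours for
    ``duration`` days."""

    dose: float  # mg/kg bw/d
    interval: float = 24.0  # h
    duration: float = 90.0  # d
    route: Literal["oral"] = "oral"

    def __post_init__(self) -> None:
        if self.dose < 0:
            raise ValueError("dose must be non-negative")
        if self.interval <= 0:
            raise ValueError("interval must be positive")
        if self.duration * 24.0 < self.interval:
            raise ValueError("duration must cover at least one interval")

    @property
    def n_doses(self) -> int:
        return int(round(self.duration * 24.0 / self.interval))


@dataclass(frozen=True)
class SolverConfig:
    """Numerical settings for :func:`simulate`."""

    method: str = "LSODA"
    rtol: float = 1e-8
    atol: float = 1e-12  # µmol
    membrane_affinity_slope: float = 0.85  # a in Kp_cell = f_lip·10^(a·logP)+f_w
    linear_clearance_intrinsic: float = 100.0  # L/h, used when kcat is absent
    absorption: Literal["first_order", "instant"] = "first_order"
    points_per_interval: int = 9
    final_points: int = 241
    negative_tolerance: float = 1e-9  # µmol/L allowed undershoot


class SolverError(RuntimeError):
    """Raised on integrator failure or unphysical output."""


@dataclass
class PKResult:
    """Concentration–time outcome of one simulation.

    ``compartments`` maps names — ``"plasma"`` and ``"<organ>:interstitial"``
    / ``"<organ>:intracellular"`` — to µmol/L series on ``times`` (h).
    Summary metrics (cmax, cmin, auc) are evaluated over the final dosing
    interval.  ``cumulative`` holds absorbed/metabolized/excreted_urine/
    feces amount series (µmol); ``administered`` the running dosed amount.
    """

    chemical_id: str
    times: np.ndarray
    compartments: dict[str, np.ndarray]
    cumulative: dict[str, np.ndarray]
    administered: np.ndarray
    body_burden: np.ndarray
    summary: dict[str, dict[str, float]]
    regimen: DoseRegimen

    def cmax(self, compartment: str) -> float:
        return self.summary[compartment]["cmax"]

    def cmin(self, compartment: str) -> float:
        return self.summary[compartment]["cmin"]

    def auc(self, compartment: str) -> float:
        return self.summary[compartment]["auc"]

    @property
    def mass_balance_error(self) -> float:
        """Max |administered − accounted| over output times, relative to the
        total administered dose."""
        accounted = (
            self.body_burden
            + self.cumulative["metabolized"]
            + self.cumulative["excreted_urine"]
            + self.cumulative["feces"]
        )
        total = self.administered[-1]
        if total == 0:
            return float(np.max(np.abs(accounted)))
        return float(np.max(np.abs(self.administered - accounted)) / total)

    def daily_amount(self, which: str) -> float:
        """Amount (µmol) of a cumulative stream over the final 24 h."""
        series = self.cumulative[which]
        t_end = self.times[-1]
        start = float(np.interp(t_end - 24.0, self.times, series))
        return float(series[-1] - start)

    def summary_frame(self) -> pd.DataFrame:
        rows = [
            {"compartment": comp, **metrics} for comp, metrics in self.summary.items()
        ]
        return pd.DataFrame(rows)

    def series_frame(self) -> pd.DataFrame:
        data = {"time_h": self.times}
        data.update(self.compartments)
        return pd.DataFrame(data)


def partition_coefficients(
    chem: ChemicalParameters,
    phys: PhysiologyConfig,
    membrane_affinity_slope: float = SolverConfig.membrane_affinity_slope,
) -> dict[str, float]:
    """Intracellular:plasma-water partition coefficient per organ.

    ``Kp_cell = f_lipid · 10^(a · logP) + (1 − f_lipid)`` — lipid sorption
    scaled by the membrane-affinity-adjusted logP plus the aqueous cell
    fraction.  Deterministic in its inputs.
    """
    k_lip = 10.0 ** (membrane_affinity_slope * chem.log_p)
    return {
        name: organ.f_lipid * k_lip + (1.0 - organ.f_lipid)
        for name, organ in phys.organs.items()
    }


def absorption_rate_constant(chem: ChemicalParameters, phys: PhysiologyConfig) -> float:
    """First-order ka (1/h) from permeability × effective surface / lumen volume."""
    return (
        chem.intestinal_permeability
        * phys.gut_surface_area
        * 3600.0
        / (phys.gut_lumen_volume * 1000.0)
    )


def dose_amount_umol(chem: ChemicalParameters, phys: PhysiologyConfig, dose: float) -> float:
    """One administration (µmol) from a mg/kg bw/d dose level."""
    return dose * phys.body_weight / chem.molecular_weight * 1000.0


def simulate(
    chem: ChemicalParameters,
    phys: PhysiologyConfig | None = None,
    regimen: DoseRegimen | None = None,
    solver: SolverConfig | None = None,
) -> PKResult:
    """Integrate the whole-body model over the full dosing history.

    Cmax/Cmin/AUC are extracted over the final dosing interval.  Raises
    :class:`SolverError` on integrator failure or concentrations more
    negative than the configured tolerance.
    """
    phys = phys or build_physiology()
    regimen = regimen or DoseRegimen(dose=chem.oral_dose)
    solver = solver or SolverConfig()

    organ_names = list(phys.organs)
    kp_cell = partition_coefficients(chem, phys, solver.membrane_affinity_slope)
    fu = chem.fraction_unbound
    # effective volume linking organ amount to its local plasma concentration
    vkp = {
        name: organ.volume
        * (organ.f_vascular + organ.f_interstitial * fu + organ.f_intracellular * fu * kp_cell[name])
        for name, organ in phys.organs.items()
    }
    has = {name: name in phys.organs for name in ("lung", "gut", "liver", "kidney")}
    q_sys = phys.cardiac_output
    q_gut = phys.organs["gut"].flow if has["gut"] else 0.0
    q_hep = phys.organs["liver"].flow if has["liver"] else 0.0
    ka = absorption_rate_constant(chem, phys)
    kt = phys.gut_transit_rate
    vmax = None if chem.kcat is None else chem.kcat * phys.hepatic_enzyme_capacity
    clint = solver.linear_clearance_intrinsic
    km = chem.km
    gfr = phys.glomerular_filtration

    n_organs = len(organ_names)
    idx = {name: 3 + i for i, name in enumerate(organ_names)}
    I_LUMEN, I_VEN, I_ART = 0, 1, 2
    I_ABS, I_MET, I_UR, I_FEC = 3 + n_organs, 4 + n_organs, 5 + n_organs, 6 + n_organs
    n_states = 7 + n_organs

    def rhs(_t: float, y: np.ndarray) -> np.ndarray:
        dy = np.zeros(n_states)
        c_ven = y[I_VEN] / phys.venous_volume
        c_art = y[I_ART] / phys.arterial_volume
        cp = {name: y[idx[name]] / vkp[name] for name in organ_names}

        r_abs = 0.0
        if solver.absorption == "first_order":
            r_abs = ka * y[I_LUMEN]
            dy[I_LUMEN] = -r_abs - kt * y[I_LUMEN]
            dy[I_FEC] = kt * y[I_LUMEN]
        dy[I_ABS] = r_abs

        # metabolism: hepatic if a liver exists, otherwise on venous blood
        site = cp["liver"] if has["liver"] else c_ven
        cu = fu * site
        if vmax is not None:
            r_met = vmax * cu / (km + cu) if cu > 0 else 0.0
        else:
            r_met = clint * cu
        dy[I_MET] = r_met

        # renal filtration of free chemical
        c_renal = cp["kidney"] if has["kidney"] else c_art
        r_ur = gfr * fu * c_renal
        dy[I_UR] = r_ur

        venous_in = 0.0
        for name in organ_names:
            if name in ("lung", "gut", "liver"):
                continue
            q = phys.organs[name].flow
            dy[idx[name]] = q * (c_art - cp[name])
            venous_in += q * cp[name]
        if has["kidney"]:
            dy[idx["kidney"]] -= r_ur

        if has["gut"]:
            dy[idx["gut"]] = q_gut * (c_art - cp["gut"]) + r_abs
            gut_out = q_gut * cp["gut"]
        else:
            gut_out = 0.0

        if has["liver"]:
            absorbed_direct = 0.0 if has["gut"] else r_abs
            dy[idx["liver"]] = (
                q_hep * c_art + gut_out + absorbed_direct
                - (q_hep + q_gut) * cp["liver"] - r_met
            )
            venous_in += (q_hep + q_gut) * cp["liver"]
        else:
            venous_in += gut_out + (0.0 if has["gut"] else r_abs)

        dy[I_VEN] = venous_in - q_sys * c_ven
        if not has["liver"]:
            dy[I_VEN] -= r_met

        if has["lung"]:
            dy[idx["lung"]] = q_sys * (c_ven - cp["lung"])
            dy[I_ART] = q_sys * cp["lung"] - q_sys * c_art
        else:
            dy[I_ART] = q_sys * (c_ven - c_art)
        return dy

    dose_umol = dose_amount_umol(chem, phys, regimen.dose)
    n_intervals = regimen.n_doses
    y = np.zeros(n_states)
    times: list[np.ndarray] = []
    states: list[np.ndarray] = []
    administered: list[np.ndarray] = []
    given = 0.0
    for k in range(n_intervals):
        if solver.absorption == "instant":
            y[I_VEN] += dose_umol
            y[I_ABS] += dose_umol
        else:
            y[I_LUMEN] += dose_umol
        given += dose_umol
        t0, t1 = k * regimen.interval, (k + 1) * regimen.interval
        n_pts = solver.final_points if k == n_intervals - 1 else solver.points_per_interval
        t_eval = np.linspace(t0, t1, n_pts)
        sol = solve_ivp(
            rhs,
            (t0, t1),
            y,
            method=solver.method,
            rtol=solver.rtol,
            atol=solver.atol,
            t_eval=t_eval,
            dense_output=False,
        )
        if not sol.success:
            raise SolverError(
                f"integration failed for {chem.chemical_id} in interval {k}: {sol.message}"
            )
        y = sol.y[:, -1].copy()
        sl = slice(1, None) if k else slice(None)  # avoid duplicated boundary points
        times.append(sol.t[sl])
        states.append(sol.y[:, sl])
        administered.append(np.full(sol.t[sl].shape, given))

    t = np.concatenate(times)
    ystack = np.concatenate(states, axis=1)
    admin = np.concatenate(administered)

    if ystack.min() < -solver.negative_tolerance * max(given, 1.0):
        raise SolverError(
            f"negative amounts beyond tolerance for {chem.chemical_id}: "
            f"min={ystack.min():.3e}"
        )
    ystack = np.clip(ystack, 0.0, None)

    compartments: dict[str, np.ndarray] = {"plasma": ystack[I_VEN] / phys.venous_volume}
    for name in organ_names:
        cp_series = ystack[idx[name]] / vkp[name]
        compartments[f"{name}:interstitial"] = fu * cp_series
        compartments[f"{name}:intracellular"] = kp_cell[name] * fu * cp_series

    body_burden = (
        ystack[I_LUMEN]
        + ystack[I_VEN]
        + ystack[I_ART]
        + ystack[3 : 3 + n_organs].sum(axis=0)
    )
    cumulative = {
        "absorbed": ystack[I_ABS],
        "metabolized": ystack[I_MET],
        "excreted_urine": ystack[I_UR],
        "feces": ystack[I_FEC],
    }

    final_mask = t >= (n_intervals - 1) * regimen.interval - 1e-9
    tf = t[final_mask]
    summary = {}
    for comp, series in compartments.items():
        window = series[final_mask]
        summary[comp] = {
            "cmax": float(window.max()),
            "cmin": float(window.min()),
            "auc": float(np.trapezoid(window, tf)),
        }
    return PKResult(
        chemical_id=chem.chemical_id,
        times=t,
        compartments=compartments,
        cumulative=cumulative,
        administered=admin,
        body_burden=body_burden,
        summary=summary,
        regimen=regimen,
    )


@dataclass
class NoaelSimulations:
    """Per-endpoint PKResult at NOAEL dosing, with skipped endpoints logged."""

    chemical_id: str
    results: dict[str, PKResult]
    skipped: list[str] = field(default_factory=list)

    def cmax_table(self) -> pd.DataFrame:
        """Per endpoint: interstitial and intracellular Cmax of the target
        organ (plasma Cmax for the peripheral endpoint)."""
        rows = []
        for endpoint, pk in self.results.items():
            organ = ENDPOINT_ORGANS.get(endpoint)
            if organ is None:
                cmax = pk.cmax("plasma")
                rows.append(
                    {"endpoint": endpoint, "c_interst": cmax, "c_intracel": cmax}
                )
            else:
                rows.append(
                    {
                        "endpoint": endpoint,
                        "c_interst": pk.cmax(f"{organ}:interstitial"),
                        "c_intracel": pk.cmax(f"{organ}:intracellular"),
                    }
                )
        return pd.DataFrame(rows)


def simulate_at_noael(
    chem: ChemicalParameters,
    noaels: Iterable[ReferenceValue],
    phys: PhysiologyConfig | None = None,
    regimen: DoseRegimen | None = None,
    solver: SolverConfig | None = None,
) -> NoaelSimulations:
    """Re-run :func:`simulate` with the dose replaced by each NOAEL.

    Endpoints without a NOAEL are skipped and recorded, mirroring the blank
    reference-value cells.  Identical NOAEL doses share one simulation.
    """
    phys = phys or build_physiology()
    base = regimen or DoseRegimen(dose=chem.oral_dose)
    results: dict[str, PKResult] = {}
    skipped: list[str] = []
    by_dose: dict[float, PKResult] = {}
    for ref in noaels:
        if ref.chemical_id != chem.chemical_id or ref.kind != "NOAEL":
            continue
        if ref.value is None:
            skipped.append(ref.endpoint)
            log.info("no NOAEL for %s / %s; endpoint skipped", chem.chemical_id, ref.endpoint)
            continue
        if ref.value not in by_dose:
            reg = DoseRegimen(
                dose=ref.value, interval=base.interval, duration=base.duration
            )
            by_dose[ref.value] = simulate(chem, phys, reg, solver)
        results[ref.endpoint] = by_dose[ref.value]
    return NoaelSimulations(chemical_id=chem.chemical_id, results=results, skipped=skipped)


def urine_metabolite_concentration(
    pk: PKResult,
    metabolite_mw: float,
    molar_yield: float = 1.0,
    urine_volume: float = 1.5,
    basis: Literal["excreted", "absorbed", "metabolized"] = "excreted",
) -> float:
    """Back-calculated urinary metabolite concentration (µg/L).

    Daily parent flux (µmol/d over the final interval, from the ``basis``
    cumulative stream) × molar yield × metabolite molecular weight ÷ daily
    urine volume.  ``basis="absorbed"`` treats the metabolite as the
    terminal urinary fate of the absorbed parent, the usual biomonitoring
    assumption for rapidly hydrolysed esters.
    """
    if urine_volume <= 0:
        raise ValueError("urine_volume must be positive")
    key = {"excreted": "excreted_urine", "absorbed": "absorbed", "metabolized": "metabolized"}[basis]
    daily = pk.daily_amount(key)
    return daily * molar_yield * metabolite_mw / urine_volume


#: molecular weight (g/mol) of DBCA, the dibromovinyl-cyclopropanecarboxylic
#: acid urinary metabolite of deltamethrin (C8H10Br2O2)
DBCA_MW = 297.97


def table9_logratio_diagnostics(
    noael_cmax: pd.DataFrame, reference: pd.DataFrame
) -> pd.DataFrame:
    """log10(model / reference) Cmax diagnostics against an external PBPK run.

    Joined on (chemical_id, endpoint); reported for orientation only — the
    reference values come from a different distribution engine and are not
    an equality oracle.
    """
    merged = noael_cmax.merge(
        reference,
        on=["chemical_id", "endpoint"],
        suffixes=("_model", "_ref"),
        how="inner",
    )
    for comp in ("c_interst", "c_intracel"):
        merged[f"log10_ratio_{comp}"] = np.log10(
            merged[f"{comp}_model"] / merged[f"{comp}_ref"]
        )
    return merged


def simulate_population(
    chem: ChemicalParameters,
    phys: PhysiologyConfig | None = None,
    regimen: DoseRegimen | None = None,
    solver: SolverConfig | None = None,
    n: int = 139,
    variability: float = 0.2,
    seed: int | None = None,
) -> pd.DataFrame:
    """Plasma-Cmax distribution over ``n`` virtual individuals.

    Organ flows and volumes are perturbed log-normally (geometric CV
    ``variability``) around the supplied physiology with a fixed seed.
    """
    from dataclasses import replace

    phys = phys or build_physiology()
    rng = np.random.default_rng(seed)
    rows = []
    for i in range(n):
        organs = {
            name: replace(
                o,
                volume=o.volume * rng.lognormal(0.0, variability),
                flow=o.flow * rng.lognormal(0.0, variability),
            )
            for name, o in phys.organs.items()
        }
        total_volume = (
            sum(o.volume for o in organs.values())
            + phys.venous_volume
            + phys.arterial_volume
        )
        individual = PhysiologyConfig(
            body_weight=max(phys.body_weight, total_volume),  # keep volumes feasible
            organs=organs,
            venous_volume=phys.venous_volume,
            arterial_volume=phys.arterial_volume,
            hepatic_enzyme_capacity=phys.hepatic_enzyme_capacity,
            glomerular_filtration=phys.glomerular_filtration,
            urine_flow=phys.urine_flow,
            gut_lumen_volume=phys.gut_lumen_volume,
            gut_surface_area=phys.gut_surface_area,
            gut_transit_rate=phys.gut_transit_rate,
        )
        pk = simulate(chem, individual, regimen, solver)
        rows.append({"individual": i, "cmax_plasma": pk.cmax("plasma")})
    return pd.DataFrame(rows)
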