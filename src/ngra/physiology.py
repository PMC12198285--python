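"""Reference physiology for the whole-body PBPK model.

Defaults describe a 73-kg adult European male (the population simulated in
the case study).  Organ weights and perfusion rates follow standard
reference-man compilations; each organ is split into vascular, interstitial
and intracellular sub-volumes whose fractions must sum to one, plus a lipid
mass fraction that drives tissue partitioning.
"""

from __future__ import annotations

import copy
from dataclasses import dataclass, field, replace
from typing import Mapping

FRACTION_TOL = 1e-9


@dataclass(frozen=True)
class Organ:
    """One perfusion-limited organ.

    volume L, flow L/h (blood perfusion), sub-compartment volume fractions
    (vascular/interstitial/intracellular, summing to 1), and the lipid mass
    fraction used by the tissue partition rule.
    """

    volume: float
    flow: float
    f_vascular: float
    f_interstitial: float
    f_intracellular: float
    f_lipid: float

    def __post_init__(self) -> None:
        if self.volume <= 0 or self.flow <= 0:
            raise ValueError("organ volume and flow must be positive")
        total = self.f_vascular + self.f_interstitial + self.f_intracellular
        if abs(total - 1.0) > FRACTION_TOL:
            raise ValueError(f"sub-compartment fractions sum to {total}, not 1")
        if not 0.0 <= self.f_lipid <= 1.0:
            raise ValueError("lipid fraction must lie in [0, 1]")


#: 73-kg adult male: organ volumes (L), blood flows (L/h), sub-volume
#: fractions and lipid content.  Liver flow is total (arterial + portal);
#: the portal fraction is routed through the gut in the model.
REFERENCE_MAN: dict[str, Organ] = {
    "liver": Organ(1.8, 20.0, 0.11, 0.16, 0.73, 0.05),  # hepatic artery only
    "gut": Organ(1.2, 70.0, 0.07, 0.28, 0.65, 0.04),  # drains to liver (portal)
    "kidney": Organ(0.31, 74.0, 0.11, 0.20, 0.69, 0.03),
    "brain": Organ(1.45, 46.0, 0.03, 0.18, 0.79, 0.11),
    "lung": Organ(0.5, 349.0, 0.26, 0.19, 0.55, 0.03),  # in series, total CO
    "skin": Organ(3.3, 19.0, 0.02, 0.40, 0.58, 0.05),
    "adipose": Organ(15.0, 19.0, 0.02, 0.14, 0.84, 0.80),
    "muscle": Organ(29.0, 45.0, 0.01, 0.14, 0.85, 0.02),
    "rest": Organ(5.0, 56.0, 0.04, 0.20, 0.76, 0.04),
}

REFERENCE_BODY_WEIGHT = 73.0  # kg


@dataclass
class PhysiologyConfig:
    """Whole-body physiology: organ set, blood pool, elimination capacity
    and the gut geometry behind first-order oral absorption."""

    body_weight: float = REFERENCE_BODY_WEIGHT  # kg
    organs: dict[str, Organ] = field(
        default_factory=lambda: copy.deepcopy(REFERENCE_MAN)
    )
    venous_volume: float = 3.8  # L
    arterial_volume: float = 1.9  # L
    hepatic_enzyme_capacity: float = 10.0  # µmol total enzyme in liver
    glomerular_filtration: float = 7.0  # L/h surrogate for renal filtration
    urine_flow: float = 1.5  # L/d
    gut_lumen_volume: float = 1.0  # L
    gut_surface_area: float = 250.0  # cm², effective smooth area for uptake
    gut_transit_rate: float = 0.04  # 1/h, lumen loss to faeces

    def __post_init__(self) -> None:
        if self.body_weight <= 0:
            raise ValueError("body weight must be positive")
        total_volume = (
            sum(o.volume for o in self.organs.values())
            + self.venous_volume
            + self.arterial_volume
        )
        # ~1.05 L/kg body density: organ volumes must fit inside the body
        if total_volume > 1.1 * self.body_weight:
            raise ValueError(
                f"organ volumes ({total_volume:.1f} L) exceed body volume for "
                f"{self.body_weight} kg"
            )
        for name in ("venous_volume", "arterial_volume", "glomerular_filtration",
                     "urine_flow", "gut_lumen_volume", "gut_surface_area"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")
        if self.gut_transit_rate < 0 or self.hepatic_enzyme_capacity < 0:
            raise ValueError("rates and capacities must be non-negative")

    @property
    def cardiac_output(self) -> float:
        """Total systemic flow (L/h): sum of organ flows excluding the lung,
        which sits in series between the venous and arterial pools."""
        return sum(o.flow for name, o in self.organs.items() if name != "lung")


def build_physiology(overrides: Mapping | None = None) -> PhysiologyConfig:
    """A validated physiology, defaulting to the 73-kg reference male.

    ``overrides`` may set any top-level field; ``body_weight`` rescales all
    organ and blood volumes (and flows) linearly.  Organ-level overrides go
    under an ``organs`` key mapping organ name → field → value.
    """
    overrides = dict(overrides or {})
    organ_overrides = overrides.pop("organs", {})
    phys = PhysiologyConfig()

    if "body_weight" in overrides:
        scale = float(overrides["body_weight"]) / REFERENCE_BODY_WEIGHT
        phys = PhysiologyConfig(
            body_weight=float(overrides.pop("body_weight")),
            organs={
                name: replace(o, volume=o.volume * scale, flow=o.flow * scale)
                for name, o in phys.organs.items()
            },
            venous_volume=phys.venous_volume * scale,
            arterial_volume=phys.arterial_volume * scale,
            glomerular_filtration=phys.glomerular_filtration * scale,
        )

    known = set(PhysiologyConfig.__dataclass_fields__)
    unknown = set(overrides) - known
    if unknown:
        raise ValueError(f"unknown physiology fields: {sorted(unknown)}")
    for key, value in overrides.items():
        if key == "organs":
            continue
        setattr(phys, key, float(value))
    for organ_name, fields in organ_overrides.items():
        if organ_name not in phys.organs:
            raise ValueError(f"unknown organ {organ_name!r}")
        phys.organs[organ_name] = replace(phys.organs[organ_name], **fields)
    phys.__post_init__()  # re-validate after mutation
    return phys
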