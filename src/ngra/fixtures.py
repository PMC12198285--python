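"""Packaged case-study tables and typed loaders.

The six-pyrethroid case study ships as machine-readable CSVs: regulatory
reference doses (ADI/NOAEL), PBPK chemical parameter sets, tissue- and
gene-category mean AC50s with their printed relative potencies, external
PBPK Cmax values at NOAEL dosing, and the published in-vitro disposition
comparison table.  Blank cells are preserved as missing values, never as
zeros.  A checksum manifest guards the fixtures against silent edits.
"""

from __future__ import annotations

import hashlib
import json
from importlib import resources
from typing import Literal

import pandas as pd

from .bioactivity import BioactivityIndicator, frame_to_indicators
from .pbpk import ChemicalParameters
from .potency import RelativePotencyTable, ReferenceValue

PYRETHROIDS = (
    "bifenthrin",
    "cyfluthrin",
    "cypermethrin",
    "deltamethrin",
    "l-cyhalothrin",
    "permethrin",
)

NOAEL_ENDPOINTS = (
    "peripheral_general",
    "brain_neuro_repeated",
    "kidney_long_term",
    "liver_long_term",
    "lung_long_term",
    "skin_short_term",
)

FixtureName = Literal[
    "table1", "table2", "table3", "table4", "table5", "table6", "table9", "table10"
]

_FILES: dict[str, str] = {
    "table1": "table1_reference_values.csv",
    "table2": "table2_chemical_parameters.csv",
    "table3": "table3_tissue_ac50.csv",
    "table4": "table4_gene_ac50.csv",
    "table5": "table5_tissue_rp.csv",
    "table6": "table6_gene_rp.csv",
    "table9": "table9_noael_cmax.csv",
    "table10": "table10_disposition.csv",
}


class FixtureIntegrityError(RuntimeError):
    """A packaged fixture no longer matches its recorded checksum."""


def _data_path(filename: str):
    return resources.files(__package__).joinpath("data", filename)


def _verify_checksum(filename: str, payload: bytes) -> None:
    manifest = json.loads(_data_path("checksums.json").read_text())
    expected = manifest.get(filename)
    digest = hashlib.sha256(payload).hexdigest()
    if expected is not None and digest != expected:
        raise FixtureIntegrityError(
            f"fixture {filename} checksum mismatch (expected {expected}, got {digest})"
        )


def load_fixture_frame(name: str) -> pd.DataFrame:
    """Raw fixture table as a DataFrame (blank cells as NaN)."""
    if name not in _FILES:
        raise KeyError(f"unknown fixture {name!r}; choose from {sorted(_FILES)}")
    filename = _FILES[name]
    payload = _data_path(filename).read_bytes()
    _verify_checksum(filename, payload)
    import io

    return pd.read_csv(io.BytesIO(payload))


def load_fixture(name: str):
    """Fixture parsed into the package's domain types.

    table1 → list[ReferenceValue]; table2 → dict[str, ChemicalParameters];
    table3/table4 → list[BioactivityIndicator]; table5/table6 →
    RelativePotencyTable (printed 2-dp values); table9/table10 → DataFrame.
    """
    frame = load_fixture_frame(name)
    if name == "table1":
        refs: list[ReferenceValue] = []
        for _, row in frame.iterrows():
            chem = row["chemical_id"]
            for endpoint in NOAEL_ENDPOINTS:
                value = row[endpoint]
                refs.append(
                    ReferenceValue(
                        chemical_id=chem,
                        kind="NOAEL",
                        endpoint=endpoint,
                        value=None if pd.isna(value) else float(value),
                    )
                )
            refs.append(
                ReferenceValue(
                    chemical_id=chem, kind="ADI", endpoint="general",
                    value=float(row["adi"]),
                )
            )
        return refs
    if name == "table2":
        chems: dict[str, ChemicalParameters] = {}
        for _, row in frame.iterrows():
            chems[row["chemical_id"]] = ChemicalParameters(
                chemical_id=row["chemical_id"],
                molecular_weight=float(row["molecular_weight"]),
                water_solubility=float(row["water_solubility"]),
                fraction_unbound=float(row["fraction_unbound"]),
                log_p=float(row["log_p"]),
                pka=None if pd.isna(row["pka"]) else float(row["pka"]),
                intestinal_permeability=float(row["intestinal_permeability"]),
                km=float(row["km"]),
                kcat=None if pd.isna(row["kcat"]) else float(row["kcat"]),
                oral_dose=float(row["oral_dose"]),
            )
        return chems
    if name in ("table3", "table4"):
        kind = "tissue" if name == "table3" else "gene"
        return frame_to_indicators(frame.set_index("category"), kind)
    if name in ("table5", "table6"):
        kind = "tissue" if name == "table5" else "gene"
        wide = frame.set_index("category")
        entries = {
            cat: {chem: float(v) for chem, v in row.items() if not pd.isna(v)}
            for cat, row in wide.iterrows()
        }
        return RelativePotencyTable(category_kind=kind, entries=entries)
    return frame


def realistic_regimen_doses() -> dict[str, float]:
    """Chronic dietary exposure levels (mg/kg bw/d) per chemical."""
    return {c.chemical_id: c.oral_dose for c in load_fixture("table2").values()}
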