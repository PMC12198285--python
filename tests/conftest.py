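import numpy as np
import pytest

from ngra import fixtures, pbpk
from ngra.bioactivity import BioactivityIndicator
from ngra.pbpk import ChemicalParameters, DoseRegimen, PKResult


@pytest.fixture(scope="session")
def chemicals():
    return fixtures.load_fixture("table2")


@pytest.fixture(scope="session")
def reference_values():
    return fixtures.load_fixture("table1")


@pytest.fixture(scope="session")
def tissue_indicators():
    return fixtures.load_fixture("table3")


@pytest.fixture(scope="session")
def gene_indicators():
    return fixtures.load_fixture("table4")


@pytest.fixture(scope="session")
def fast_chemical():
    """A moderately lipophilic, quickly equilibrating test chemical: short
    tissue equilibration makes periodic steady state reachable in days."""
    return ChemicalParameters(
        chemical_id="testol",
        molecular_weight=300.0,
        water_solubility=1.0,
        fraction_unbound=0.5,
        log_p=2.0,
        intestinal_permeability=3e-4,
        km=50.0,
        kcat=None,
        oral_dose=1.0,
    )


@pytest.fixture(scope="session")
def realistic_simulations(chemicals):
    """The six chronic-exposure simulations, shared across tests."""
    return {cid: pbpk.simulate(chem) for cid, chem in chemicals.items()}


def stub_pk(chemical_id: str, summary: dict[str, dict[str, float]]) -> PKResult:
    """Minimal PKResult carrying only summary metrics, for risk-layer tests."""
    t = np.linspace(0.0, 24.0, 3)
    zero = np.zeros_like(t)
    return PKResult(
        chemical_id=chemical_id,
        times=t,
        compartments={name: zero for name in summary},
        cumulative={k: zero for k in ("absorbed", "metabolized", "excreted_urine", "feces")},
        administered=zero,
        body_burden=zero,
        summary=summary,
        regimen=DoseRegimen(dose=1.0, duration=1.0),
    )


def make_indicator(chem, category, mean, kind="tissue", n=1):
    return BioactivityIndicator(
        chemical_id=chem, category_kind=kind, category=category,
        mean_ac50=mean, n_assays=n,
    )
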