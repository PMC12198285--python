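"""Margins of exposure, binning, prioritization and mixture MOET."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from ngra.risk import (
    TIER3_SCHEME,
    TIER5_SCHEME,
    BinScheme,
    bin_moe,
    combined_moe,
    margin_of_exposure,
    prioritize,
    refined_risk_table,
    results_to_frame,
    screening_table,
)
from ngra.pbpk import NoaelSimulations

from conftest import make_indicator, stub_pk


def pk_with(chem, plasma=1e-4, **organ_cmax):
    """Stub PK summary: organ_cmax maps organ → (interstitial, intracellular)."""
    summary = {"plasma": {"cmax": plasma, "cmin": plasma / 2, "auc": plasma * 24}}
    for organ, (inter, intra) in organ_cmax.items():
        summary[f"{organ}:interstitial"] = {"cmax": inter, "cmin": 0.0, "auc": 0.0}
        summary[f"{organ}:intracellular"] = {"cmax": intra, "cmin": 0.0, "auc": 0.0}
    return stub_pk(chem, summary)


class TestMarginOfExposure:
    def test_simple_division(self):
        assert margin_of_exposure(10.0, 0.1) == pytest.approx(100.0)

    def test_equal_pod_and_exposure(self):
        assert margin_of_exposure(2.0, 2.0) == 1.0

    def test_absent_pod_flagged_not_zero(self):
        assert margin_of_exposure(None, 1.0) is None

    def test_zero_exposure_is_an_error(self):
        with pytest.raises(ValueError):
            margin_of_exposure(1.0, 0.0)


class TestBinning:
    @pytest.mark.parametrize(
        "moe, label",
        [
            (99.99, "<100 (higher concern)"),
            (100.0, "100-1000"),  # boundary belongs to the upper bin
            (1e6, ">100,000 (lowest concern)"),
        ],
    )
    def test_screening_scheme_labels(self, moe, label):
        assert bin_moe(moe, TIER3_SCHEME) == label

    def test_binning_is_monotone(self):
        values = [0.5, 1.0, 5.0, 10.0, 99.0, 100.0, 5000.0]
        ranks = [TIER5_SCHEME.labels.index(bin_moe(v, TIER5_SCHEME)) for v in values]
        assert ranks == sorted(ranks)

    def test_invalid_scheme_rejected(self):
        with pytest.raises(ValueError):
            BinScheme("bad", (100.0, 10.0), ("a", "b", "c"), ("r", "g", "b"))


class TestCombinedMoe:
    def test_single_element_identity(self):
        assert combined_moe([50.0]) == 50.0

    def test_two_equal_elements_halve(self):
        assert combined_moe([100.0, 100.0]) == pytest.approx(50.0)

    def test_reciprocal_sum_oracle_case(self):
        assert combined_moe([120.0, 350.0, 900.0, 4000.0]) == pytest.approx(79.67, abs=0.005)

    @given(st.lists(st.floats(0.1, 1e6), min_size=1, max_size=8))
    @settings(max_examples=200, deadline=None)
    def test_never_exceeds_smallest_and_is_permutation_invariant(self, moes):
        moet = combined_moe(moes)
        assert moet <= min(moes) * (1 + 1e-12)
        assert combined_moe(list(reversed(moes))) == pytest.approx(moet, rel=1e-12)

    def test_adding_a_chemical_never_increases_moet(self):
        base = [120.0, 350.0]
        assert combined_moe(base + [900.0]) < combined_moe(base)

    def test_empty_is_an_error(self):
        with pytest.raises(ValueError):
            combined_moe([])


class TestScreeningTable:
    def test_end_to_end_arithmetic(self):
        inds = [make_indicator("x", "Brain", 10.0)]
        pks = {"x": pk_with("x", brain=(1e-4, 1e-2))}
        results = screening_table(inds, pks)
        inter = next(r for r in results if r.compartment == "interstitial")
        assert inter.moe == pytest.approx(1e5)
        assert inter.bin == ">100,000 (lowest concern)"  # boundary → upper bin
        intra = next(r for r in results if r.compartment == "intracellular")
        assert intra.moe == pytest.approx(1e3)
        assert intra.bin == "1000-100,000"

    def test_missing_ac50_yields_flagged_cell(self):
        inds = [make_indicator("x", "Brain", 10.0), make_indicator("y", "Liver", 5.0)]
        pks = {
            "x": pk_with("x", brain=(1e-4, 1e-2), liver=(1e-4, 1e-2)),
            "y": pk_with("y", brain=(1e-4, 1e-2), liver=(1e-4, 1e-2)),
        }
        results = screening_table(inds, pks)
        flagged = [r for r in results if r.flagged_absent]
        assert {(r.chemical_id, r.tissue) for r in flagged} == {("x", "Liver"), ("y", "Brain")}
        assert all("lack of AC50" in r.note for r in flagged)

    def test_cell_count_accounting(self):
        inds = [make_indicator("x", "Brain", 10.0), make_indicator("x", "Liver", 5.0)]
        pks = {"x": pk_with("x", brain=(1e-4, 1e-2), liver=(1e-4, 1e-2))}
        results = screening_table(inds, pks)
        frame = results_to_frame(results)
        assert len(frame) == 1 * 2 * 2  # chemicals × tissues × compartments
        assert frame["moe"].notna().all()

    def test_no_overlap_is_an_error(self):
        with pytest.raises(ValueError):
            screening_table([make_indicator("x", "Brain", 1.0)], {"y": pk_with("y")})


class TestPrioritize:
    def _results(self, moes):
        inds = [make_indicator("x", t, m * 1e-4) for t, m in moes.items()]
        pks = {"x": pk_with("x", **{t.lower(): (1e-4, 1e-4) for t in moes})}
        return screening_table(inds, pks, tissue_organs={t: t.lower() for t in moes})

    def test_all_above_threshold_is_empty(self):
        assert prioritize(self._results({"Brain": 500.0})) == []

    def test_single_cell_below_threshold(self):
        targets = prioritize(self._results({"Brain": 99.0, "Liver": 200.0}))
        assert [(t.chemical_id, t.tissue) for t in targets] == [("x", "Brain")]

    def test_flagged_sets_nest_with_threshold(self):
        results = self._results({"Brain": 50.0, "Liver": 500.0, "Skin": 5000.0})
        under_100 = {(t.chemical_id, t.tissue) for t in prioritize(results, 100.0)}
        under_1000 = {(t.chemical_id, t.tissue) for t in prioritize(results, 1000.0)}
        assert under_100 <= under_1000

    def test_gene_indicators_attached(self):
        genes = [make_indicator("x", "Neuroreceptor", 0.3, kind="gene")]
        targets = prioritize(self._results({"Brain": 10.0}), gene_indicators=genes)
        assert targets[0].gene_indicators[0].category == "Neuroreceptor"


class TestRefinedRiskTable:
    def test_in_vivo_track_with_noael_equal_to_dose_gives_unit_moes(self):
        pk = pk_with("x", brain=(1e-4, 1e-2))
        sims = NoaelSimulations("x", {"brain_neuro_repeated": pk})
        results, combined = refined_risk_table(
            None, {"x": pk}, track="in_vivo", noael_results={"x": sims},
            tissues=["Brain"],
        )
        assert all(r.moe == pytest.approx(1.0) for r in results if r.moe is not None)
        assert all(c.moet == pytest.approx(1.0) for c in combined)

    def test_missing_noael_flagged(self):
        pk = pk_with("x", skin=(1e-4, 1e-2))
        sims = NoaelSimulations("x", {}, skipped=["skin_short_term"])
        results, _ = refined_risk_table(
            None, {"x": pk}, track="in_vivo", noael_results={"x": sims},
            tissues=["Skin"],
        )
        assert all(r.flagged_absent for r in results)
        assert all("lack of NOAELs" in r.note for r in results)

    def test_nam_track_pairs_free_with_interstitial(self):
        import pandas as pd

        refined = pd.DataFrame(
            [{"chemical_id": "x", "tissue": "Brain", "c_nom": 10.0,
              "c_free": 0.01, "c_cell": 100.0, "c_mem": 1000.0}]
        )
        pk = pk_with("x", brain=(1e-4, 1e-2))
        results, combined = refined_risk_table(refined, {"x": pk}, track="nam")
        by_comp = {r.compartment: r for r in results}
        assert by_comp["interstitial"].moe == pytest.approx(0.01 / 1e-4)
        assert by_comp["intracellular"].moe == pytest.approx(100.0 / 1e-2)
        assert sorted(c.moet for c in combined) == pytest.approx([100.0, 10000.0])

    def test_combined_never_exceeds_smallest_member(self):
        import pandas as pd

        refined = pd.DataFrame(
            [
                {"chemical_id": c, "tissue": "Brain", "c_nom": 10.0,
                 "c_free": f, "c_cell": 10 * f, "c_mem": 0.0}
                for c, f in [("x", 0.01), ("y", 0.05)]
            ]
        )
        pks = {c: pk_with(c, brain=(1e-4, 1e-2)) for c in ("x", "y")}
        results, combined = refined_risk_table(refined, pks, track="nam")
        for c in combined:
            members = [r.moe for r in results
                       if r.tissue == c.tissue and r.compartment == c.compartment]
            assert c.moet <= min(members) * (1 + 1e-12)
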