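import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

import gfresponse as gf
from gfresponse.bias import EnrichmentResult
from gfresponse.errors import ValidationError


def cvm_bruteforce(a, b):
    """Independent double-loop ECDF implementation of the two-sample statistic."""
    a, b = list(a), list(b)
    n, m = len(a), len(b)
    total = 0.0
    for z in a + b:
        fa = sum(1 for x in a if x <= z) / n
        fb = sum(1 for y in b if y <= z) / m
        total += (fa - fb) ** 2
    return total / (n + m)


class TestCvmDistance:
    def test_identical_samples_zero(self):
        assert gf.cvm_distance([1.0, 2.0, 3.0], [1.0, 2.0, 3.0]) == 0.0

    def test_disjoint_samples_maximal(self):
        # fully separated n = m = 3 samples: frozen value 19/54 from the
        # pooled-ECDF sum (14/9 + 5/9) divided by the pooled size 6
        d = gf.cvm_distance([1, 2, 3], [11, 12, 13])
        assert d == pytest.approx(19 / 54)
        # no n=m=3 configuration scores higher
        assert d >= cvm_bruteforce([1, 3, 5], [2, 4, 6])

    def test_monotone_transform_invariance(self):
        rng = np.random.default_rng(0)
        a, b = rng.normal(size=9), rng.normal(size=13)
        d0 = gf.cvm_distance(a, b)
        assert gf.cvm_distance(np.exp(a), np.exp(b)) == pytest.approx(d0)
        assert gf.cvm_distance(a ** 3, b ** 3) == pytest.approx(d0)

    def test_empty_sample_rejected(self):
        with pytest.raises(ValidationError):
            gf.cvm_distance([], [1.0])

    def test_matches_bruteforce_on_random_pairs(self):
        rng = np.random.default_rng(7)
        for _ in range(50):
            n, m = rng.integers(1, 13, size=2)
            a, b = rng.normal(size=n), rng.normal(size=m)
            assert gf.cvm_distance(a, b) == pytest.approx(cvm_bruteforce(a, b), abs=1e-12)


class TestFitPathwayScale:
    def test_identity_distributions(self):
        rng = np.random.default_rng(2)
        x = rng.lognormal(0.5, 0.4, size=300)
        assert gf.fit_pathway_scale(x, x) == pytest.approx(1.0, rel=0.02)

    def test_recovers_planted_compression(self):
        rng = np.random.default_rng(3)
        perk = rng.lognormal(1.0, 0.5, size=500)
        pakt = perk / 2.386
        assert gf.fit_pathway_scale(pakt, perk) == pytest.approx(2.386, rel=0.02)

    def test_grid_excluding_optimum_warns_and_clamps(self):
        rng = np.random.default_rng(4)
        perk = rng.lognormal(1.0, 0.3, size=200)
        pakt = perk / 8.0
        with pytest.warns(RuntimeWarning, match="boundary"):
            alpha = gf.fit_pathway_scale(pakt, perk, grid=np.geomspace(0.5, 2.0, 30))
        assert alpha <= 2.0 + 1e-12
        assert alpha == pytest.approx(2.0, rel=0.05)

    def test_estimator_facade(self):
        rng = np.random.default_rng(5)
        perk = rng.lognormal(1.0, 0.5, size=400)
        est = gf.PathwayScaler().fit(perk / 2.386, perk)
        assert est.alpha_ == pytest.approx(2.386, rel=0.02)
        np.testing.assert_allclose(est.transform([1.0]), [est.alpha_])


class TestPathwayBias:
    @pytest.mark.parametrize("perk,pakt,alpha,expected", [
        (2.0, 2.0, 1.0, 45.0),
        (1.0, 0.0, 1.0, 0.0),
        (0.0, 1.0, 1.0, 90.0),
        (1.0, math.sqrt(3.0), 1.0, 60.0),
        (3.0, 1.0, 3.0, 45.0),
    ])
    def test_analytic_angles(self, perk, pakt, alpha, expected):
        assert gf.pathway_bias(perk, pakt, alpha) == pytest.approx(expected)

    def test_both_zero_undefined(self):
        assert math.isnan(gf.pathway_bias(0.0, 0.0, 1.0))

    @settings(max_examples=200, derandomize=True)
    @given(st.floats(0.001, 100), st.floats(0.001, 100), st.floats(0.01, 100))
    def test_scale_invariance(self, perk, pakt, c):
        a = gf.pathway_bias(perk, pakt, 2.386)
        b = gf.pathway_bias(c * perk, c * pakt, 2.386)
        assert a == pytest.approx(b, abs=1e-9)

    def test_records_on_panel(self, noisy_responses):
        rec = gf.bias_records(noisy_responses, alpha=2.386)
        assert rec["bias_angle"].between(0, 90).all()
        assert (rec["perk_fc"] > 0).all()


class TestCorrelatePanel:
    def test_self_correlation_is_one(self, noisy_panel, noisy_responses):
        # build a predictor that IS the response
        sub = noisy_responses[(noisy_responses["dose"] == 100.0)
                              & (noisy_responses["target"] == "pERK")]
        lig = sub["ligand"].iloc[0]
        vals = sub[sub["ligand"] == lig][["cell_line", "max_fold_change"]]
        basal = vals.rename(columns={"max_fold_change": "value"}).assign(
            analyte="SELF", kind="expression", below_detection=False)
        panel = gf.correlate_panel(noisy_responses, basal, ligands=[lig],
                                   targets=["pERK"])
        row = panel[panel["analyte"] == "SELF"].iloc[0]
        assert row["coefficient"] == pytest.approx(1.0)
        assert row["p_value"] < 1e-10

    def test_constant_predictor_is_missing(self, noisy_panel, noisy_responses):
        basal = noisy_panel.basal.copy()
        basal.loc[basal["analyte"] == "EGFR", "value"] = 1.0
        panel = gf.correlate_panel(noisy_responses, basal,
                                   predictors=[("EGFR", "expression")])
        assert panel["missing"].all()
        assert panel["p_value"].isna().all()

    def test_spearman_matches_scipy(self, noisy_panel, noisy_responses):
        from scipy import stats
        lig = next(iter(noisy_panel.lrmap))
        rec = sorted(noisy_panel.lrmap[lig])[0]
        panel = gf.correlate_panel(noisy_responses, noisy_panel.basal,
                                   method="spearman", ligands=[lig],
                                   targets=["pERK"], predictors=[(rec, "expression")])
        row = panel.iloc[0]
        sub = noisy_responses[(noisy_responses["dose"] == 100.0)
                              & (noisy_responses["target"] == "pERK")
                              & (noisy_responses["ligand"] == lig)]
        b = noisy_panel.basal
        pred = b[(b["analyte"] == rec) & (b["kind"] == "expression")]
        merged = sub.merge(pred, on="cell_line")
        rho, p = stats.spearmanr(merged["value"], merged["max_fold_change"])
        assert row["coefficient"] == pytest.approx(rho)
        assert row["p_value"] == pytest.approx(p)

    def test_absolute_response_variant(self, noisy_panel, noisy_responses):
        panel = gf.correlate_panel(noisy_responses, noisy_panel.basal,
                                   response_value="absolute",
                                   predictors=[("ERBB2", "expression")])
        assert (panel["response_value"] == "absolute").all()
        assert panel["coefficient"].between(-1, 1).all()


class TestCompareGroups:
    def test_identical_groups_near_one(self):
        assert gf.compare_groups([1, 2, 3], [1, 2, 3]) > 0.8

    def test_separated_triplets_exact_p(self):
        # exact two-sided enumeration: 2/C(6,3) = 0.1
        assert gf.compare_groups([1, 2, 3], [10, 11, 12]) == pytest.approx(0.1)

    def test_empty_group_rejected(self):
        with pytest.raises(ValidationError):
            gf.compare_groups([], [1.0])

    def test_planted_subtype_effect_detected(self):
        """HER2-amplified lines carry higher basal ErbB2 than TNBC lines."""
        panel = gf.generate_panel(39, 2, seed=13)
        b = panel.basal
        erbb2 = b[(b["analyte"] == "ERBB2") & (b["kind"] == "expression")]
        merged = erbb2.merge(panel.subtypes, on="cell_line")
        p = gf.compare_groups(
            merged.loc[merged["subtype"] == "HER2amp", "value"],
            merged.loc[merged["subtype"] == "TNBC", "value"])
        assert p < 0.05


class TestResponderEnrichment:
    def test_identical_distributions(self):
        rng = np.random.default_rng(0)
        levels = rng.normal(size=20)
        sig = np.arange(20) % 2 == 0
        res = gf.responder_enrichment(sig, levels)
        assert res.p_value > 0.05
        assert not res.undefined

    def test_separated_levels_minimal_p(self):
        levels = np.array([1, 2, 3, 10, 11, 12], dtype=float)
        sig = levels > 5
        res = gf.responder_enrichment(sig, levels)
        assert res.p_value == pytest.approx(0.1)
        assert res.responder_median == 11

    def test_degenerate_groups_flagged(self):
        all_resp = gf.responder_enrichment([True, True], [1.0, 2.0])
        assert all_resp.undefined
        single = gf.responder_enrichment([True, False, False], [5.0, 1.0, 2.0])
        assert single.low_power and not single.undefined

    def test_responders_have_higher_receptor_levels(self):
        """The generator plants receptor-gated responsiveness; enrichment sees it."""
        panel = gf.generate_panel(39, 15, seed=17)
        responses = gf.compute_fold_changes(panel.cube)
        lig = next(iter(panel.lrmap))
        rec = sorted(panel.lrmap[lig])[0]
        t = panel.truth.classes
        sel = t[(t["ligand"] == lig) & (t["target"] == "pERK")].set_index("cell_line")
        b = panel.basal
        levels = b[(b["analyte"] == rec) & (b["kind"] == "expression")].set_index("cell_line")
        cells = sel.index
        res = gf.responder_enrichment(
            (sel.loc[cells, "kinetic_class"] != "none").to_numpy(),
            levels.loc[cells, "value"].to_numpy())
        assert res.responder_median > res.nonresponder_median
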