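"""Inference layer: complex fractions, group statistics, interaction calls."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st

from patchfrap import (
    ConditionGroup,
    bootstrap_complex_fraction,
    classify_interaction,
    compare_groups,
    complex_fraction,
    groups_from_results,
    ligand_effect,
    p_to_stars,
)

FREE = {"condition": "A+B", "crosslinked": "no", "ligand": "none"}
CL = {"condition": "A+B", "crosslinked": "yes", "ligand": "none"}


def _group(label, rf_mean, d_mean, n, rf_sd=0.0, d_sd=0.0, seed=0):
    rng = np.random.default_rng(seed)
    rf = np.clip(rf_mean + rf_sd * rng.standard_normal(n), 0.0, 1.0)
    d = np.abs(d_mean + d_sd * rng.standard_normal(n))
    return ConditionGroup(label=label, Rf_values=rf, D_values=d)


class TestComplexFraction:
    @pytest.mark.parametrize(
        "free,cl,expected",
        [(64, 39, 39), (62, 42, 32), (52, 36, 31), (56, 34, 39), (56, 18, 68)],
    )
    def test_published_condition_means(self, free, cl, expected):
        # the five free-vs-crosslinked mobile-fraction pairs, to printed rounding
        assert round(complex_fraction(free, cl)) == expected

    def test_no_reduction_gives_zero(self):
        for x in (10.0, 56.0, 99.5):
            assert complex_fraction(x, x) == 0.0

    @settings(derandomize=True, max_examples=50, deadline=None)
    @given(
        free=st.floats(1.0, 100.0),
        ratio=st.floats(0.0, 1.0),
        scale=st.floats(0.01, 10.0),
    )
    def test_scale_invariance(self, free, ratio, scale):
        cl = free * ratio
        assert complex_fraction(scale * free, scale * cl) == pytest.approx(
            complex_fraction(free, cl), abs=1e-9
        )

    def test_mobility_increase_is_an_error(self):
        with pytest.raises(ValueError, match="no mobility reduction"):
            complex_fraction(40.0, 55.0)

    def test_bootstrap_ci_brackets_point_estimate(self):
        rng = np.random.default_rng(1)
        free = np.clip(0.64 + 0.08 * rng.standard_normal(30), 0, 1)
        cl = np.clip(0.39 + 0.06 * rng.standard_normal(30), 0, 1)
        lo, hi = bootstrap_complex_fraction(free, cl, seed=2)
        point = complex_fraction(free.mean(), cl.mean())
        assert lo < point < hi
        assert hi - lo < 40


class TestCompareGroups:
    def test_identical_groups_not_significant(self):
        g1 = _group(FREE, 0.6, 0.03, 10)
        g2 = _group(CL, 0.6, 0.03, 10)
        cmp = compare_groups([g1, g2], "Rf")
        assert cmp.contrasts["p_adj"].iloc[0] == 1.0

    def test_two_group_contrast_uses_t_test(self):
        from scipy import stats

        g1 = _group(FREE, 0.64, 0.025, 12, rf_sd=0.05, seed=1)
        g2 = _group(CL, 0.39, 0.025, 12, rf_sd=0.05, seed=2)
        cmp = compare_groups([g1, g2], "Rf")
        expected = stats.ttest_ind(g1.Rf_values, g2.Rf_values, equal_var=True).pvalue
        assert cmp.contrasts["p_adj"].iloc[0] == pytest.approx(expected, rel=1e-10)

    def test_rejects_tiny_groups(self):
        g1 = _group(FREE, 0.6, 0.03, 1)
        g2 = _group(CL, 0.6, 0.03, 5)
        with pytest.raises(ValueError, match="n < 2"):
            compare_groups([g1, g2], "Rf")

    def test_type_one_error_calibrated(self):
        # two groups drawn from one distribution: ~5% rejections at alpha=0.05
        rng = np.random.default_rng(7)
        rejects = 0
        n_rep = 400
        for _ in range(n_rep):
            a = _group(FREE, 0.6, 0.03, 15, rf_sd=0.08, seed=rng.integers(2**31))
            b = _group(CL, 0.6, 0.03, 15, rf_sd=0.08, seed=rng.integers(2**31))
            cmp = compare_groups([a, b], "Rf")
            rejects += cmp.contrasts["p_adj"].iloc[0] < 0.05
        assert rejects / n_rep == pytest.approx(0.05, abs=0.03)

    def test_bonferroni_familywise_error_conservative(self):
        # three identical groups: family-wise error rate stays below alpha
        rng = np.random.default_rng(8)
        fwe = 0
        n_rep = 300
        labels = [FREE, CL, {"condition": "A+B", "crosslinked": "yes", "ligand": "VEGF-A"}]
        for _ in range(n_rep):
            gs = [_group(lab, 0.6, 0.03, 12, rf_sd=0.08, seed=rng.integers(2**31)) for lab in labels]
            cmp = compare_groups(gs, "Rf")
            fwe += (cmp.contrasts["p_adj"] < 0.05).any()
        assert fwe / n_rep <= 0.07

    def test_star_tiers(self):
        assert p_to_stars(0.2) == "ns"
        assert p_to_stars(0.03) == "*"
        assert p_to_stars(0.004) == "**"
        assert p_to_stars(5e-4) == "***"
        assert p_to_stars(5e-5) == "****"


class TestClassifyInteraction:
    def test_stable_signature(self):
        free = _group(FREE, 0.64, 0.025, 20, rf_sd=0.05, d_sd=0.004, seed=3)
        cl = _group(CL, 0.39, 0.025, 20, rf_sd=0.05, d_sd=0.004, seed=4)
        call = classify_interaction(free, cl)
        assert call.classification == "stable"
        assert call.complex_fraction == pytest.approx(
            complex_fraction(100 * free.Rf_values.mean(), 100 * cl.Rf_values.mean()), abs=1e-9
        )

    def test_transient_signature(self):
        free = _group(FREE, 0.65, 0.030, 20, rf_sd=0.05, d_sd=0.003, seed=5)
        cl = _group(CL, 0.65, 0.018, 20, rf_sd=0.05, d_sd=0.003, seed=6)
        call = classify_interaction(free, cl)
        assert call.classification == "transient"

    def test_mixed_and_none(self):
        free = _group(FREE, 0.64, 0.030, 20, rf_sd=0.04, d_sd=0.003, seed=7)
        both = _group(CL, 0.40, 0.018, 20, rf_sd=0.04, d_sd=0.003, seed=8)
        assert classify_interaction(free, both).classification == "mixed"
        same = _group(CL, 0.64, 0.030, 20, rf_sd=0.04, d_sd=0.003, seed=9)
        call = classify_interaction(free, same)
        assert call.classification == "none"
        assert abs(call.complex_fraction) < 10

    def test_meta_mismatch_rejected(self):
        other = {"condition": "A+C", "crosslinked": "yes", "ligand": "none"}
        free = _group(FREE, 0.6, 0.03, 5, rf_sd=0.02, seed=1)
        cl = _group(other, 0.4, 0.03, 5, rf_sd=0.02, seed=2)
        with pytest.raises(ValueError, match="condition and ligand"):
            classify_interaction(free, cl)
        assert classify_interaction(free, cl, strict=False).classification in (
            "stable", "mixed")

    def test_sparse_d_estimates_still_allow_rf_call(self):
        free = ConditionGroup(FREE, Rf_values=np.linspace(0.6, 0.7, 8), D_values=np.array([0.03]))
        cl = ConditionGroup(CL, Rf_values=np.linspace(0.35, 0.43, 8), D_values=np.array([]))
        call = classify_interaction(free, cl)
        assert call.classification == "stable"
        assert np.isnan(call.p_D)
        assert "too few" in call.notes


class TestLigandEffect:
    @pytest.mark.parametrize("base,plus", [(0.39, 0.26), (0.42, 0.27)])
    def test_published_ligand_effect_sizes_detected(self, base, plus):
        g1 = _group(CL, base, 0.025, 30, rf_sd=0.15 * base, seed=11)
        g2 = _group({**CL, "ligand": "VEGF-A"}, plus, 0.025, 30, rf_sd=0.15 * plus, seed=12)
        cmp = ligand_effect(g1, g2)
        assert cmp.contrasts["p_adj"].iloc[0] < 0.05
        assert cmp.contrasts["mean_b"].iloc[0] < cmp.contrasts["mean_a"].iloc[0]

    def test_null_ligand_not_significant(self):
        g1 = _group(CL, 0.39, 0.025, 30, rf_sd=0.06, seed=13)
        g2 = _group({**CL, "ligand": "BMP9"}, 0.39, 0.025, 30, rf_sd=0.06, seed=14)
        assert ligand_effect(g1, g2).contrasts["p_adj"].iloc[0] >= 0.05


class TestNullCohortPipeline:
    def test_identical_cohorts_rarely_flag_differences(self, quiet_noise):
        # same ground truth in both arms: the full generate -> fit -> compare
        # pipeline should stay silent in >= 9/10 replicate cohorts
        from patchfrap import (BeamProtocol, MobilityParams, fit_curve,
                               generate_cohort, results_to_frame)

        beam = BeamProtocol(w=0.77, K=3.0, t_grid=np.arange(120) * 0.5,
                            n_pre=10, monitor_interval=0.5)
        mob = MobilityParams(D=0.025, R_f=0.64)
        spec = [
            ({"condition": "N", "crosslinked": "no", "ligand": "none"}, mob, 8),
            ({"condition": "N", "crosslinked": "yes", "ligand": "none"}, mob, 8),
        ]
        quiet = 0
        for rep in range(10):
            curves = generate_cohort(spec, beam, quiet_noise, seed=300 + 50 * rep)
            fits = [fit_curve(c, beam) for c in curves]
            groups = groups_from_results(results_to_frame(fits))
            cmp = compare_groups(list(groups.values()), "Rf", alpha=0.05)
            quiet += cmp.contrasts["p_adj"].iloc[0] >= 0.05
        assert quiet >= 9


class TestGroupsFromResults:
    def test_reliability_filter_shrinks_d_counts(self):
        df = pd.DataFrame(
            {
                "condition": ["X"] * 6,
                "crosslinked": ["no"] * 6,
                "ligand": ["none"] * 6,
                "Rf_hat": [0.6, 0.62, 0.58, 0.15, 0.61, 0.59],
                "D_hat_um2_per_s": [0.03, 0.031, 0.029, 0.05, 0.03, 0.028],
                "d_reliable": [True, True, True, False, True, True],
                "converged": [True] * 6,
            }
        )
        g = groups_from_results(df)["X|no|none"]
        assert g.n_Rf == 6
        assert g.n_D == 5
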