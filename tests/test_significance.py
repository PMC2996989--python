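import numpy as np
import pytest

from episens.growth import summarize_replicates
from episens.io import StrainKey, ValidationError
from episens.significance import (
    BootstrapNull,
    assign_environment,
    bootstrap_p_esscore,
    bootstrap_p_fscore,
    bootstrap_p_sscore,
    cv_of_mean,
    esscore_pvalues,
    fscore_pvalues,
    ttest_single_vs_wt,
)
from episens.simulate import E1, E2, sample_null_pair_stats


class TestBootstrapNull:
    def test_variance_formula(self):
        null = BootstrapNull(m0=0.007, cv1=0.02, cv2=0.015, n_trials=10000, seed=0)
        assert null.variance == pytest.approx(0.007**2 * (0.02**2 + 0.015**2))

    def test_minimum_trials(self):
        with pytest.raises(ValidationError):
            BootstrapNull(m0=0.007, cv1=0.02, cv2=0.015, n_trials=100, seed=0)


class TestFScoreBootstrap:
    def test_zero_epsilon_gives_p_one(self):
        res = bootstrap_p_fscore(0.72, 0.02, 0.8, 0.01, 0.9, 0.01, 1.0, 0.01, 0.02, n_trials=2000, seed=1)
        assert res.epsilon_obs == pytest.approx(0.0)
        assert res.p_value == pytest.approx(1.0)

    def test_strong_interaction_hits_addone_floor(self):
        # planted eps = -0.5 with tight CVs: nothing in the null is as extreme
        res = bootstrap_p_fscore(0.36, 0.015, 0.8, 0.007, 0.9, 0.007, 1.0, 0.007, 0.015, n_trials=10000, seed=1)
        assert res.p_value == pytest.approx(1.0 / 10001.0)

    def test_fixed_seed_reproducible(self):
        kw = dict(n_trials=5000, seed=7)
        a = bootstrap_p_fscore(0.70, 0.02, 0.8, 0.01, 0.9, 0.01, 1.0, 0.01, 0.02, **kw)
        b = bootstrap_p_fscore(0.70, 0.02, 0.8, 0.01, 0.9, 0.01, 1.0, 0.01, 0.02, **kw)
        assert a.p_value == b.p_value

    def test_seed_sensitivity_is_monte_carlo_sized(self):
        ps = [
            bootstrap_p_fscore(0.70, 0.02, 0.8, 0.01, 0.9, 0.01, 1.0, 0.01, 0.02, n_trials=20000, seed=s).p_value
            for s in range(5)
        ]
        assert np.std(ps) < 5.0 / np.sqrt(20000)

    def test_fixed_null_mode_runs(self):
        res = bootstrap_p_fscore(
            0.70, 0.02, 0.8, 0.01, 0.9, 0.01, 1.0, 0.01, 0.02,
            n_trials=2000, seed=1, null_mean_mode="fixed",
        )
        assert 0 < res.p_value <= 1

    def test_power_monotone_in_effect_and_noise(self):
        """Rejection rate grows with |planted eps| and shrinks with CV."""
        rng = np.random.default_rng(3)
        power = np.zeros((3, 3))
        for i, eps in enumerate((0.05, 0.12, 0.3)):
            for j, cv in enumerate((0.02, 0.05, 0.08)):
                stats = sample_null_pair_stats(
                    300, replicate_cv=cv, seed=100 + 10 * i + j,
                    eps_true=(eps, eps), two_environments=False,
                )
                piv = {s: stats[stats["strain"] == s].set_index("pair") for s in ("wt", "x", "y", "xy")}
                eo = (
                    piv["xy"]["mean"] * piv["wt"]["mean"] / (piv["x"]["mean"] * piv["y"]["mean"]) - 1
                ).to_numpy()
                cv1 = piv["xy"]["cv_mean"].to_numpy()
                p = fscore_pvalues(eo, cv1, float(np.median(cv1)), 2000, rng)
                power[i, j] = (p < 0.05).mean()
        assert (np.diff(power, axis=0) >= -0.02).all()  # more effect, more power
        assert (np.diff(power, axis=1) <= 0.02).all()  # more noise, less power


class TestSScoreBootstrap:
    def test_degenerate_cvs_zero_epsilon(self):
        res = bootstrap_p_sscore(
            0.72, 0.0, 0.8, 0.0, 0.9, 0.0, 1.0, 0.0,
            0.48, 0.0, 0.72, 0.0, 0.6, 0.0, 0.9, 0.0,
            cv2_e1=0.0, cv2_e2=0.0, n_trials=2000, seed=1,
        )
        assert res.epsilon_obs == pytest.approx(0.0, abs=1e-12)
        assert res.p_value == pytest.approx(1.0)

    def test_modulated_pair_detected(self):
        # eps_fit 0 in E1 and -0.4 in E2 -> eps_sen = 2/3, strongly significant
        res = bootstrap_p_sscore(
            0.72, 0.015, 0.8, 0.007, 0.9, 0.007, 1.0, 0.007,
            0.6 * 0.432, 0.015, 0.72, 0.007, 0.6, 0.007, 1.0, 0.007,
            cv2_e1=0.015, cv2_e2=0.015, n_trials=10000, seed=2,
        )
        assert res.epsilon_obs == pytest.approx(1 / 0.6 - 1, rel=1e-6)
        assert res.p_value < 0.01


class TestESScoreBootstrap:
    def test_wt_equal_sensitivity_not_significant(self):
        res = bootstrap_p_esscore(0.8, 0.005, 0.64, 0.005, 1.0, 0.005, 0.8, 0.005, n_trials=2000, seed=3)
        assert res.epsilon_obs == pytest.approx(0.0)
        assert res.p_value == pytest.approx(1.0)

    def test_planted_sensitivity_effect_detected(self):
        """S(X) = 1.5 S(wt) is flagged in >= 90% of simulated datasets."""
        rng = np.random.default_rng(4)
        n_sets, cv, n_rep = 200, 0.03, 19
        hits = 0
        for k in range(n_sets):
            draws = {}
            for name, true in (("x1", 0.9), ("x2", 0.9 * 0.8 / 1.5), ("w1", 1.0), ("w2", 0.8)):
                r = true * (1 + rng.normal(0, cv, n_rep))
                draws[name] = (r.mean(), r.std(ddof=1) / r.mean() / np.sqrt(n_rep))
            res = bootstrap_p_esscore(
                draws["x1"][0], draws["x1"][1], draws["x2"][0], draws["x2"][1],
                draws["w1"][0], draws["w1"][1], draws["w2"][0], draws["w2"][1],
                n_trials=2000, seed=k,
            )
            hits += res.p_value < 0.05
        assert hits / n_sets >= 0.9


class TestTTest:
    def test_identical_sets_p_one(self):
        a = summarize_replicates([0.01, 0.011, 0.009], StrainKey.single("A"), "E1")
        assert ttest_single_vs_wt(a, a) == pytest.approx(1.0)

    def test_large_shift_significant(self):
        rng = np.random.default_rng(0)
        wt = 0.0077 * (1 + rng.normal(0, 0.02, 19))
        mut = wt.mean() - 5 * wt.std(ddof=1) + 0.0077 * rng.normal(0, 0.0002, 19)
        p = ttest_single_vs_wt(
            summarize_replicates(mut, StrainKey.single("A"), "E1"),
            summarize_replicates(wt, StrainKey.wildtype(), "E1"),
        )
        assert p < 1e-6

    def test_summary_path_equals_replicate_path(self):
        rng = np.random.default_rng(1)
        a = list(0.007 * (1 + rng.normal(0, 0.05, 10)))
        b = list(0.0077 * (1 + rng.normal(0, 0.05, 12)))
        ra = summarize_replicates(a, StrainKey.single("A"), "E1")
        rb = summarize_replicates(b, StrainKey.wildtype(), "E1")
        p_rep = ttest_single_vs_wt(ra, rb)
        p_sum = ttest_single_vs_wt(
            (ra.mean, ra.cv * ra.mean, ra.n), (rb.mean, rb.cv * rb.mean, rb.n)
        )
        assert p_rep == pytest.approx(p_sum, rel=1e-12)

    def test_single_replicate_rejected(self):
        a = summarize_replicates([0.01], StrainKey.single("A"), "E1")
        b = summarize_replicates([0.01, 0.011], StrainKey.wildtype(), "E1")
        with pytest.raises(ValidationError):
            ttest_single_vs_wt(a, b)


class TestAssignEnvironment:
    @pytest.mark.parametrize(
        "p1,p2,expected",
        [
            (0.005, 0.5, "E1-only"),
            (0.5, 0.005, "E2-only"),
            (0.005, 0.005, "both"),
            (0.5, 0.5, "none"),
        ],
    )
    def test_four_way_rule(self, p1, p2, expected):
        assert assign_environment(p1, p2, alpha=0.01) == expected

    def test_p_outside_unit_interval_rejected(self):
        with pytest.raises(ValidationError):
            assign_environment(-0.1, 0.5)


def test_cv_of_mean():
    assert cv_of_mean(0.03, 9) == pytest.approx(0.01)
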