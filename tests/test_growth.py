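import math

import numpy as np
import pytest

from episens.growth import (
    FitWindow,
    GrowthCurve,
    estimate_single_from_doubles,
    fit_growth_rate,
    fit_od_table,
    summarize_replicates,
)
from episens.io import PhenotypeTable, StrainKey, StrainPhenotype, ValidationError
from episens.simulate import generate_od_curves


def _curve(rate=0.0077, od0=0.05, step=15.0, end=600.0, strain=None):
    t = np.arange(0.0, end + step / 2, step)
    return GrowthCurve(
        strain=strain or StrainKey.single("A"),
        environment="E1",
        replicate_id=1,
        times=t,
        od=od0 * np.exp(rate * t),
    )


class TestFitGrowthRate:
    def test_noiseless_exponential_recovered_exactly(self):
        res = fit_growth_rate(_curve(rate=0.0077))
        assert not res.rejected
        assert res.rate == pytest.approx(0.0077, abs=1e-9)

    def test_doubling_time_identity(self):
        # OD doubling every 90 minutes corresponds to rate ln(2)/90
        t = np.arange(0.0, 600.1, 15.0)
        curve = GrowthCurve(StrainKey.single("A"), "E1", 1, t, 0.05 * 2 ** (t / 90.0))
        res = fit_growth_rate(curve)
        assert res.rate == pytest.approx(math.log(2) / 90.0, abs=1e-9)

    def test_too_few_window_points_is_rejection_not_error(self):
        res = fit_growth_rate(_curve(step=60.0), FitWindow(min_points=10))
        assert res.rejected
        assert "10" in res.reason

    def test_window_is_conjunctive(self):
        # points with OD in range but outside the time bounds are dropped
        res = fit_growth_rate(_curve(rate=0.02, od0=0.11, step=5.0, end=30.0))
        assert res.rejected

    def test_nonpositive_od_excluded_before_log(self):
        t = np.arange(60.0, 361.0, 15.0)
        od = 0.2 * np.ones_like(t)
        od[:15] = 0.0
        curve = GrowthCurve(StrainKey.single("A"), "E1", 1, t, od)
        res = fit_growth_rate(curve, FitWindow(min_points=10))
        assert res.rejected

    def test_low_r2_flagged_not_rejected(self, rng):
        t = np.arange(60.0, 361.0, 15.0)
        od = rng.uniform(0.1, 0.4, size=t.size)
        res = fit_growth_rate(GrowthCurve(StrainKey.single("A"), "E1", 1, t, od))
        assert not res.rejected
        assert res.low_r2


class TestGrowthCurveValidation:
    def test_needs_two_points(self):
        with pytest.raises(ValidationError):
            GrowthCurve(StrainKey.wildtype(), "E1", 1, np.array([0.0]), np.array([0.1]))

    def test_times_strictly_increasing(self):
        with pytest.raises(ValidationError):
            GrowthCurve(StrainKey.wildtype(), "E1", 1, np.array([0.0, 0.0]), np.array([0.1, 0.1]))


class TestSummarizeReplicates:
    def test_constant_rates(self):
        s = summarize_replicates([0.01, 0.01, 0.01], StrainKey.single("A"), "E1")
        assert (s.mean, s.cv, s.n) == (pytest.approx(0.01), pytest.approx(0.0), 3)

    def test_two_replicates_hand_arithmetic(self):
        s = summarize_replicates([0.009, 0.011], StrainKey.single("A"), "E1")
        assert s.mean == pytest.approx(0.010)
        assert s.cv == pytest.approx(np.std([0.009, 0.011], ddof=1) / 0.010)

    def test_empty_rejected(self):
        with pytest.raises(ValidationError):
            summarize_replicates([], StrainKey.single("A"), "E1")

    def test_single_replicate_cv_unestimable(self):
        s = summarize_replicates([0.01], StrainKey.single("A"), "E1")
        assert s.cv is None and s.cv_unestimable


def _panel(mu_overrides=None):
    """Epistasis-free partner panel for gene X: every partner implies 0.8."""
    partners = {"YA": (0.9, 0.72), "YB": (0.8, 0.64), "YC": (1.0, 0.80)}
    if mu_overrides:
        partners.update(mu_overrides)
    singles = PhenotypeTable.from_records(
        [(StrainKey.single(g), "E1", m_single, 0.02, 19) for g, (m_single, _) in partners.items()]
    )
    doubles = PhenotypeTable.from_records(
        [(StrainKey.double("X", g), "E1", m_double, 0.05, 4) for g, (_, m_double) in partners.items()]
    )
    wt = StrainPhenotype(StrainKey.wildtype(), "E1", 1.0, 0.02, 19)
    return doubles, singles, wt


class TestEstimateSingleFromDoubles:
    def test_epistasis_free_panel(self):
        doubles, singles, wt = _panel()
        est = estimate_single_from_doubles("X", doubles, singles, wt, "E1")
        assert est.estimate == pytest.approx(0.8)
        assert est.n_partners == 3
        np.testing.assert_allclose(sorted(est.mu_values), [0.8, 0.8, 0.8])

    def test_median_robust_to_outlier(self):
        doubles, singles, wt = _panel({"YD": (1.0, 1.2)})  # mu = 1.2 outlier
        est = estimate_single_from_doubles("X", doubles, singles, wt, "E1")
        assert est.estimate == pytest.approx(0.8)

    def test_partner_order_invariance(self):
        doubles, singles, wt = _panel()
        rev_doubles = PhenotypeTable(doubles.frame.iloc[::-1].reset_index(drop=True))
        a = estimate_single_from_doubles("X", doubles, singles, wt, "E1")
        b = estimate_single_from_doubles("X", rev_doubles, singles, wt, "E1")
        assert a.estimate == b.estimate

    def test_deviation_flag_beyond_5_percent(self):
        doubles, singles, wt = _panel()
        singles_with_x = PhenotypeTable(
            PhenotypeTable.from_records(
                [(StrainKey.single("X"), "E1", 0.7, 0.02, 19)]
            ).frame.pipe(lambda f: __import__("pandas").concat([f, singles.frame], ignore_index=True))
        )
        est = estimate_single_from_doubles("X", doubles, singles_with_x, wt, "E1")
        assert est.deviates  # 0.8 vs 0.7 measured: > 5% deviation

    def test_zero_partners_rejected(self):
        doubles, singles, wt = _panel()
        with pytest.raises(ValidationError):
            estimate_single_from_doubles("Z", doubles, singles, wt, "E1")

    def test_partner_without_single_rate_skipped(self):
        doubles, singles, wt = _panel()
        import pandas as pd

        extra = PhenotypeTable.from_records([(StrainKey.double("X", "YE"), "E1", 0.5, 0.05, 4)])
        doubles = PhenotypeTable(pd.concat([doubles.frame, extra.frame], ignore_index=True))
        est = estimate_single_from_doubles("X", doubles, singles, wt, "E1")
        assert est.n_partners == 3
        assert est.skipped_partners == ["YE"]


class TestNoisePropagation:
    def test_fitted_rate_scatter_scales_with_od_noise(self):
        """Across-replicate CV of fitted rates grows with the OD noise level."""
        table = PhenotypeTable.from_records([(StrainKey.wildtype(), "E1", 0.0077, 0.0, 20)])
        spread = {}
        for sigma in (0.01, 0.05):
            curves = generate_od_curves(table, od0=0.05, od_noise_cv=sigma, seed=9)
            rates = [fit_growth_rate(c).rate for c in curves]
            spread[sigma] = np.std(rates, ddof=1) / np.mean(rates)
        assert spread[0.05] > spread[0.01]

    def test_fit_od_table_round_trip(self):
        table = PhenotypeTable.from_records(
            [
                (StrainKey.wildtype(), "E1", 0.0077, 0.0, 3),
                (StrainKey.single("A"), "E1", 0.0062, 0.0, 3),
            ]
        )
        curves = generate_od_curves(table, od_noise_cv=0.0)
        fitted, rejected = fit_od_table(curves)
        assert not rejected
        assert fitted.get(StrainKey.wildtype(), "E1").mean_rate == pytest.approx(0.0077, abs=1e-9)
        assert fitted.get(StrainKey.single("A"), "E1").mean_rate == pytest.approx(0.0062, abs=1e-9)
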