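"""Confidence ellipse, death-time law, cohort summaries, bleb statistics."""

import numpy as np
import pandas as pd
import pytest

from neurostrain import (
    CHI2_2_95,
    DeathTimeModel,
    InjuryRecord,
    StrainDeathModel,
    bivariate_density_grid,
    cohort_summary,
    confidence_ellipse,
    major_axis_relation,
    predict_death_time,
    scaled_inverse_cdf,
    welch_ttest,
)
from neurostrain.injury import DeathTimeRelation

SQRT_CHI2 = np.sqrt(CHI2_2_95)


class TestConfidenceEllipse:
    def test_identity_covariance_circular(self):
        e = confidence_ellipse((np.zeros(2), np.eye(2)))
        l1, l2 = e.axis_lengths()
        assert l1 == pytest.approx(SQRT_CHI2)  # ≈ 2.4477
        assert l2 == pytest.approx(SQRT_CHI2)
        assert e.eccentricity == pytest.approx(0.0, abs=1e-9)

    def test_diagonal_covariance_axis_lengths(self):
        e = confidence_ellipse((np.zeros(2), np.diag([4.0, 1.0])))
        l1, l2 = e.axis_lengths()
        assert l1 == pytest.approx(2 * SQRT_CHI2)
        assert l2 == pytest.approx(SQRT_CHI2)
        # major axis along the first coordinate
        assert abs(e.a1[0]) == pytest.approx(l1)
        assert abs(e.a1[1]) == pytest.approx(0.0, abs=1e-12)

    def test_eccentricity_from_two_to_one_axis_ratio(self):
        # eigenvalue ratio 4 gives |a1| = 2|a2| and e = sqrt(3)/2
        e = confidence_ellipse((np.zeros(2), np.diag([4.0, 1.0])))
        assert e.eccentricity == pytest.approx(np.sqrt(3) / 2)

    def test_axes_orthogonal_and_ordered(self, rng):
        A = rng.normal(size=(2, 2))
        cov = A @ A.T + 0.1 * np.eye(2)
        e = confidence_ellipse((rng.normal(size=2), cov))
        assert abs(e.a1 @ e.a2) < 1e-9
        assert np.linalg.norm(e.a1) >= np.linalg.norm(e.a2)

    def test_coverage_of_fitted_normal(self):
        # 95% ellipse should contain ~95% of draws from the same normal
        rng = np.random.default_rng(42)
        mu = np.array([0.107, 9.67])
        cov = np.array([[7.4e-4, -4.3e-2], [-4.3e-2, 2.6]])
        e = confidence_ellipse((mu, cov), level=0.95)
        draws = rng.multivariate_normal(mu, cov, size=100_000)
        frac = np.mean(e.contains(draws))
        assert frac == pytest.approx(0.95, abs=0.01)

    def test_non_pd_covariance_rejected(self):
        with pytest.raises(ValueError):
            confidence_ellipse((np.zeros(2), np.diag([1.0, 0.0])))


class TestMajorAxisRelation:
    def test_printed_ellipse_parameters_recover_printed_law(self):
        # centroid (0.107, 9.67), major half-axis (0.065, 3.94):
        # slope 3.94/0.065 ≈ 60.6 and intercept ≈ 0.267, consistent with the
        # published t_d = 62.5(0.265 − <Ec>) to within its internal rounding
        mu, cov = DeathTimeModel().mean_cov()
        rel = major_axis_relation(confidence_ellipse((mu, cov)))
        assert rel.slope_mag == pytest.approx(3.94 / 0.065, rel=1e-6)
        assert rel.slope_mag == pytest.approx(62.5, rel=0.04)
        assert rel.strain_intercept == pytest.approx(0.107 + 9.67 / (3.94 / 0.065), rel=1e-6)
        assert rel.strain_intercept == pytest.approx(0.265, rel=0.01)

    def test_major_axis_along_strain_only_is_degenerate(self):
        cov = np.diag([1e-4, 4.0])  # major axis parallel to the time axis
        with pytest.raises(ValueError):
            major_axis_relation(confidence_ellipse((np.zeros(2), cov)))

    def test_invariant_to_axis_sign_flip(self):
        mu, cov = DeathTimeModel().mean_cov()
        e = confidence_ellipse((mu, cov))
        flipped = type(e)(
            centroid=e.centroid, a1=-e.a1, a2=e.a2, level=e.level,
            eccentricity=e.eccentricity,
            eccentricity_standardized=e.eccentricity_standardized,
        )
        r1 = major_axis_relation(e)
        r2 = major_axis_relation(flipped)
        assert r1.slope_mag == pytest.approx(r2.slope_mag)
        assert r1.strain_intercept == pytest.approx(r2.strain_intercept)


class TestPredictDeathTime:
    printed = DeathTimeRelation(slope_mag=62.5, strain_intercept=0.265)

    def test_seven_percent_strain_predicts_about_12_hours(self):
        t = predict_death_time(self.printed, 0.07)
        assert t == pytest.approx(12.1875)
        assert round(t) == 12

    def test_intercept_predicts_zero(self):
        assert predict_death_time(self.printed, 0.265) == pytest.approx(0.0, abs=1e-12)

    def test_centroid_strain_value(self):
        assert predict_death_time(self.printed, 0.107) == pytest.approx(9.875)

    def test_beyond_intercept_clamped_with_warning(self):
        with pytest.warns(UserWarning):
            t = predict_death_time(self.printed, 0.4)
        assert t == 0.0


class TestBivariateDensityGrid:
    def test_grid_integrates_to_one(self):
        mu, cov = DeathTimeModel().mean_cov()
        x, y, dens = bivariate_density_grid((mu, cov), resolution=400)
        integral = np.trapezoid(np.trapezoid(dens, y, axis=1), x)
        assert integral == pytest.approx(1.0, abs=0.01)

    def test_density_peaks_at_centroid(self):
        mu, cov = DeathTimeModel().mean_cov()
        x, y, dens = bivariate_density_grid((mu, cov), resolution=201)
        i, j = np.unravel_index(np.argmax(dens), dens.shape)
        assert x[i] == pytest.approx(mu[0], abs=(x[1] - x[0]))
        assert y[j] == pytest.approx(mu[1], abs=(y[1] - y[0]))


class TestScaledInverseCdf:
    def test_two_point_step_curve(self):
        out = scaled_inverse_cdf(np.array([0.1, 0.2]), scale=1.0)
        curve = out["curve"]
        assert curve["probability"].tolist() == [1.0, 0.5]
        assert curve["strain"].tolist() == [0.1, 0.2]

    def test_scale_multiplies_probabilities(self):
        full = scaled_inverse_cdf(np.array([0.1, 0.2, 0.3]), scale=1.0)["curve"]
        scaled = scaled_inverse_cdf(np.array([0.1, 0.2, 0.3]), scale=0.64)["curve"]
        assert np.allclose(scaled["probability"], 0.64 * full["probability"])

    def test_histogram_fractions_sum_to_one(self, rng):
        out = scaled_inverse_cdf(rng.lognormal(size=200), scale=0.64)
        assert out["histogram"]["fraction"].sum() == pytest.approx(1.0)

    def test_empty_input_rejected(self):
        with pytest.raises(ValueError):
            scaled_inverse_cdf(np.array([]))


def _records():
    recs = []
    # higher-rate group: 10 dead cells, 6 with blebs; lower: 10 dead, 4 blebs
    for i in range(10):
        recs.append(
            InjuryRecord(f"hi{i}", "75 s^-1", 0.1, 0.05, death_time_hr=9.0,
                         bleb_formed=i < 6)
        )
        recs.append(
            InjuryRecord(f"lo{i}", "10 s^-1", 0.1, 0.05, death_time_hr=10.0,
                         bleb_formed=i < 4)
        )
    return recs


class TestCohortSummary:
    def test_printed_bleb_percentages_give_1p7_fold(self):
        # 64% vs 37% bleb prevalence among dead cells
        recs = []
        for i in range(100):
            recs.append(
                InjuryRecord(f"a{i}", "75 s^-1", 0.1, 0.0, death_time_hr=9.0,
                             bleb_formed=i < 64)
            )
            recs.append(
                InjuryRecord(f"b{i}", "10 s^-1", 0.1, 0.0, death_time_hr=9.0,
                             bleb_formed=i < 37)
            )
        out = cohort_summary(recs, 1.0, fold_change_groups=("75 s^-1", "10 s^-1"))
        assert out.bleb_fold_change == 1.7

    def test_all_dead_full_viability_is_100_percent(self):
        recs = [
            InjuryRecord(f"c{i}", "10 s^-1", 0.1, 0.0, death_time_hr=5.0)
            for i in range(10)
        ]
        out = cohort_summary(recs, 1.0)
        assert out.table.loc["10 s^-1", "pct_death"] == 100.0

    def test_viability_normalisation(self):
        recs = _records() + [
            InjuryRecord(f"s{i}", "75 s^-1", 0.05, 0.0) for i in range(10)
        ]
        out = cohort_summary(recs, {"75 s^-1": 0.8, "10 s^-1": 1.0})
        # 10 dead of 20 cells, normalized by 0.8 viability
        assert out.table.loc["75 s^-1", "pct_death"] == pytest.approx(62.5)

    def test_zero_viability_rejected(self):
        with pytest.raises(ValueError):
            cohort_summary(_records(), 0.0)

    def test_permutation_invariant(self, rng):
        recs = _records()
        shuffled = list(recs)
        rng.shuffle(shuffled)
        a = cohort_summary(recs, 1.0).table.sort_index()
        b = cohort_summary(shuffled, 1.0).table.sort_index()
        pd.testing.assert_frame_equal(a, b)


class TestWelchTTest:
    def test_identical_samples(self):
        t, p = welch_ttest([1, 2, 3, 4], [1, 2, 3, 4])
        assert t == pytest.approx(0.0)
        assert p == pytest.approx(1.0)

    def test_matches_direct_formula(self):
        a = np.array([1.0, 2, 3, 4, 5])
        b = np.array([2.0, 3, 4, 5, 6])
        t, p = welch_ttest(a, b)
        # brute-force Welch formula
        va, vb = a.var(ddof=1) / len(a), b.var(ddof=1) / len(b)
        t_ref = (a.mean() - b.mean()) / np.sqrt(va + vb)
        df = (va + vb) ** 2 / (va**2 / (len(a) - 1) + vb**2 / (len(b) - 1))
        from scipy import stats

        p_ref = 2 * stats.t.sf(abs(t_ref), df)
        assert t == pytest.approx(t_ref)
        assert p == pytest.approx(p_ref)

    def test_null_p_values_uniform(self):
        ps = []
        for k in range(200):
            rng = np.random.default_rng(k)
            _, p = welch_ttest(rng.normal(size=400), rng.normal(size=400))
            ps.append(p)
        from scipy import stats

        assert stats.kstest(ps, "uniform").pvalue > 0.01

    def test_degenerate_equal_constants(self):
        t, p = welch_ttest([3.0, 3.0], [3.0, 3.0])
        assert (t, p) == (0.0, 1.0)


class TestStrainDeathModel:
    def test_from_dataframe_drops_survivors(self):
        df = pd.DataFrame(
            {"mean_Ec": [0.1, 0.2, 0.15], "death_time_hr": [10.0, np.nan, 8.0]}
        )
        model = StrainDeathModel.from_dataframe(df)
        assert model.nobs == 2

    def test_fit_recovers_generating_ellipse(self):
        dm = DeathTimeModel()
        pairs = dm.sample(3000, np.random.default_rng(3))
        res = StrainDeathModel(pairs[:, 0], pairs[:, 1]).fit(seed=3)
        slope_true, intercept_true = dm.major_axis_line()
        assert res.slope_mag == pytest.approx(slope_true, rel=0.08)
        assert res.centroid_time_hr == pytest.approx(9.67, rel=0.03)
        assert res.strain_intercept == pytest.approx(intercept_true, rel=0.05)
        assert 0.90 <= res.inlier_fraction() <= 0.99

    def test_summary_and_report_roundtrip(self):
        dm = DeathTimeModel()
        pairs = dm.sample(200, np.random.default_rng(4))
        res = StrainDeathModel(pairs[:, 0], pairs[:, 1]).fit(seed=4)
        text = res.summary()
        assert "slope" in text and "intercept" in text
        d = res.to_dict()
        assert set(d) >= {
            "centroid", "covariance", "slope_hr_per_strain", "strain_intercept",
            "h", "seed", "eccentricity",
        }

    def test_plot_smoke(self):
        import matplotlib

        matplotlib.use("Agg")
        dm = DeathTimeModel()
        pairs = dm.sample(100, np.random.default_rng(5))
        res = StrainDeathModel(pairs[:, 0], pairs[:, 1]).fit(seed=5)
        ax = res.plot(show_density=True)
        assert ax is not None
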