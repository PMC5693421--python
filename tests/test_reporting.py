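"""Agreement statistics and regression machinery."""

import numpy as np
import pytest

import nucleomorph as nm
from nucleomorph.classifier import ClassificationResult
from nucleomorph.features import ShapeFeatures


class TestPercentAgreement:
    def test_identical_vectors(self):
        v = ["normal", "dysmorphic"] * 25
        assert nm.percent_agreement(v, v) == 100.0

    def test_complementary_vectors(self):
        a = ["normal"] * 10
        b = ["dysmorphic"] * 10
        assert nm.percent_agreement(a, b) == 0.0

    def test_nine_of_ten(self):
        a = ["normal"] * 10
        b = ["normal"] * 9 + ["dysmorphic"]
        assert nm.percent_agreement(a, b) == 90.0

    def test_length_mismatch_rejected(self):
        with pytest.raises(ValueError, match="length"):
            nm.percent_agreement(["normal"], ["normal", "normal"])

    def test_symmetric(self):
        rng = np.random.default_rng(4)
        a, b = rng.integers(0, 2, 50), rng.integers(0, 2, 50)
        assert nm.percent_agreement(a, b) == nm.percent_agreement(b, a)


class TestCohensKappa:
    def test_perfect_agreement_both_classes(self):
        v = ["normal", "dysmorphic"] * 25
        assert nm.cohens_kappa(v, v) == 1.0

    def test_known_confusion_table(self):
        # [[45, 5], [5, 45]]: p_o = 0.90, p_e = 0.50, kappa = 0.80
        a = [0] * 50 + [1] * 50
        b = [0] * 45 + [1] * 5 + [0] * 5 + [1] * 45
        assert nm.cohens_kappa(a, b) == pytest.approx(0.80)

    def test_independent_raters_near_zero(self):
        rng = np.random.default_rng(0)
        a, b = rng.integers(0, 2, 10_000), rng.integers(0, 2, 10_000)
        assert abs(nm.cohens_kappa(a, b)) < 0.05

    def test_matches_sklearn_on_random_vectors(self):
        from sklearn.metrics import cohen_kappa_score

        rng = np.random.default_rng(8)
        for _ in range(10):
            a = rng.integers(0, 2, 200)
            b = np.where(rng.random(200) < 0.3, 1 - a, a)
            assert nm.cohens_kappa(a, b) == pytest.approx(cohen_kappa_score(a, b))

    def test_symmetric(self):
        rng = np.random.default_rng(5)
        a, b = rng.integers(0, 2, 100), rng.integers(0, 2, 100)
        assert nm.cohens_kappa(a, b) == pytest.approx(nm.cohens_kappa(b, a))

    def test_constant_identical_raters_convention(self):
        assert nm.cohens_kappa(["normal"] * 10, ["normal"] * 10) == 1.0

    def test_kappa_one_iff_full_agreement_with_both_classes(self):
        v = ["normal", "dysmorphic"] * 10
        assert nm.cohens_kappa(v, v) == 1.0
        w = list(v)
        w[0] = "dysmorphic"
        assert nm.cohens_kappa(v, w) < 1.0


def _call(label, nid=0):
    return ClassificationResult(nid, label, 4 if label == "normal" else 3, (0, 0, 0))


def _feat(area=100.0, ecc=0.5, mnc=0.1):
    return ShapeFeatures(area_a=area, hull_area_h=area, rc=0.0, mnc=mnc,
                         nc_max=mnc, eccentricity=ecc, orientation=0.0,
                         centroid=(0.0, 0.0))


class TestSummarizeSample:
    def test_percent_dysmorphic(self):
        calls = [_call("dysmorphic", i) for i in range(3)] + [
            _call("normal", i) for i in range(3, 10)
        ]
        feats = [_feat() for _ in range(10)]
        s = nm.summarize_sample(calls, feats, "s1")
        assert s.percent_dysmorphic == 30.0
        assert s.n_dysmorphic == 3 and s.n_nuclei == 10

    def test_all_normal_dysmorphic_stats_undefined(self):
        calls = [_call("normal", i) for i in range(5)]
        feats = [_feat() for _ in range(5)]
        s = nm.summarize_sample(calls, feats, "s2")
        assert not s.dysmorphic_stats_defined
        assert np.isnan(s.mean_area_dysmorphic)

    def test_matches_direct_counting(self):
        rng = np.random.default_rng(12)
        labels = ["dysmorphic" if x else "normal" for x in rng.integers(0, 2, 40)]
        areas = rng.uniform(50, 150, 40)
        calls = [_call(l, i) for i, l in enumerate(labels)]
        feats = [_feat(area=a) for a in areas]
        s = nm.summarize_sample(calls, feats, "s3")
        mask = np.array(labels) == "dysmorphic"
        assert s.n_dysmorphic == mask.sum()
        assert s.mean_area_dysmorphic == pytest.approx(areas[mask].mean())

    def test_empty_sample_not_an_error(self):
        s = nm.summarize_sample([], [], "empty")
        assert s.n_nuclei == 0 and np.isnan(s.percent_dysmorphic)


class TestAgeTrendRegression:
    def test_collinear_points_perfect_fit(self):
        fit = nm.fit_age_trend([(20, 11), (30, 14), (40, 17), (50, 20)])
        assert fit.r_squared == pytest.approx(1.0)
        assert fit.residual_se == pytest.approx(0.0, abs=1e-10)
        assert fit.slope == pytest.approx(0.3)

    def test_prediction_interval_contains_confidence_interval(self):
        rng = np.random.default_rng(2)
        ages = rng.uniform(20, 70, 30)
        pct = 0.3 * ages + 5 + rng.normal(0, 2, 30)
        fit = nm.fit_age_trend(np.column_stack([ages, pct]))
        bands = fit.predict(np.linspace(10, 80, 15))
        assert (bands.pi_lower <= bands.ci_lower).all()
        assert (bands.pi_upper >= bands.ci_upper).all()

    def test_slope_ci_coverage(self):
        """95% CI covers the true slope in 93-97% of simulated replicates."""
        hits = 0
        n_rep = 500
        for i in range(n_rep):
            rng = np.random.default_rng(1000 + i)
            ages = rng.uniform(20, 70, 50)
            pct = 0.3 * ages + 5 + rng.normal(0, 2, 50)
            lo, hi = nm.fit_age_trend(np.column_stack([ages, pct])).slope_confint()
            hits += lo <= 0.3 <= hi
        assert 0.93 <= hits / n_rep <= 0.97

    def test_degenerate_design_rejected(self):
        with pytest.raises(ValueError, match="degenerate|predictor"):
            nm.fit_age_trend([(40, 1), (40, 2), (40, 3)])


@pytest.fixture(scope="module")
def line_fit():
    return nm.fit_age_trend([(0, 5), (20, 11), (40, 17), (60, 23)])  # y = 0.3x + 5


class TestDeviationFromTrend:

    def test_on_line_zero(self, line_fit):
        assert nm.deviation_from_trend(line_fit, (30, 14)) == pytest.approx(0.0)

    def test_stated_arithmetic(self, line_fit):
        assert nm.deviation_from_trend(line_fit, (40, 20)) == pytest.approx(3.0)

    def test_antisymmetric_about_line(self, line_fit):
        up = nm.deviation_from_trend(line_fit, (50, 25))
        down = nm.deviation_from_trend(line_fit, (50, 2 * line_fit.predict_mean(50) - 25))
        assert up == pytest.approx(-down)


class TestOnsetRegression:
    def test_collinear(self):
        fit = nm.onset_regression([(-5, 60), (0, 45), (5, 30), (10, 15)])
        assert fit.r_squared == pytest.approx(1.0)
        assert fit.slope == pytest.approx(-3.0)

    def test_shared_machinery_with_age_trend(self):
        pts = [(1.0, 2.0), (2.0, 3.5), (3.0, 3.0), (4.0, 5.0)]
        a = nm.onset_regression(pts)
        b = nm.fit_age_trend(pts)
        assert a.slope == b.slope and a.r_squared == b.r_squared

    def test_negative_slope_sign_recovery(self):
        """At |slope|/sigma = 3 the fitted slope sign is right >= 95% of seeds."""
        hits = 0
        n_rep = 400
        for i in range(n_rep):
            rng = np.random.default_rng(5000 + i)
            dev = rng.uniform(-5, 10, 12)
            onset = 45 - 3.0 * dev + rng.normal(0, 1.0, 12) / 1.0
            fit = nm.onset_regression(np.column_stack([dev, onset]))
            hits += fit.slope < 0
        assert hits / n_rep >= 0.95
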