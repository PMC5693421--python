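"""Three-limit training and 4-step classification, checked against oracles."""

import itertools

import numpy as np
import pytest

import nucleomorph as nm
from nucleomorph.classifier import (
    FEATURE_NAMES,
    ClassificationResult,
    FeatureLimits,
    LabeledNucleus,
    ModelError,
    best_intermediate,
    classify,
    fit_limits,
    load_model,
    save_model,
)
from nucleomorph.features import ShapeFeatures


def make_features(rc, mnc, nc_max) -> ShapeFeatures:
    return ShapeFeatures(
        area_a=1000.0, hull_area_h=1000.0 / (1 - rc) if rc < 1 else 1000.0,
        rc=rc, mnc=mnc, nc_max=nc_max,
        eccentricity=0.5, orientation=0.0, centroid=(0.0, 0.0),
    )


def labeled(rc, mnc, nc_max, label) -> LabeledNucleus:
    return LabeledNucleus(make_features(rc, mnc, nc_max), label)


EXAMPLE_LIMITS = FeatureLimits({
    "rc": (0.01, 0.02, 0.05),
    "mnc": (0.5, 1.0, 2.0),
    "nc_max": (1.0, 2.0, 4.0),
})


class TestFitLimits:
    def test_min_max_rules_on_toy_set(self):
        training = [
            labeled(0.01, 1.0, 1.0, "normal"),
            labeled(0.02, 1.0, 1.0, "normal"),
            labeled(0.015, 1.0, 1.0, "dysmorphic"),
            labeled(0.05, 1.0, 1.0, "dysmorphic"),
        ]
        limits = fit_limits(training)
        lo, mid, hi = limits.limits["rc"]
        assert lo == 0.015 and hi == 0.02
        assert lo <= mid <= hi
        # optimal misclassification count is 1, and the clamped intermediate
        # achieves it under strict comparisons (dys value at t is not < t)
        rc_norm = np.array([0.01, 0.02])
        rc_dys = np.array([0.015, 0.05])
        _, cost = best_intermediate(rc_norm, rc_dys)
        assert cost == 1
        assert (rc_dys < mid).sum() + (rc_norm > mid).sum() == 1

    def test_intermediate_matches_exhaustive_scan(self):
        rng = np.random.default_rng(17)
        for _ in range(20):
            n, d = rng.integers(3, 30), rng.integers(3, 30)
            norm = rng.normal(0.3, 0.15, n).clip(0)
            dys = rng.normal(0.7, 0.2, d).clip(0)
            t_star, cost_star = best_intermediate(norm, dys)
            # exhaustive scan over a dense grid must not beat the optimum
            grid = np.linspace(-0.5, 2.0, 20001)
            costs = [(dys < t).sum() + (norm > t).sum() for t in grid]
            assert cost_star == min(costs)
            assert (dys < t_star).sum() + (norm > t_star).sum() == cost_star

    def test_separated_classes_cost_zero(self):
        norm = np.array([0.1, 0.2, 0.3])
        dys = np.array([0.5, 0.6])
        _, cost = best_intermediate(norm, dys)
        assert cost == 0

    def test_single_class_rejected(self):
        with pytest.raises(ValueError, match="both"):
            fit_limits([labeled(0.1, 0.1, 0.1, "normal")])

    def test_nonfinite_features_rejected(self):
        bad = [labeled(0.1, 0.1, 0.1, "normal"),
               labeled(float("nan"), 0.2, 0.2, "dysmorphic")]
        with pytest.raises(ValueError, match="non-finite"):
            fit_limits(bad)

    def test_training_set_consistency(self):
        # forced by min/max rules with strict comparisons: no training normal
        # fires step 2, no training dysmorphic fires step 1
        rng = np.random.default_rng(3)
        training = [
            labeled(*rng.uniform(0, 0.3, 3), "normal") for _ in range(30)
        ] + [
            labeled(*rng.uniform(0.2, 0.8, 3), "dysmorphic") for _ in range(30)
        ]
        limits = fit_limits(training)
        for t in training:
            result = classify(t.features, limits)
            if t.manual_label == "normal":
                assert result.deciding_step != 2
            else:
                assert result.deciding_step != 1


class TestClassify:
    def test_step1_small_feature_overrides_extreme(self):
        r = classify(make_features(0.005, 3.0, 5.0), EXAMPLE_LIMITS)
        assert (r.predicted_label, r.deciding_step) == ("normal", 1)

    def test_step2_above_upper(self):
        r = classify(make_features(0.02, 0.8, 4.5), EXAMPLE_LIMITS)
        assert (r.predicted_label, r.deciding_step) == ("dysmorphic", 2)

    def test_step3_two_intermediates(self):
        r = classify(make_features(0.03, 1.5, 1.5), EXAMPLE_LIMITS)
        assert (r.predicted_label, r.deciding_step) == ("dysmorphic", 3)

    def test_step4_default_normal(self):
        r = classify(make_features(0.03, 0.5, 1.0), EXAMPLE_LIMITS)
        assert (r.predicted_label, r.deciding_step) == ("normal", 4)

    def test_truth_table_enumeration(self):
        """All 4^3 interval assignments agree with an enumeration oracle."""
        # representative value inside each interval, per feature
        values = {
            name: {
                "below": lo / 2,
                "low_mid": (lo + mid) / 2,
                "mid_up": (mid + hi) / 2,
                "above": hi * 2,
            }
            for name, (lo, mid, hi) in EXAMPLE_LIMITS.limits.items()
        }

        def oracle(intervals):
            # independent statement of the 4-step scheme over interval codes
            if "below" in intervals:
                return ("normal", 1)
            if "above" in intervals:
                return ("dysmorphic", 2)
            if sum(code == "mid_up" for code in intervals) >= 2:
                return ("dysmorphic", 3)
            return ("normal", 4)

        for combo in itertools.product(["below", "low_mid", "mid_up", "above"], repeat=3):
            vec = tuple(values[name][code] for name, code in zip(FEATURE_NAMES, combo))
            r = classify(vec, EXAMPLE_LIMITS)
            assert (r.predicted_label, r.deciding_step) == oracle(combo), combo

    def test_step1_mode_all_variant(self):
        r = classify(make_features(0.005, 3.0, 5.0), EXAMPLE_LIMITS, step1_mode="all")
        assert (r.predicted_label, r.deciding_step) == ("dysmorphic", 2)

    def test_monotone_toward_dysmorphic(self):
        rng = np.random.default_rng(9)
        for _ in range(200):
            vec = [rng.uniform(EXAMPLE_LIMITS.lower(n), EXAMPLE_LIMITS.intermediate(n))
                   for n in FEATURE_NAMES]
            base = classify(tuple(vec), EXAMPLE_LIMITS)
            if base.deciding_step != 4:
                continue
            i = rng.integers(0, 3)
            vec[i] += rng.uniform(0, 5)
            bumped = classify(tuple(vec), EXAMPLE_LIMITS)
            if bumped.predicted_label != base.predicted_label:
                assert bumped.predicted_label == "dysmorphic"

    def test_nonfinite_rejected(self):
        with pytest.raises(ValueError, match="non-finite"):
            classify((float("inf"), 0.1, 0.1), EXAMPLE_LIMITS)

    def test_pure_function(self):
        vec = (0.03, 1.5, 1.5)
        results = {classify(vec, EXAMPLE_LIMITS).predicted_label for _ in range(10)}
        assert results == {"dysmorphic"}


class TestModelPersistence:
    def test_round_trip_identity(self, tmp_path):
        path = tmp_path / "model.json"
        save_model(EXAMPLE_LIMITS, path)
        loaded = load_model(path)
        assert loaded.limits == EXAMPLE_LIMITS.limits

    def test_missing_feature_rejected(self, tmp_path):
        path = tmp_path / "model.json"
        save_model(EXAMPLE_LIMITS, path)
        import json

        payload = json.loads(path.read_text())
        del payload["limits"]["mnc"]
        path.write_text(json.dumps(payload))
        with pytest.raises(ModelError, match="mnc"):
            load_model(path)

    def test_inconsistent_limits_rejected(self, tmp_path):
        path = tmp_path / "model.json"
        save_model(EXAMPLE_LIMITS, path)
        import json

        payload = json.loads(path.read_text())
        # intermediate outside the [lower, upper] band violates the invariant
        payload["limits"]["rc"] = {"lower": 0.01, "intermediate": 5.0, "upper": 1.0}
        path.write_text(json.dumps(payload))
        with pytest.raises(ModelError):
            load_model(path)

    def test_schema_version_checked(self, tmp_path):
        path = tmp_path / "model.json"
        path.write_text('{"schema_version": 99, "limits": {}}')
        with pytest.raises(ModelError, match="schema_version"):
            load_model(path)


class TestSyntheticRecovery:
    def test_held_out_agreement_above_90pct(self):
        """Limits trained on one synthetic corpus classify a held-out corpus
        with >= 90% agreement against the generator's ground-truth labels."""
        def corpus(seed):
            specs = nm.sample_nucleus_specs(100, 100, seed=seed)
            return [
                (nm.compute_features(nm.generate_boundary(s, 1000)), s.label)
                for s in specs
            ]

        train = corpus(101)
        held_out = corpus(202)
        limits = fit_limits([LabeledNucleus(f, lab) for f, lab in train])
        agree = np.mean(
            [classify(f, limits).predicted_label == lab for f, lab in held_out]
        )
        assert agree >= 0.90
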