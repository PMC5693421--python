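"""Trainable three-limit dysmorphy classifier.

For each of the three features (rc, mnc, nc_max) three thresholds are
learned from a manually labeled training set:

* **upper** — the largest feature value among normal-labeled nuclei;
* **lower** — the smallest feature value among dysmorphic-labeled nuclei;
* **intermediate** — the threshold minimizing the combined count of
  dysmorphic nuclei below it and normal nuclei above it, clamped into
  [lower, upper].

Classification applies four steps strictly in order, with strict
inequalities throughout:

1. any feature below its lower limit  -> normal
2. any feature above its upper limit  -> dysmorphic
3. at least two features above their intermediate limits -> dysmorphic
4. otherwise -> normal

Step 1 deliberately fires on a *single* small feature even when another
feature is extreme; ``step1_mode="all"`` is available as a documented
variant requiring all three features to be below their lower limits.
"""

from __future__ import annotations

import json
import logging
import math
from dataclasses import dataclass
from pathlib import Path

import numpy as np

from .features import ShapeFeatures

logger = logging.getLogger(__name__)

FEATURE_NAMES = ("rc", "mnc", "nc_max")
NORMAL = "normal"
DYSMORPHIC = "dysmorphic"

MODEL_SCHEMA_VERSION = 1


class ModelError(ValueError):
    """Raised for malformed or inconsistent persisted models."""


@dataclass
class LabeledNucleus:
    features: ShapeFeatures
    manual_label: str
    observer_id: str = ""

    def __post_init__(self) -> None:
        if self.manual_label not in (NORMAL, DYSMORPHIC):
            raise ValueError(f"label must be normal/dysmorphic, got {self.manual_label!r}")


@dataclass
class FeatureLimits:
    """Per-feature (lower, intermediate, upper) thresholds; the trained model."""

    limits: dict[str, tuple[float, float, float]]

    def __post_init__(self) -> None:
        missing = set(FEATURE_NAMES) - set(self.limits)
        if missing:
            raise ModelError(f"limits missing for features: {sorted(missing)}")
        for name in FEATURE_NAMES:
            lo, mid, hi = self.limits[name]
            if not (math.isfinite(lo) and math.isfinite(mid) and math.isfinite(hi)):
                raise ModelError(f"{name}: non-finite limit")
            # lower > upper is legal only when the training classes were
            # fully separated on this feature (min dysmorphic > max normal);
            # the intermediate must then sit in the gap.
            if min(lo, hi) < 0 or not (min(lo, hi) <= mid <= max(lo, hi)):
                raise ModelError(
                    f"{name}: require limits >= 0 with intermediate between "
                    f"lower and upper, got ({lo}, {mid}, {hi})"
                )

    def lower(self, name: str) -> float:
        return self.limits[name][0]

    def intermediate(self, name: str) -> float:
        return self.limits[name][1]

    def upper(self, name: str) -> float:
        return self.limits[name][2]


@dataclass
class ClassificationResult:
    nucleus_id: int
    predicted_label: str
    deciding_step: int
    feature_snapshot: tuple[float, float, float]


def _feature_vector(features) -> tuple[float, float, float]:
    if isinstance(features, ShapeFeatures):
        vec = features.as_tuple()
    else:
        vec = tuple(float(v) for v in features)
        if len(vec) != 3:
            raise ValueError("expected (rc, mnc, nc_max)")
    if not all(math.isfinite(v) for v in vec):
        raise ValueError(f"non-finite feature values: {vec}")
    return vec


def best_intermediate(
    normal_values: np.ndarray, dysmorphic_values: np.ndarray
) -> tuple[float, int]:
    """Threshold minimizing (#dysmorphic < t) + (#normal > t), and that count.

    Candidates are midpoints of consecutive distinct sorted values plus one
    candidate below the minimum and one above the maximum; ties prefer the
    smallest threshold.
    """
    values = np.sort(np.unique(np.concatenate([normal_values, dysmorphic_values])))
    candidates = [values[0] - 1.0]
    candidates += [0.5 * (values[i] + values[i + 1]) for i in range(len(values) - 1)]
    candidates.append(values[-1] + 1.0)
    best_t, best_cost = candidates[0], None
    for t in candidates:
        cost = int(np.sum(dysmorphic_values < t)) + int(np.sum(normal_values > t))
        if best_cost is None or cost < best_cost:
            best_t, best_cost = t, cost
    return float(best_t), int(best_cost)


def fit_limits(training: list[LabeledNucleus]) -> FeatureLimits:
    """Train the three limits for every feature from a labeled set."""
    normals = [n for n in training if n.manual_label == NORMAL]
    dysmorphics = [n for n in training if n.manual_label == DYSMORPHIC]
    if not normals or not dysmorphics:
        raise ValueError("training set must contain both normal and dysmorphic nuclei")
    bad = [
        i for i, n in enumerate(training)
        if not all(math.isfinite(v) for v in n.features.as_tuple())
    ]
    if bad:
        raise ValueError(f"non-finite feature values for training nuclei at indices {bad}")

    limits: dict[str, tuple[float, float, float]] = {}
    for idx, name in enumerate(FEATURE_NAMES):
        norm_vals = np.array([n.features.as_tuple()[idx] for n in normals])
        dys_vals = np.array([n.features.as_tuple()[idx] for n in dysmorphics])
        lower = float(dys_vals.min())
        upper = float(norm_vals.max())
        mid, _ = best_intermediate(norm_vals, dys_vals)
        lo, hi = min(lower, upper), max(lower, upper)
        if not lo <= mid <= hi:
            logger.warning(
                "%s: optimal intermediate %.6g outside [%.6g, %.6g]; clamped",
                name, mid, lo, hi,
            )
            mid = min(max(mid, lo), hi)
        if lower > upper:
            logger.info(
                "%s: classes fully separated (min dysmorphic %.6g > max normal %.6g)",
                name, lower, upper,
            )
        limits[name] = (lower, mid, upper)
    return FeatureLimits(limits)


def classify(
    features, limits: FeatureLimits, nucleus_id: int = 0, step1_mode: str = "any"
) -> ClassificationResult:
    """Apply the 4-step scheme; pure function of (features, limits)."""
    if step1_mode not in ("any", "all"):
        raise ValueError("step1_mode must be 'any' or 'all'")
    vec = _feature_vector(features)
    below_lower = [vec[i] < limits.lower(name) for i, name in enumerate(FEATURE_NAMES)]
    step1 = all(below_lower) if step1_mode == "all" else any(below_lower)
    if step1:
        return ClassificationResult(nucleus_id, NORMAL, 1, vec)
    if any(vec[i] > limits.upper(name) for i, name in enumerate(FEATURE_NAMES)):
        return ClassificationResult(nucleus_id, DYSMORPHIC, 2, vec)
    n_above_mid = sum(
        vec[i] > limits.intermediate(name) for i, name in enumerate(FEATURE_NAMES)
    )
    if n_above_mid >= 2:
        return ClassificationResult(nucleus_id, DYSMORPHIC, 3, vec)
    return ClassificationResult(nucleus_id, NORMAL, 4, vec)


def save_model(limits: FeatureLimits, path: str | Path, metadata: dict | None = None) -> None:
    """Persist limits as JSON; load(save(x)) round-trips exactly."""
    payload = {
        "schema_version": MODEL_SCHEMA_VERSION,
        "limits": {
            name: {"lower": lo, "intermediate": mid, "upper": hi}
            for name, (lo, mid, hi) in limits.limits.items()
        },
        "metadata": metadata or {},
    }
    Path(path).write_text(json.dumps(payload, indent=2))


def load_model(path: str | Path) -> FeatureLimits:
    try:
        payload = json.loads(Path(path).read_text())
    except json.JSONDecodeError as exc:
        raise ModelError(f"{path}: not valid JSON ({exc})") from exc
    if payload.get("schema_version") != MODEL_SCHEMA_VERSION:
        raise ModelError(
            f"{path}: schema_version {payload.get('schema_version')!r} != "
            f"{MODEL_SCHEMA_VERSION}; expected keys: schema_version, limits"
        )
    raw = payload.get("limits", {})
    limits = {}
    for name in FEATURE_NAMES:
        if name not in raw:
            raise ModelError(
                f"{path}: missing limits for {name!r}; each feature needs "
                "{lower, intermediate, upper}"
            )
        entry = raw[name]
        try:
            limits[name] = (
                float(entry["lower"]), float(entry["intermediate"]), float(entry["upper"])
            )
        except (KeyError, TypeError) as exc:
            raise ModelError(
                f"{path}: {name} limits must be numeric lower/intermediate/upper"
            ) from exc
    return FeatureLimits(limits)
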