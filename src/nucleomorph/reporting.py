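"""Inter-rater agreement, per-sample morphology summaries, age-trend regression.

Agreement between two binary label vectors is reported both as raw percent
agreement and as Cohen's Kappa (chance-corrected via the raters' marginal
label frequencies) — percent agreement alone flatters raters who guess.

The age-trend analysis fits percent-dysmorphic against age at biopsy by
ordinary least squares, with t-based 95% confidence and prediction bands,
and measures each patient's signed deviation from the fitted control trend.
The same machinery regresses symptom-onset age on that deviation.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import statsmodels.api as sm

from .classifier import DYSMORPHIC, ClassificationResult
from .features import ShapeFeatures

logger = logging.getLogger(__name__)


@dataclass
class AgreementResult:
    kappa: float
    percent_agreement: float
    n: int
    confusion: np.ndarray  # 2x2, rows = rater a, cols = rater b, order (normal, dys)


def _as_labels(vec) -> np.ndarray:
    arr = np.asarray(vec)
    if arr.dtype.kind in "ifb":
        return arr.astype(int)
    mapping = {"normal": 0, "dysmorphic": 1}
    try:
        return np.array([mapping[str(v)] for v in arr])
    except KeyError as exc:
        raise ValueError(f"labels must be normal/dysmorphic, got {exc}") from exc


def confusion_counts(a, b) -> np.ndarray:
    a, b = _as_labels(a), _as_labels(b)
    if len(a) != len(b):
        raise ValueError(f"label vectors differ in length: {len(a)} vs {len(b)}")
    conf = np.zeros((2, 2), dtype=int)
    for ai, bi in zip(a, b):
        conf[ai, bi] += 1
    return conf


def percent_agreement(a, b) -> float:
    """100 x fraction of positions with identical labels."""
    conf = confusion_counts(a, b)
    n = conf.sum()
    if n < 1:
        raise ValueError("need at least one label pair")
    return 100.0 * float(np.trace(conf)) / float(n)


def cohens_kappa(a, b) -> float:
    """(p_o - p_e) / (1 - p_e) with chance agreement p_e from the marginals.

    When both raters are constant and identical, p_e = 1 and the ratio is
    indeterminate; agreement is perfect, so 1.0 is returned (and logged).
    """
    conf = confusion_counts(a, b)
    n = conf.sum()
    if n < 2:
        raise ValueError("need at least two label pairs for kappa")
    p_o = float(np.trace(conf)) / n
    p_e = float(np.sum(conf.sum(axis=1) * conf.sum(axis=0))) / (n * n)
    if p_e >= 1.0:
        logger.info("both raters constant and identical; kappa = 1 by convention")
        return 1.0
    return (p_o - p_e) / (1.0 - p_e)


def agreement(a, b) -> AgreementResult:
    conf = confusion_counts(a, b)
    return AgreementResult(
        kappa=cohens_kappa(a, b),
        percent_agreement=percent_agreement(a, b),
        n=int(conf.sum()),
        confusion=conf,
    )


@dataclass
class SampleSummary:
    """Morphology aggregates for one sample (coverslip or individual)."""

    sample_id: str
    n_nuclei: int
    n_dysmorphic: int
    percent_dysmorphic: float
    mean_area: float
    sd_area: float
    mean_area_dysmorphic: float
    sd_area_dysmorphic: float
    mean_eccentricity: float
    sd_eccentricity: float
    mean_mnc: float
    sd_mnc: float
    mean_mnc_dysmorphic: float
    sd_mnc_dysmorphic: float
    dysmorphic_stats_defined: bool = True


def _mean_sd(values: np.ndarray) -> tuple[float, float]:
    if values.size == 0:
        return (math.nan, math.nan)
    return float(np.mean(values)), float(np.std(values, ddof=1)) if values.size > 1 else 0.0


def summarize_sample(
    calls: list[ClassificationResult],
    features: list[ShapeFeatures],
    sample_id: str,
) -> SampleSummary:
    """Counts, percent dysmorphic, and overall / dysmorphic-only aggregates."""
    if len(calls) != len(features):
        raise ValueError("calls and features must be aligned")
    n = len(calls)
    dys_mask = np.array([c.predicted_label == DYSMORPHIC for c in calls], dtype=bool)
    n_dys = int(dys_mask.sum())
    area = np.array([f.area_a for f in features])
    ecc = np.array([f.eccentricity for f in features])
    mnc = np.array([f.mnc for f in features])
    mean_area, sd_area = _mean_sd(area)
    mean_ecc, sd_ecc = _mean_sd(ecc)
    mean_mnc, sd_mnc = _mean_sd(mnc)
    mean_area_d, sd_area_d = _mean_sd(area[dys_mask])
    mean_mnc_d, sd_mnc_d = _mean_sd(mnc[dys_mask])
    return SampleSummary(
        sample_id=sample_id,
        n_nuclei=n,
        n_dysmorphic=n_dys,
        percent_dysmorphic=100.0 * n_dys / n if n else math.nan,
        mean_area=mean_area,
        sd_area=sd_area,
        mean_area_dysmorphic=mean_area_d,
        sd_area_dysmorphic=sd_area_d,
        mean_eccentricity=mean_ecc,
        sd_eccentricity=sd_ecc,
        mean_mnc=mean_mnc,
        sd_mnc=sd_mnc,
        mean_mnc_dysmorphic=mean_mnc_d,
        sd_mnc_dysmorphic=sd_mnc_d,
        dysmorphic_stats_defined=n_dys > 0,
    )


@dataclass
class RegressionFit:
    """OLS fit of y on x with t-based confidence and prediction intervals."""

    slope: float
    intercept: float
    r_squared: float
    p_slope: float
    residual_se: float
    n: int
    level: float = 0.95
    _results: object = field(default=None, repr=False)

    def predict(self, x) -> pd.DataFrame:
        """Fitted mean with CI and PI at the given predictor values.

        Columns: x, fit, ci_lower, ci_upper, pi_lower, pi_upper.
        """
        x = np.atleast_1d(np.asarray(x, dtype=float))
        exog = sm.add_constant(x, has_constant="add")
        pred = self._results.get_prediction(exog)
        frame = pred.summary_frame(alpha=1.0 - self.level)
        return pd.DataFrame(
            {
                "x": x,
                "fit": frame["mean"].to_numpy(),
                "ci_lower": frame["mean_ci_lower"].to_numpy(),
                "ci_upper": frame["mean_ci_upper"].to_numpy(),
                "pi_lower": frame["obs_ci_lower"].to_numpy(),
                "pi_upper": frame["obs_ci_upper"].to_numpy(),
            }
        )

    def predict_mean(self, x: float) -> float:
        return self.intercept + self.slope * float(x)

    def slope_confint(self) -> tuple[float, float]:
        ci = self._results.conf_int(alpha=1.0 - self.level)
        return float(ci[1, 0]), float(ci[1, 1])


def _ols_fit(x: np.ndarray, y: np.ndarray, level: float = 0.95) -> RegressionFit:
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if len(x) != len(y):
        raise ValueError("x and y must be the same length")
    if len(x) < 3:
        raise ValueError("need at least 3 points for a regression with intervals")
    if np.ptp(x) == 0:
        raise ValueError("degenerate design: all predictor values equal")
    exog = sm.add_constant(x, has_constant="add")
    results = sm.OLS(y, exog).fit()
    return RegressionFit(
        slope=float(results.params[1]),
        intercept=float(results.params[0]),
        r_squared=float(results.rsquared),
        p_slope=float(results.pvalues[1]),
        residual_se=float(np.sqrt(results.mse_resid)),
        n=len(x),
        level=level,
        _results=results,
    )


def fit_age_trend(points, level: float = 0.95) -> RegressionFit:
    """OLS of percent-dysmorphic on age at biopsy, with 95% CI/PI bands.

    ``points`` is a sequence of (age_years, percent_dysmorphic) pairs.
    """
    arr = np.asarray(points, dtype=float)
    return _ols_fit(arr[:, 0], arr[:, 1], level=level)


def deviation_from_trend(fit: RegressionFit, individual: tuple[float, float]) -> float:
    """Observed minus trend-predicted percent dysmorphic, in percentage points."""
    age, observed = individual
    return float(observed) - fit.predict_mean(age)


def onset_regression(records, level: float = 0.95) -> RegressionFit:
    """OLS of symptom-onset age on deviation-from-trend (same CI/PI machinery).

    ``records`` is a sequence of (deviation_pct_points, onset_age_years).
    """
    arr = np.asarray(records, dtype=float)
    return _ols_fit(arr[:, 0], arr[:, 1], level=level)
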