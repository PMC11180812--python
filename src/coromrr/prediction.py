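"""MRR prediction models, Doppler reference MRR, and validation statistics.

Two predictors estimate the actual MRR from quantities available during a
routine pressure-wire study:

* linear:    MRR_pl = b0 + b1 * MRRpb_max, from pressure bounds alone;
* quadratic: the percent area stenosis locates the actual MRR inside the
  pressure-bounded interval through a quadratic AS% -> ratio model,
  MRR_pq = MRRpb_max - ratio * (MRRpb_max - MRRpb_min).

The published derivation-cohort coefficients ship as immutable presets;
``fit_linear``/``fit_quadratic`` re-derive coefficient sets from new
cohorts without mutating the presets. Agreement with the Doppler
reference uses Pearson correlation and Bland-Altman limits of agreement.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np
import statsmodels.api as sm
from scipy import stats

CMD_MRR_THRESHOLD = 2.5
"""MRR below this value flags coronary microvascular dysfunction."""


def _bounded_r_squared(model) -> float:
    # constant y makes TSS zero; report 0 rather than nan/-inf
    r2 = float(model.rsquared)
    if not np.isfinite(r2):
        return 0.0
    return min(max(r2, 0.0), 1.0)


@dataclass(frozen=True)
class PredictionCoefficients:
    """Coefficients of the linear and stenosis-informed quadratic predictors.

    Defaults are the full derivation-cohort values; ``non_ischemic_preset``
    swaps in the FFR > 0.8 subgroup linear fit.
    """

    linear_intercept: float = 1.0422
    linear_slope: float = 0.5122
    ratio_a0: float = 0.004717
    ratio_a1: float = 0.006787
    ratio_a2: float = 0.00003998
    clamp_ratio: bool = True


FULL_COHORT = PredictionCoefficients()
NON_ISCHEMIC = replace(FULL_COHORT, linear_intercept=0.69, linear_slope=0.64)

PRESETS: dict[str, PredictionCoefficients] = {
    "full-cohort": FULL_COHORT,
    "non-ischemic-ffr-gt-0.8": NON_ISCHEMIC,
}


@dataclass(frozen=True)
class RegressionFit:
    """OLS fit summary: coefficients in increasing polynomial order."""

    coefficients: tuple[float, ...]
    r_squared: float
    p_value: float
    n: int


@dataclass(frozen=True)
class AgreementStats:
    """Bland-Altman bias and 95% limits of agreement (reference - test)."""

    bias: float
    loa_low: float
    loa_high: float
    n: int


@dataclass(frozen=True)
class DopplerRecord:
    """Average peak velocities (cm/s) from an intracoronary Doppler wire."""

    apv_rest: float
    apv_hyp: float

    def __post_init__(self) -> None:
        if self.apv_rest <= 0 or self.apv_hyp <= 0:
            raise ValueError("Doppler velocities must be > 0")

    @property
    def cfr(self) -> float:
        return self.apv_hyp / self.apv_rest


def predict_mrr_linear(
    mrr_pb_max: float, coefs: PredictionCoefficients = FULL_COHORT
) -> float:
    """Linear MRR prediction from the upper pressure bound alone."""
    return coefs.linear_intercept + coefs.linear_slope * mrr_pb_max


def predict_ratio_from_as(
    as_percent: float, coefs: PredictionCoefficients = FULL_COHORT
) -> float:
    """Predicted interval position (0 = upper bound, 1 = lower) from AS%."""
    x = as_percent
    ratio = coefs.ratio_a0 + coefs.ratio_a1 * x + coefs.ratio_a2 * x * x
    if coefs.clamp_ratio:
        ratio = min(max(ratio, 0.0), 1.0)
    return ratio


def predict_mrr_quadratic(
    mrr_pb_min: float,
    mrr_pb_max: float,
    as_percent: float,
    coefs: PredictionCoefficients = FULL_COHORT,
) -> float:
    """Combined pressure + stenosis MRR prediction.

    Places the MRR inside [mrr_pb_min, mrr_pb_max] at the interval
    position predicted from the percent area stenosis. A degenerate
    interval returns the (equal) upper bound.
    """
    if mrr_pb_max < mrr_pb_min:
        raise ValueError("mrr_pb_max must be >= mrr_pb_min")
    ratio = predict_ratio_from_as(as_percent, coefs)
    return mrr_pb_max - ratio * (mrr_pb_max - mrr_pb_min)


def mrr_doppler(doppler: DopplerRecord, Pa_rest: float, Pd_hyp: float) -> float:
    """Doppler reference MRR: (APV_hyp/APV_rest) * Pa_rest / Pd_hyp.

    ``Pd_hyp`` should be the hydrostatic-corrected hyperemic distal
    pressure when the height offset is known.
    """
    if Pa_rest <= 0 or Pd_hyp <= 0:
        raise ValueError("pressures must be > 0")
    return doppler.cfr * Pa_rest / Pd_hyp


def fit_linear(x: np.ndarray, y: np.ndarray) -> RegressionFit:
    """OLS straight-line fit; p-value is the two-sided slope test."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size < 3:
        raise ValueError("need at least 3 points for a linear fit")
    if not (np.all(np.isfinite(x)) and np.all(np.isfinite(y))):
        raise ValueError("inputs must be finite")
    if np.ptp(x) == 0:
        raise ValueError("x is constant; slope is undefined")
    model = sm.OLS(y, sm.add_constant(x)).fit()
    return RegressionFit(
        coefficients=tuple(model.params),
        r_squared=_bounded_r_squared(model),
        p_value=float(model.pvalues[1]),
        n=int(x.size),
    )


def fit_quadratic(x: np.ndarray, y: np.ndarray) -> RegressionFit:
    """OLS fit of y on [1, x, x^2]; p-value is the overall F-test."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size < 4:
        raise ValueError("need at least 4 points for a quadratic fit")
    design = sm.add_constant(np.column_stack([x, x * x]))
    if np.linalg.matrix_rank(design) < 3:
        raise ValueError("design matrix is rank deficient")
    model = sm.OLS(y, design).fit()
    return RegressionFit(
        coefficients=tuple(model.params),
        r_squared=_bounded_r_squared(model),
        p_value=float(model.f_pvalue),
        n=int(x.size),
    )


def pearson(x: np.ndarray, y: np.ndarray) -> tuple[float, float]:
    """Pearson r and two-sided p-value (t distribution, n-2 df)."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size < 3:
        raise ValueError("need at least 3 points for a correlation")
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        raise ValueError("zero variance input")
    result = stats.pearsonr(x, y)
    return float(result.statistic), float(result.pvalue)


def bland_altman(reference: np.ndarray, test: np.ndarray) -> AgreementStats:
    """Bland-Altman agreement between a reference and a test method.

    Differences are oriented reference - test; limits of agreement use the
    sample (n-1) standard deviation with the 1.96 multiplier.
    """
    reference = np.asarray(reference, dtype=float)
    test = np.asarray(test, dtype=float)
    if reference.shape != test.shape:
        raise ValueError("series lengths differ")
    if reference.size < 2:
        raise ValueError("need at least 2 paired values")
    diffs = reference - test
    bias = float(np.mean(diffs))
    sd = float(np.std(diffs, ddof=1))
    return AgreementStats(
        bias=bias,
        loa_low=bias - 1.96 * sd,
        loa_high=bias + 1.96 * sd,
        n=int(reference.size),
    )


def classify_cmd(mrr: float, threshold: float = CMD_MRR_THRESHOLD) -> bool:
    """True (microvascular dysfunction) iff MRR is strictly below threshold."""
    if mrr < 0:
        raise ValueError("MRR must be non-negative")
    return mrr < threshold
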