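"""Agreement and misclassification statistics for gradient estimators.

Given paired (estimate, truth) gradients this module computes the usual
method-comparison battery: Bland-Altman bias and limits of agreement,
Pearson correlation with the standard error of estimate of the line
truth ~ estimate, false-positive/false-negative counts at a clinical
decision threshold (default 40 mmHg), a Shapiro-Wilk normality check of
the differences and a paired Wilcoxon signed-rank test.

Differences are always estimate − truth, so positive bias means the
estimator overestimates the true gradient.
"""

from __future__ import annotations

from dataclasses import dataclass, asdict
from typing import Dict, Tuple

import numpy as np
import pandas as pd
from scipy import stats

from .fitting import predict
from .hemodynamics import ModelCoefficients

__all__ = [
    "BlandAltman",
    "EvaluationReport",
    "ESTIMATOR_ORDER",
    "bland_altman",
    "correlation_and_see",
    "classify_threshold",
    "paired_comparison",
    "evaluate_estimators",
]

#: Fixed estimator order of combined reports.
ESTIMATOR_ORDER = ("bernoulli_max", "bernoulli_avg", "adjusted_model")

LOA_MULTIPLIER = 1.96  # conventional 95% limits of agreement


@dataclass(frozen=True)
class BlandAltman:
    mean_diff: float  # bias [mmHg]
    sd_diff: float  # SD of differences, n-1 [mmHg]
    loa_low: float  # mean - 1.96 SD [mmHg]
    loa_high: float  # mean + 1.96 SD [mmHg]


@dataclass(frozen=True)
class EvaluationReport:
    """One estimator's agreement with ground truth."""

    estimator: str
    n: int
    mean_diff: float
    sd_diff: float
    loa_low: float
    loa_high: float
    r: float
    r2: float
    see: float
    threshold: float
    n_fp: int
    n_fn: int
    normality_p: float
    paired_test_p: float
    degenerate: bool = False  # all differences zero; signed-rank undefined

    def to_dict(self) -> dict:
        return asdict(self)


def _paired(estimate, truth, min_n: int = 3) -> Tuple[np.ndarray, np.ndarray]:
    est = np.asarray(estimate, dtype=float)
    tru = np.asarray(truth, dtype=float)
    if est.shape != tru.shape or est.ndim != 1:
        raise ValueError("estimate and truth must be equal-length 1-d arrays")
    if est.size < min_n:
        raise ValueError(f"need at least {min_n} pairs, got {est.size}")
    if not np.all(np.isfinite(est) & np.isfinite(tru)):
        raise ValueError("non-finite value in paired series")
    return est, tru


def bland_altman(estimate, truth) -> BlandAltman:
    """Bias and 95% limits of agreement of estimate − truth."""
    est, tru = _paired(estimate, truth)
    diff = est - tru
    mean = float(diff.mean())
    sd = float(diff.std(ddof=1))
    return BlandAltman(mean, sd, mean - LOA_MULTIPLIER * sd, mean + LOA_MULTIPLIER * sd)


def correlation_and_see(estimate, truth) -> Tuple[float, float, float]:
    """Pearson r, r², and the standard error of estimate [mmHg].

    The SEE is the residual standard error (n−2 degrees of freedom) of
    the ordinary least-squares line truth ~ estimate — the spread of true
    gradients around the calibration line of the estimator.
    """
    est, tru = _paired(estimate, truth)
    if est.std() == 0 or tru.std() == 0:
        raise ValueError("correlation undefined: a series has zero variance")
    fit = stats.linregress(est, tru)
    resid = tru - (fit.intercept + fit.slope * est)
    see = float(np.sqrt(np.sum(resid**2) / (est.size - 2)))
    r = float(fit.rvalue)
    return r, r * r, see


def classify_threshold(estimate, truth, threshold: float = 40.0) -> Tuple[int, int]:
    """False-positive / false-negative counts at a decision threshold.

    A false positive places a case strictly above the threshold while the
    truth is at or below it; a false negative misses a truly
    above-threshold case. Equality counts as below ("above" is strict).
    """
    est, tru = _paired(estimate, truth, min_n=1)
    n_fp = int(np.sum((tru <= threshold) & (est > threshold)))
    n_fn = int(np.sum((tru > threshold) & (est <= threshold)))
    return n_fp, n_fn


def paired_comparison(estimate, truth) -> Tuple[float, float, bool]:
    """Shapiro-Wilk normality p of the differences and paired Wilcoxon p.

    Returns ``(normality_p, paired_test_p, degenerate)``; when every
    difference is zero the signed-rank statistic is undefined and the
    result is flagged degenerate with both p-values 1.
    """
    est, tru = _paired(estimate, truth)
    diff = est - tru
    if np.all(diff == 0):
        return 1.0, 1.0, True
    normality_p = float(stats.shapiro(diff).pvalue)
    wil = stats.wilcoxon(est, tru, alternative="two-sided")
    return normality_p, float(wil.pvalue), False


def _single_report(
    name: str, estimate: np.ndarray, truth: np.ndarray, threshold: float
) -> EvaluationReport:
    ba = bland_altman(estimate, truth)
    r, r2, see = correlation_and_see(estimate, truth)
    n_fp, n_fn = classify_threshold(estimate, truth, threshold)
    normality_p, paired_p, degenerate = paired_comparison(estimate, truth)
    return EvaluationReport(
        estimator=name,
        n=int(estimate.size),
        mean_diff=ba.mean_diff,
        sd_diff=ba.sd_diff,
        loa_low=ba.loa_low,
        loa_high=ba.loa_high,
        r=r,
        r2=r2,
        see=see,
        threshold=threshold,
        n_fp=n_fp,
        n_fn=n_fn,
        normality_p=normality_p,
        paired_test_p=paired_p,
        degenerate=degenerate,
    )


def evaluate_estimators(
    records: pd.DataFrame,
    coeffs: ModelCoefficients,
    threshold: float = 40.0,
) -> Dict[str, EvaluationReport]:
    """Evaluate the three gradient estimators against ground truth.

    Runs, in fixed order, the classical Bernoulli estimator on the peak
    velocity (``4·v_max²``), the Bernoulli estimator on the area-averaged
    velocity (``4·(10·Q/AVA)²``) and the adjusted power-law model with
    the supplied coefficients, over the retained (non-excluded) rows of a
    cohort table, and returns one report per estimator.
    """
    retained = records.loc[~records["excluded"].astype(bool)]
    ava = retained["ava_cm2"].to_numpy(dtype=float)
    q = retained["q_l_s"].to_numpy(dtype=float)
    v_max = retained["v_max_m_s"].to_numpy(dtype=float)
    truth = retained["tpg_true_mmhg"].to_numpy(dtype=float)

    v_avg = 10.0 * q / ava
    estimates = {
        "bernoulli_max": 4.0 * v_max**2,
        "bernoulli_avg": 4.0 * v_avg**2,
        "adjusted_model": predict(coeffs, ava, q),
    }
    return {
        name: _single_report(name, estimates[name], truth, threshold)
        for name in ESTIMATOR_ORDER
    }
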