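"""Attribute chi-square P-values to features and select by BH-adjusted threshold.

The selection statistic is a per-feature score: a singular-vector component
(``u_li``) or a projection (``b_i``).  Under the working null hypothesis that
these scores are Gaussian with standard deviation ``sigma``, the squared
standardized score follows a chi-square distribution with one degree of
freedom, so

    P_i = P_chi2[ > (score_i / sigma)^2 ]     (df = 1).

P-values are adjusted by the Benjamini-Hochberg step-up procedure and
features with adjusted P strictly below the threshold are selected
(0.01 is the conventional choice for this family of methods).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.stats import chi2
from statsmodels.stats.multitest import multipletests

__all__ = [
    "FeatureScore",
    "chi2_pvalues",
    "estimate_sigma",
    "bh_adjust",
    "select",
    "score_features",
]


def estimate_sigma(statistic: np.ndarray) -> float:
    """Population standard deviation (ddof=0) of a score vector.

    All components contribute; no trimming.  Raises on vectors of length < 2
    or with zero spread, for which the standardized score is undefined.
    """
    statistic = np.asarray(statistic, dtype=float)
    if statistic.size < 2:
        raise ValueError("need at least two components to estimate sigma")
    sigma = float(statistic.std(ddof=0))
    if sigma == 0.0:
        raise ValueError("score vector has zero spread; sigma undefined")
    return sigma


def chi2_pvalues(statistic: np.ndarray, sigma: float) -> np.ndarray:
    """P_i = survival function of chi2(df=1) at (statistic_i / sigma)^2."""
    if sigma <= 0:
        raise ValueError("sigma must be positive")
    statistic = np.asarray(statistic, dtype=float)
    return chi2.sf((statistic / sigma) ** 2, df=1)


def bh_adjust(raw_p: np.ndarray) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted P-values, original order preserved."""
    raw_p = np.asarray(raw_p, dtype=float)
    if raw_p.size == 0:
        return raw_p
    if np.any((raw_p <= 0) | (raw_p > 1)):
        raise ValueError("raw P-values must lie in (0, 1]")
    return multipletests(raw_p, method="fdr_bh")[1]


@dataclass(frozen=True)
class FeatureScore:
    """Per-feature selection statistic with raw/adjusted P-values and flags."""

    feature_ids: tuple[str, ...]
    statistic: np.ndarray
    sigma: float
    raw_p: np.ndarray
    adjusted_p: np.ndarray
    selected: np.ndarray
    threshold: float

    @property
    def selected_ids(self) -> tuple[str, ...]:
        return tuple(np.asarray(self.feature_ids, dtype=object)[self.selected])

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "feature_id": list(self.feature_ids),
                "statistic": self.statistic,
                "raw_p": self.raw_p,
                "adjusted_p": self.adjusted_p,
                "selected": self.selected,
            }
        )


def score_features(
    feature_ids,
    statistic: np.ndarray,
    threshold: float = 0.01,
    sigma: float | None = None,
    raw_p: np.ndarray | None = None,
) -> FeatureScore:
    """Build a :class:`FeatureScore` from a statistic vector.

    If ``raw_p`` is given (e.g. empirical P-values from a shuffling null) it
    is used directly; otherwise chi-square df=1 P-values are computed with
    ``sigma`` (estimated from the statistic when not supplied).
    """
    statistic = np.asarray(statistic, dtype=float)
    if raw_p is None:
        if sigma is None:
            sigma = estimate_sigma(statistic)
        raw_p = chi2_pvalues(statistic, sigma)
    else:
        raw_p = np.asarray(raw_p, dtype=float)
        if sigma is None:
            sigma = float("nan")
    adjusted = bh_adjust(raw_p)
    return FeatureScore(
        feature_ids=tuple(map(str, feature_ids)),
        statistic=statistic,
        sigma=float(sigma),
        raw_p=raw_p,
        adjusted_p=adjusted,
        selected=adjusted < threshold,
        threshold=float(threshold),
    )


def select(scores: FeatureScore, threshold: float | None = None) -> tuple[str, ...]:
    """Feature ids with adjusted P strictly below the threshold, input order."""
    thr = scores.threshold if threshold is None else threshold
    mask = scores.adjusted_p < thr
    return tuple(np.asarray(scores.feature_ids, dtype=object)[mask])
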