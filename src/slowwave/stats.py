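"""Paired-comparison statistics for baseline-vs-stimulation contrasts.

Each animal serves as its own control (baseline day vs stimulation day), so
the workhorse is the two-tailed paired t-test on per-subject differences
d = y - x: t = mean(d) / (sd(d)/sqrt(n)) with the sample sd (n-1 denominator)
and p from the t distribution with n-1 df. Summaries are mean ± SEM. Subjects
missing a value in either condition (e.g. no REM epochs on one day) are
dropped pairwise, which is why degrees of freedom vary between contrasts.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass

import numpy as np
from scipy import stats as sps

logger = logging.getLogger(__name__)

__all__ = ["PairedResult", "paired_t", "summarize", "bh_adjust"]


@dataclass(frozen=True)
class PairedResult:
    """Result of a two-tailed paired t-test on d = y - x."""

    t_statistic: float
    degrees_of_freedom: int
    p_two_tailed: float
    mean_difference: float
    sem_difference: float
    n_pairs: int
    degenerate: bool = False


def paired_t(x, y) -> PairedResult:
    """Two-tailed paired t-test of condition B (y) against condition A (x).

    Pairs with a missing (NaN) member are dropped with a logged count. With
    zero spread in the differences the test is degenerate: t is ±inf with
    p = 0 when the mean difference is non-zero, and t = 0 with p = 1 when it
    is exactly zero.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or x.ndim != 1:
        raise ValueError("x and y must be 1-D arrays of equal length")
    keep = ~(np.isnan(x) | np.isnan(y))
    n_dropped = int(np.sum(~keep))
    if n_dropped:
        logger.info("paired_t: dropped %d pairs with missing members", n_dropped)
    d = y[keep] - x[keep]
    n = d.size
    if n < 2:
        raise ValueError(f"need at least 2 complete pairs, got {n}")
    mean_d = float(np.mean(d))
    sd_d = float(np.std(d, ddof=1))
    sem_d = sd_d / math.sqrt(n)
    df = n - 1
    if sd_d == 0.0:
        if mean_d == 0.0:
            return PairedResult(0.0, df, 1.0, 0.0, 0.0, n, degenerate=True)
        t = math.inf if mean_d > 0 else -math.inf
        return PairedResult(t, df, 0.0, mean_d, 0.0, n, degenerate=True)
    t = mean_d / sem_d
    p = 2.0 * float(sps.t.sf(abs(t), df))
    return PairedResult(t, df, p, mean_d, sem_d, n)


def summarize(values) -> tuple[float, float]:
    """Mean and SEM (sd/sqrt(n), sample sd) of a sample; SEM is 0 when n = 1."""
    v = np.asarray(values, dtype=float)
    v = v[~np.isnan(v)]
    if v.size == 0:
        raise ValueError("summarize needs at least one value")
    if v.size == 1:
        logger.warning("summarize: single value, SEM reported as 0")
        return float(v[0]), 0.0
    return float(np.mean(v)), float(np.std(v, ddof=1) / math.sqrt(v.size))


def bh_adjust(p_values) -> np.ndarray:
    """Benjamini-Hochberg adjusted p-values (optional; OFF by default).

    Provided for users who want FDR control across many band/state
    contrasts; the default reporting applies no multiple-testing correction.
    """
    from statsmodels.stats.multitest import multipletests

    p = np.asarray(p_values, dtype=float)
    return multipletests(p, method="fdr_bh")[1]
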