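"""Group-comparison statistics.

Nonparametric two-sample tests (Mann-Whitney U, two-sample
Kolmogorov-Smirnov, Fisher's exact test), all two-tailed, plus the two-stage
step-up false-discovery-rate procedure of Benjamini, Krieger and Yekutieli
(BKY) used to correct families of comparisons.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "TestResult",
    "mann_whitney",
    "ks_two_sample",
    "fisher_exact",
    "bky_fdr",
    "benjamini_hochberg",
]


@dataclass
class TestResult:
    """Outcome of one two-sample test."""

    test_name: str
    statistic: float
    p_value: float
    n1: int
    n2: int

    def __post_init__(self) -> None:
        if not 0.0 <= self.p_value <= 1.0:
            raise ValueError("p-value outside [0, 1]")

    def as_dict(self) -> dict:
        return {
            "test": self.test_name,
            "statistic": self.statistic,
            "p": self.p_value,
            "n1": self.n1,
            "n2": self.n2,
        }


def _check_samples(a, b) -> tuple[np.ndarray, np.ndarray]:
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if a.size == 0 or b.size == 0:
        raise ValueError("empty sample")
    return a, b


def mann_whitney(a: Sequence[float], b: Sequence[float]) -> TestResult:
    """Two-tailed Mann-Whitney U test.

    Exact enumeration for small samples (both n <= 8), otherwise the normal
    approximation with tie correction.
    """
    a, b = _check_samples(a, b)
    small = a.size <= 8 and b.size <= 8
    ties = np.unique(np.concatenate([a, b])).size < a.size + b.size
    method = "exact" if (small and not ties) else "asymptotic"
    res = stats.mannwhitneyu(a, b, alternative="two-sided", method=method)
    return TestResult("mann-whitney", float(res.statistic), float(res.pvalue),
                      a.size, b.size)


def ks_two_sample(a: Sequence[float], b: Sequence[float]) -> TestResult:
    """Two-sample Kolmogorov-Smirnov test; D = max |ECDF_a - ECDF_b|."""
    a, b = _check_samples(a, b)
    res = stats.ks_2samp(a, b, alternative="two-sided")
    return TestResult("kolmogorov-smirnov", float(res.statistic),
                      float(res.pvalue), a.size, b.size)


def fisher_exact(table: Sequence[Sequence[int]]) -> TestResult:
    """Two-tailed Fisher's exact test on a 2x2 count table."""
    t = np.asarray(table)
    if t.shape != (2, 2):
        raise ValueError("Fisher's exact test needs a 2x2 table")
    if np.any(t < 0):
        raise ValueError("table counts must be nonnegative")
    odds, p = stats.fisher_exact(t, alternative="two-sided")
    return TestResult("fisher-exact", float(odds), float(p),
                      int(t[0].sum()), int(t[1].sum()))


def _bh_adjust(p: np.ndarray) -> np.ndarray:
    """Benjamini-Hochberg adjusted p-values (monotone step-up)."""
    m = p.size
    order = np.argsort(p)
    ranked = p[order] * m / np.arange(1, m + 1)
    adjusted = np.minimum.accumulate(ranked[::-1])[::-1]
    out = np.empty(m)
    out[order] = np.minimum(adjusted, 1.0)
    return out


def benjamini_hochberg(
    p_values: Sequence[float], q_level: float = 0.05
) -> tuple[np.ndarray, np.ndarray]:
    """Plain BH linear step-up: (rejection flags, adjusted p-values)."""
    p = _validate_p(p_values)
    adj = _bh_adjust(p)
    return adj <= q_level, adj


def _validate_p(p_values) -> np.ndarray:
    p = np.asarray(p_values, dtype=float)
    if p.size == 0:
        raise ValueError("empty p-value list")
    if np.any((p < 0) | (p > 1)) or np.any(np.isnan(p)):
        raise ValueError("p-values must lie in [0, 1]")
    return p


def bky_fdr(
    p_values: Sequence[float], q_level: float = 0.05
) -> tuple[np.ndarray, np.ndarray]:
    """Two-stage step-up FDR control (BKY Definition 6).

    Stage 1 runs the BH step-up at the deflated level q' = q / (1 + q); the
    number of stage-1 rejections r1 estimates the number of true nulls as
    m0 = m - r1.  If r1 is 0 (nothing rejectable) or m (everything rejected)
    the stage-1 decision stands; otherwise stage 2 reruns BH at the inflated
    level q' * m / m0.

    Returns
    -------
    rejected : bool array
        Per-hypothesis rejection flags.
    q_values : float array
        Adjusted q-values calibrated to the supplied ``q_level``:
        ``rejected == (q_values <= q_level)`` (up to the clip at 1).  Because
        the m0 estimate depends on ``q_level``, these are not transferable to
        a different level.
    """
    p = _validate_p(p_values)
    m = p.size
    q_prime = q_level / (1.0 + q_level)
    adj = _bh_adjust(p)
    stage1 = adj <= q_prime
    r1 = int(stage1.sum())
    if r1 == 0 or r1 == m:
        qvals = np.minimum(adj * (1.0 + q_level), 1.0)
        return stage1, qvals
    m0 = m - r1
    rejected = adj <= q_prime * m / m0
    qvals = np.minimum(adj * (m0 / m) * (1.0 + q_level), 1.0)
    return rejected, qvals


def results_table(results: Sequence[tuple[str, TestResult]],
                  q_level: float = 0.05) -> pd.DataFrame:
    """Tidy table of named test results with BKY-adjusted q-values."""
    rows = [{"comparison": name, **r.as_dict()} for name, r in results]
    df = pd.DataFrame(rows)
    if len(df):
        rejected, q = bky_fdr(df["p"].to_numpy(), q_level)
        df["q"] = q
        df["significant"] = rejected
    return df
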