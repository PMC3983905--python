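"""Two-sample comparison statistics used throughout the analysis:
Kolmogorov-Smirnov, Welch's t, and Pearson correlation."""

from __future__ import annotations

import json
from dataclasses import dataclass, asdict

import numpy as np
from scipy import stats as sps

__all__ = ["TestResult", "ks_two_sample", "t_test_welch", "pearson_r"]


@dataclass(frozen=True)
class TestResult:
    test: str
    statistic: float
    p_value: float
    n_a: int
    n_b: int

    def to_json(self) -> str:
        return json.dumps(asdict(self))


def _as_sample(x, name: str, min_n: int = 2) -> np.ndarray:
    arr = np.asarray(x, dtype=float)
    if arr.ndim != 1:
        raise ValueError(f"sample {name} must be one-dimensional")
    if len(arr) < min_n:
        raise ValueError(f"sample {name} needs at least {min_n} values, got {len(arr)}")
    if not np.all(np.isfinite(arr)):
        raise ValueError(f"sample {name} contains non-finite values")
    return arr


def ks_two_sample(a, b) -> TestResult:
    """Two-sided two-sample KS test.

    D is the supremum ECDF distance; the p-value uses the asymptotic
    Kolmogorov distribution with effective n = n_a*n_b/(n_a+n_b),
    appropriate for the hundreds-to-thousands of genes compared here.
    """
    a = _as_sample(a, "a")
    b = _as_sample(b, "b")
    res = sps.ks_2samp(a, b, alternative="two-sided", method="asymp")
    return TestResult("ks_two_sample", float(res.statistic), float(min(res.pvalue, 1.0)), len(a), len(b))


def t_test_welch(a, b) -> TestResult:
    """Welch's unequal-variance t-test, two-sided p via Welch-Satterthwaite df."""
    a = _as_sample(a, "a")
    b = _as_sample(b, "b")
    if a.var(ddof=1) == 0 and b.var(ddof=1) == 0:
        raise ValueError("both samples have zero variance; t statistic undefined")
    res = sps.ttest_ind(a, b, equal_var=False)
    return TestResult("t_test_welch", float(res.statistic), float(res.pvalue), len(a), len(b))


def pearson_r(x, y) -> float:
    """Product-moment correlation; errors on degenerate (zero-variance) input."""
    x = _as_sample(x, "x", min_n=3)
    y = _as_sample(y, "y", min_n=3)
    if len(x) != len(y):
        raise ValueError(f"length mismatch: {len(x)} vs {len(y)}")
    if x.std() == 0:
        raise ValueError("sample x has zero variance")
    if y.std() == 0:
        raise ValueError("sample y has zero variance")
    return float(sps.pearsonr(x, y).statistic)
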