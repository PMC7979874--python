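"""Light inferential layer: t-tests, Cohen's d, multiplicity corrections."""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import stats as sps
from statsmodels.stats.multitest import multipletests

__all__ = ["TestResult", "t_test", "adjust_p"]


@dataclass(frozen=True)
class TestResult:
    statistic: float
    p_value: float
    df: float
    ci: tuple[float, float]
    effect_size_d: float
    tail: str
    kind: str


def _ci(mean: float, se: float, df: float, tail: str, alpha: float = 0.05) -> tuple[float, float]:
    if tail == "two":
        h = sps.t.ppf(1 - alpha / 2, df) * se
        return (mean - h, mean + h)
    h = sps.t.ppf(1 - alpha, df) * se
    # one-sided intervals follow the [lower, +inf) / (-inf, upper] style
    return (mean - h, np.inf) if tail == "greater" else (-np.inf, mean + h)


def t_test(sample, null_value: float = 0.0, paired=None, tail: str = "two") -> TestResult:
    """One-sample or paired t-test with Cohen's d.

    For a one-sample test, d = (mean - null) / SD of the sample; for a
    paired test, d = mean(diff) / SD(diff).  ``tail`` is "two", "greater"
    or "less".  Zero-variance input raises.
    """
    x = np.asarray(sample, dtype=float)
    if paired is not None:
        y = np.asarray(paired, dtype=float)
        if x.shape != y.shape:
            raise ValueError("paired samples must have equal length")
        x = x - y
        null_value = 0.0
        kind = "paired"
    else:
        kind = "one-sample"
    if x.size < 2:
        raise ValueError("need at least 2 observations")
    sd = x.std(ddof=1)
    if sd == 0:
        raise ValueError("zero-variance sample")
    alt = {"two": "two-sided", "greater": "greater", "less": "less"}[tail]
    res = sps.ttest_1samp(x, null_value, alternative=alt)
    df = x.size - 1
    mean = x.mean()
    return TestResult(
        statistic=float(res.statistic),
        p_value=float(res.pvalue),
        df=float(df),
        ci=_ci(mean, sd / np.sqrt(x.size), df, tail),
        effect_size_d=float((mean - null_value) / sd),
        tail=tail,
        kind=kind,
    )


def adjust_p(p_values, method: str = "fdr_bh") -> np.ndarray:
    """Multiple-comparison adjustment: Benjamini-Hochberg or Bonferroni."""
    p = np.asarray(p_values, dtype=float)
    if np.any((p < 0) | (p > 1)):
        raise ValueError("p values must lie in [0, 1]")
    if method == "none":
        return p.copy()
    if method not in ("fdr_bh", "bonferroni"):
        raise ValueError(f"unknown method: {method!r}")
    return multipletests(p, method=method)[1]
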