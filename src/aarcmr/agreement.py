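"""Agreement statistics: Bland-Altman, t tests, one-way ANOVA with Bonferroni.

Conventions follow the study's statistical layer: differences are taken as
method - reference (CMR - histology), limits of agreement use the classic
1.96 x SD of the paired differences, the unpaired t test pools variances by
default (Welch available), and pairwise post-hoc p-values are Bonferroni
multiplied by the number of pairwise comparisons, capped at 1.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np
import pandas as pd
from scipy import stats as sps


@dataclass
class BlandAltmanResult:
    n: int
    bias: float
    sd_diff: float
    loa_low: float
    loa_high: float
    method: str = "method"
    reference: str = "reference"


@dataclass
class TestResult:
    name: str
    statistic: float
    df: float
    p: float
    p_adjusted: Optional[float] = None
    groups: Optional[tuple] = None
    n: Optional[tuple] = None


def _as1d(x) -> np.ndarray:
    a = np.asarray(x, dtype=float).ravel()
    return a


def bland_altman(reference, method, reference_label: str = "reference",
                 method_label: str = "method") -> BlandAltmanResult:
    """Bias (mean of method - reference) and 1.96*SD limits of agreement."""
    ref, met = _as1d(reference), _as1d(method)
    if len(ref) != len(met):
        raise ValueError("reference and method must be paired (equal lengths)")
    if len(ref) < 2:
        raise ValueError("Bland-Altman needs at least 2 pairs")
    d = met - ref
    bias = float(np.mean(d))
    sd = float(np.std(d, ddof=1))
    return BlandAltmanResult(len(d), bias, sd, bias - 1.96 * sd, bias + 1.96 * sd,
                             method_label, reference_label)


def paired_t(reference, method) -> TestResult:
    """Two-sided paired t test on method - reference.

    Zero-variance edge cases are resolved by the limit: all-zero differences
    give t = 0, p = 1; constant nonzero differences give p = 0.
    """
    ref, met = _as1d(reference), _as1d(method)
    if len(ref) != len(met) or len(ref) < 2:
        raise ValueError("paired t needs >= 2 pairs of equal length")
    d = met - ref
    n = len(d)
    sd = np.std(d, ddof=1)
    if sd == 0:
        if np.mean(d) == 0:
            return TestResult("paired_t", 0.0, n - 1, 1.0, n=(n,))
        return TestResult("paired_t", float(np.sign(np.mean(d)) * np.inf), n - 1, 0.0, n=(n,))
    t = float(np.mean(d) / (sd / np.sqrt(n)))
    p = float(2.0 * sps.t.sf(abs(t), n - 1))
    return TestResult("paired_t", t, n - 1, p, n=(n,))


def unpaired_t(group_a, group_b, welch: bool = False) -> TestResult:
    """Two-sided two-sample t test (pooled variance by default)."""
    a, b = _as1d(group_a), _as1d(group_b)
    if len(a) < 2 or len(b) < 2:
        raise ValueError("each group needs n >= 2")
    if np.std(a, ddof=1) == 0 and np.std(b, ddof=1) == 0:
        if np.mean(a) == np.mean(b):
            df = len(a) + len(b) - 2
            return TestResult("unpaired_t", 0.0, df, 1.0, n=(len(a), len(b)))
        df = len(a) + len(b) - 2
        return TestResult("unpaired_t", float(np.sign(np.mean(a) - np.mean(b)) * np.inf),
                          df, 0.0, n=(len(a), len(b)))
    res = sps.ttest_ind(a, b, equal_var=not welch)
    df = float(res.df) if hasattr(res, "df") else (len(a) + len(b) - 2)
    return TestResult("unpaired_t" + ("_welch" if welch else ""), float(res.statistic),
                      df, float(res.pvalue), n=(len(a), len(b)))


def anova_bonferroni(groups: Sequence, labels: Optional[Sequence[str]] = None) -> list:
    """One-way ANOVA plus all pairwise t tests with Bonferroni adjustment.

    Returns [omnibus TestResult, pairwise TestResult, ...]; pairwise adjusted
    p = min(1, raw * m) with m the number of pairwise comparisons.
    """
    arrays = [_as1d(g) for g in groups]
    if len(arrays) < 2:
        raise ValueError("ANOVA needs at least 2 groups")
    if any(len(a) < 2 for a in arrays):
        raise ValueError("every group needs n >= 2")
    if labels is None:
        labels = [f"group{i + 1}" for i in range(len(arrays))]
    grand = np.concatenate(arrays)
    if np.std(grand, ddof=0) == 0:
        k = len(arrays)
        omnibus = TestResult("anova", 0.0, float(k - 1), 1.0,
                             groups=tuple(labels), n=tuple(len(a) for a in arrays))
    else:
        f, p = sps.f_oneway(*arrays)
        omnibus = TestResult("anova", float(f), float(len(arrays) - 1), float(p),
                             groups=tuple(labels), n=tuple(len(a) for a in arrays))
    results = [omnibus]
    pairs = list(itertools.combinations(range(len(arrays)), 2))
    m = len(pairs)
    for i, j in pairs:
        t = unpaired_t(arrays[i], arrays[j])
        adj = min(1.0, t.p * m)
        results.append(TestResult("pairwise_t_bonferroni", t.statistic, t.df, t.p,
                                  p_adjusted=adj, groups=(labels[i], labels[j]),
                                  n=(len(arrays[i]), len(arrays[j]))))
    return results


def group_summary(df: pd.DataFrame, value_columns: Sequence[str],
                  by: str = "group") -> pd.DataFrame:
    """mean, sample SD, n and a formatted "mean +/- SD" per group and column."""
    records = []
    for g, sub in df.groupby(by, sort=False):
        for col in value_columns:
            v = sub[col].dropna().to_numpy(dtype=float)
            n = len(v)
            mean = float(np.mean(v)) if n else float("nan")
            sd = float(np.std(v, ddof=1)) if n > 1 else float("nan")
            if n == 0:
                text = ""
            elif n == 1:
                text = f"{mean:.1f}"
            else:
                text = f"{mean:.1f} ± {sd:.1f}"
            records.append({by: g, "metric": col, "mean": mean, "sd": sd,
                            "n": n, "summary": text})
    return pd.DataFrame.from_records(records)
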