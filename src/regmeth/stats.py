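"""Statistical primitives: Wilcoxon rank-sum, BH FDR, Pearson inference.

The Pearson machinery follows R's ``cor.test`` conventions: the two-sided
p-value comes from t = r*sqrt(df/(1-r^2)) on df = n-2 degrees of freedom,
and the 95% confidence interval from the Fisher z transform
tanh(atanh(r) +/- 1.959964/sqrt(n-3)).
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass
from typing import Dict, List, Sequence, Tuple

import numpy as np
from scipy import stats as _sps
from statsmodels.stats.multitest import multipletests

__all__ = [
    "CorrelationResult",
    "wilcoxon_rank_sum",
    "bh_fdr",
    "pearson_test",
    "pearson_from_t",
    "fisher_z_interval",
    "relative_tfbs_change",
    "signal_vs_methylation_correlation",
]

_Z95 = 1.959964  # R cor.test's 97.5% normal quantile


@dataclass
class CorrelationResult:
    r: float
    n: int
    df: int
    t: float
    pvalue: float
    ci_low: float
    ci_high: float


def wilcoxon_rank_sum(
    x: Sequence[float], y: Sequence[float], alternative: str = "two_sided"
) -> Tuple[float, float]:
    """Wilcoxon rank-sum (Mann-Whitney) test of x against y.

    Exact null distribution when min(n1, n2) <= 10 and the data are
    tie-free; otherwise the normal approximation with tie-corrected
    variance and continuity correction. Returns (U statistic of x, p).

    ``alternative='greater'`` tests whether x tends to exceed y.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size == 0 or y.size == 0:
        raise ValueError("wilcoxon_rank_sum: empty input")
    alt = {"two_sided": "two-sided", "less": "less", "greater": "greater"}[alternative]
    pooled = np.concatenate([x, y])
    has_ties = np.unique(pooled).size < pooled.size
    if np.ptp(pooled) == 0:
        # all values identical: no evidence either way
        u = x.size * y.size / 2.0
        return u, 1.0
    method = "exact" if (min(x.size, y.size) <= 10 and not has_ties) else "asymptotic"
    res = _sps.mannwhitneyu(x, y, alternative=alt, method=method, use_continuity=True)
    return float(res.statistic), float(res.pvalue)


def bh_fdr(pvalues: Sequence[float]) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p-values, in input order."""
    p = np.asarray(pvalues, dtype=float)
    if p.size == 0:
        return p
    if np.any((p < 0) | (p > 1) | ~np.isfinite(p)):
        raise ValueError("bh_fdr: p-values must lie in [0, 1]")
    return multipletests(p, method="fdr_bh")[1]


def fisher_z_interval(r: float, n: int, z_crit: float = _Z95) -> Tuple[float, float]:
    """Fisher-z confidence interval for a Pearson correlation.

    At |r| = 1 atanh diverges; the interval collapses onto the point, which
    mirrors the degenerate certainty of a perfectly collinear sample.
    """
    if n < 4:
        return (-1.0, 1.0)
    if abs(r) >= 1.0:
        return (r, r)
    h = z_crit / math.sqrt(n - 3)
    z = math.atanh(r)
    return (math.tanh(z - h), math.tanh(z + h))


def pearson_test(x: Sequence[float], y: Sequence[float]) -> CorrelationResult:
    """Pearson product-moment correlation with t-based p and Fisher-z CI."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size != y.size:
        raise ValueError("pearson_test: length mismatch")
    n = int(x.size)
    if n < 3:
        raise ValueError("pearson_test: need n >= 3")
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        raise ValueError("pearson_test: zero variance input, r undefined")
    r = float(np.corrcoef(x, y)[0, 1])
    r = max(-1.0, min(1.0, r))
    df = n - 2
    if abs(r) == 1.0:
        t = math.copysign(math.inf, r)
        p = 0.0
    else:
        t = r * math.sqrt(df / (1.0 - r * r))
        p = 2.0 * float(_sps.t.sf(abs(t), df))
    lo, hi = fisher_z_interval(r, n)
    return CorrelationResult(r=r, n=n, df=df, t=t, pvalue=p, ci_low=lo, ci_high=hi)


def pearson_from_t(t: float, df: int) -> float:
    """Recover r from a printed t statistic and its degrees of freedom."""
    if df < 1:
        raise ValueError("pearson_from_t: df must be >= 1")
    return t / math.sqrt(df + t * t)


def correlation_from_t(t: float, df: int) -> CorrelationResult:
    """Full correlation inference from a printed (t, df) pair (n = df + 2)."""
    r = pearson_from_t(t, df)
    n = df + 2
    p = 2.0 * float(_sps.t.sf(abs(t), df))
    lo, hi = fisher_z_interval(r, n)
    return CorrelationResult(r=r, n=n, df=df, t=t, pvalue=p, ci_low=lo, ci_high=hi)


def relative_tfbs_change(
    delta_motif_a: Dict[Tuple[str, str], float],
    delta_all_a: Dict[str, float],
    delta_motif_b: Dict[Tuple[str, str], float],
    delta_all_b: Dict[str, float],
    relative: str = "diff",
) -> Tuple[CorrelationResult, List[Tuple[str, str]]]:
    """Correlate two cohorts' motif-specific methylation changes.

    For each (motif, cell type) pair, the relative change is the cohort's
    average methylation difference at motif-bearing open chromatin of that
    cell type, relative to the difference at all open chromatin of the
    type: ``diff`` (default) subtracts, ``ratio`` divides. The Pearson test
    then runs across all pairs present in both cohorts; missing pairs are
    dropped with a warning.
    """
    if relative not in ("diff", "ratio"):
        raise ValueError("relative must be 'diff' or 'ratio'")

    def rel(dm: float, da: float) -> float:
        return dm - da if relative == "diff" else dm / da

    keys = sorted(set(delta_motif_a) & set(delta_motif_b))
    dropped = sorted(set(delta_motif_a) ^ set(delta_motif_b))
    if dropped:
        warnings.warn(f"dropping {len(dropped)} (motif, cell type) pairs missing in one cohort")
    xs = [rel(delta_motif_a[k], delta_all_a[k[1]]) for k in keys]
    ys = [rel(delta_motif_b[k], delta_all_b[k[1]]) for k in keys]
    return pearson_test(xs, ys), keys


def signal_vs_methylation_correlation(
    signal_diff: Sequence[float],
    meth_diff: Sequence[float],
    wildtype_signal: Sequence[float],
    min_signal: float = 10.0,
) -> Tuple[CorrelationResult, int]:
    """Correlate per-unit signal change with methylation change.

    Units (e.g. CpG islands) whose average wild-type signal falls below
    ``min_signal`` are excluded before testing, so weakly covered units do
    not drive the correlation. Returns the result and the survivor count.
    """
    sd = np.asarray(signal_diff, dtype=float)
    md = np.asarray(meth_diff, dtype=float)
    wt = np.asarray(wildtype_signal, dtype=float)
    if not (sd.size == md.size == wt.size):
        raise ValueError("aligned per-unit vectors required")
    keep = wt >= min_signal
    n_kept = int(keep.sum())
    if n_kept < 3:
        raise ValueError(f"only {n_kept} units pass the min_signal filter; need >= 3")
    return pearson_test(sd[keep], md[keep]), n_kept
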