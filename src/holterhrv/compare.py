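"""Paired before/after comparison and dose-association regression.

The paired Wilcoxon signed-rank test is computed exactly: zero differences
are dropped (Wilcoxon's original treatment), absolute differences receive
average ranks under ties, and the two-sided p-value comes from the exact
null distribution of the positive-rank sum W, built by dynamic programming
over doubled ranks (doubling makes tied average ranks integral).  For more
than 25 informative pairs a normal approximation with tie correction is used.

Regression of per-patient changes against pulse-delivery parameters is
ordinary least squares with the usual two-sided t-test on the slope.
"""

from __future__ import annotations

import numpy as np
from scipy import stats as sps

from .types import AnalysisError, ComparisonRow, RegressionRow

EXACT_N_MAX = 25


def _exact_wilcoxon_p(w2: int, ranks2: np.ndarray) -> float:
    """Two-sided exact p for doubled statistic ``w2`` given doubled ranks."""
    total = int(ranks2.sum())
    # counts[s] = number of sign assignments with doubled positive-rank sum s
    counts = np.zeros(total + 1)
    counts[0] = 1.0
    for r in ranks2:
        shifted = np.zeros_like(counts)
        shifted[r:] = counts[: counts.size - r]
        counts = counts + shifted
    n_total = counts.sum()
    lo = counts[: w2 + 1].sum() / n_total  # P(W2 <= w2)
    hi = counts[w2:].sum() / n_total       # P(W2 >= w2)
    return float(min(1.0, 2.0 * min(lo, hi)))


def wilcoxon_exact_p(diffs: np.ndarray) -> tuple[float, float]:
    """(W, two-sided p) for paired differences; exact for n <= 25."""
    d = np.asarray(diffs, dtype=float)
    d = d[d != 0]
    n = d.size
    if n == 0:
        return 0.0, 1.0
    ranks = sps.rankdata(np.abs(d))
    w = float(ranks[d > 0].sum())
    if n <= EXACT_N_MAX:
        ranks2 = np.round(2 * ranks).astype(int)
        p = _exact_wilcoxon_p(int(round(2 * w)), ranks2)
    else:
        mu = n * (n + 1) / 4.0
        # variance with tie correction
        var = (ranks**2).sum() / 4.0
        z = (w - mu) / np.sqrt(var)
        p = float(2.0 * sps.norm.sf(abs(z)))
    return w, p


def paired_wilcoxon(
    before: np.ndarray, after: np.ndarray, min_n: int = 5
) -> tuple[float, float, float, float]:
    """(median change, 25th pct, 75th pct, p) for paired per-patient values.

    Change is after - before.  Quartiles use linear interpolation between
    order statistics.  Requires at least ``min_n`` non-zero differences;
    an all-zero difference vector reports p = 1.
    """
    b = np.asarray(before, dtype=float)
    a = np.asarray(after, dtype=float)
    if b.size != a.size:
        raise AnalysisError("paired_wilcoxon: unequal vector lengths")
    ok = np.isfinite(b) & np.isfinite(a)
    d = a[ok] - b[ok]
    if d.size == 0:
        raise AnalysisError("paired_wilcoxon: no finite pairs")
    nz = np.count_nonzero(d)
    if nz == 0:
        med, q25, q75 = (float(np.percentile(d, q)) for q in (50, 25, 75))
        return med, q25, q75, 1.0
    if nz < min_n:
        raise AnalysisError(
            f"paired_wilcoxon: only {nz} non-zero differences (need >= {min_n})"
        )
    _, p = wilcoxon_exact_p(d)
    med = float(np.percentile(d, 50))
    q25 = float(np.percentile(d, 25))
    q75 = float(np.percentile(d, 75))
    return med, q25, q75, p


def compare_row(
    parameter: str, before: np.ndarray, after: np.ndarray, min_n: int = 5
) -> ComparisonRow:
    med, q25, q75, p = paired_wilcoxon(before, after, min_n=min_n)
    return ComparisonRow(
        parameter=parameter,
        median_change=med,
        pct25=q25,
        pct75=q75,
        p_value=p,
        n=int(np.count_nonzero(np.isfinite(np.asarray(before)) & np.isfinite(np.asarray(after)))),
    )


def regress_changes(
    delta: np.ndarray, dose: np.ndarray, delta_name: str = "", dose_name: str = ""
) -> RegressionRow:
    """OLS of per-patient changes on a pulse-delivery parameter."""
    y = np.asarray(delta, dtype=float)
    x = np.asarray(dose, dtype=float)
    ok = np.isfinite(x) & np.isfinite(y)
    x, y = x[ok], y[ok]
    if x.size < 3:
        raise AnalysisError(f"regress_changes: need at least 3 points, got {x.size}")
    if np.var(x) == 0:
        raise AnalysisError("regress_changes: zero variance in dose parameter")
    fit = sps.linregress(x, y)
    return RegressionRow(
        delta_parameter=delta_name,
        dose_parameter=dose_name,
        slope=float(fit.slope),
        r=float(fit.rvalue),
        p_value=float(fit.pvalue),
    )
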