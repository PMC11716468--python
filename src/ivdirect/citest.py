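"""Conditional independence test engines for stratified categorical data.

Two engines test ``Z ⊥ Y | S`` for a binary instrument Z, an ordinal outcome
Y and a discrete stratification S (here, propensity-score strata):

``mi_g2``
    The conditional mutual information G-test.  For stratified counts
    ``n_szy`` the statistic is the likelihood-ratio deviance

        G² = 2 Σ_{s,z,y} n_szy · ln( n_szy · n_s / (n_sz · n_sy) ),

    which equals ``2·N·MI(Z;Y|S)`` for the empirical distribution.  Degrees
    of freedom accumulate per stratum over levels with positive marginals,
    df = Σ_s (R_s−1)(C_s−1), so sparse strata do not inflate the reference
    distribution.

``cmh``
    The generalized Cochran–Mantel–Haenszel statistic (general association,
    no continuity correction) for a 2×C table over K strata, df = C−1.

Both are referred to the chi-square upper tail and report Cramér's V with a
Cohen practical-significance label.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .errors import DegenerateTableError

__all__ = [
    "CITestResult",
    "conditional_mi_test",
    "cmh_test",
    "cramers_v",
    "stratified_counts",
]

#: Cohen's thresholds for Cramér's V at min-dimension 2 (divide by sqrt(df*))
_COHEN = (0.1, 0.3, 0.5)


@dataclass
class CITestResult:
    """Outcome of one (conditional) independence test."""

    engine: str  # mi_g2 | cmh | pearson_chi2
    statistic: float
    df: int
    p_value: float
    n: int
    cramers_v: float
    cohen_label: str
    strata_used: int

    def significant(self, alpha: float = 0.05) -> bool:
        """Strict-inequality rejection at level alpha (p == alpha retains H0)."""
        return self.p_value < alpha


def cramers_v(
    statistic: float, n: int, r_levels: int, c_levels: int
) -> tuple[float, str]:
    """Cramér's V = sqrt(X² / (n·(min(r,c)−1))), truncated to [0, 1].

    The Cohen label uses thresholds 0.1 / 0.3 / 0.5 scaled by
    ``1/sqrt(min(r,c)−1)``: below the first is "negligible", then "low",
    "moderate", "large".
    """
    if n <= 0:
        raise ValueError("n must be positive")
    k = min(r_levels, c_levels) - 1
    if k < 1:
        raise ValueError("both margins need at least 2 levels")
    v = float(np.sqrt(max(statistic, 0.0) / (n * k)))
    v = min(v, 1.0)
    scale = np.sqrt(k)
    low, moderate, large = (t / scale for t in _COHEN)
    if v >= large:
        label = "large"
    elif v >= moderate:
        label = "moderate"
    elif v >= low:
        label = "low"
    else:
        label = "negligible"
    return v, label


def _as_labels(strata) -> np.ndarray:
    # accept a StratumAssignment or any array-like of labels
    labels = getattr(strata, "labels", strata)
    return np.asarray(labels)


def stratified_counts(z, y, strata) -> np.ndarray:
    """Aligned (K, R, C) count array over observed stratum/z/y levels.

    Rows where any of z, y or the stratum label is missing are excluded.
    """
    z = np.asarray(z, dtype=float)
    y = np.asarray(y, dtype=float)
    s = _as_labels(strata).astype(float)
    if not (len(z) == len(y) == len(s)):
        raise ValueError("z, y and strata must be aligned on the same records")
    ok = ~(np.isnan(z) | np.isnan(y) | np.isnan(s))
    z, y, s = z[ok], y[ok], s[ok]
    if z.size == 0:
        raise DegenerateTableError("no complete records to test")
    z_lev = np.unique(z)
    y_lev = np.unique(y)
    s_lev = np.unique(s)
    zi = np.searchsorted(z_lev, z)
    yi = np.searchsorted(y_lev, y)
    si = np.searchsorted(s_lev, s)
    counts = np.zeros((len(s_lev), len(z_lev), len(y_lev)))
    np.add.at(counts, (si, zi, yi), 1.0)
    return counts


def g2_from_counts(counts: np.ndarray) -> tuple[float, int]:
    """G² statistic and df from a (K, R, C) stratified count array.

    Zero cells contribute 0 (0·ln 0 := 0); per-stratum df counts only z/y
    levels with a positive marginal in that stratum.
    """
    g2 = 0.0
    df = 0
    for tab in counts:
        n_s = tab.sum()
        if n_s == 0:
            continue
        rz = tab.sum(axis=1)  # z marginals
        cy = tab.sum(axis=0)  # y marginals
        with np.errstate(divide="ignore", invalid="ignore"):
            expected = np.outer(rz, cy) / n_s
            ratio = np.where(tab > 0, tab * n_s / np.outer(rz, cy), 1.0)
            g2 += 2.0 * np.sum(np.where(tab > 0, tab * np.log(ratio), 0.0))
        r_pos = int((rz > 0).sum())
        c_pos = int((cy > 0).sum())
        if r_pos >= 2 and c_pos >= 2:
            df += (r_pos - 1) * (c_pos - 1)
    return float(max(g2, 0.0)), df


def conditional_mi_test(z, y, strata) -> CITestResult:
    """Conditional mutual information G-test of Z ⊥ Y given strata."""
    counts = stratified_counts(z, y, strata)
    g2, df = g2_from_counts(counts)
    if df == 0:
        raise DegenerateTableError(
            "all strata are degenerate on z or y (zero degrees of freedom)"
        )
    n = int(counts.sum())
    p = float(stats.chi2.sf(g2, df))
    r = int((counts.sum(axis=(0, 2)) > 0).sum())
    c = int((counts.sum(axis=(0, 1)) > 0).sum())
    v, label = cramers_v(g2, n, r, c)
    return CITestResult(
        engine="mi_g2",
        statistic=g2,
        df=df,
        p_value=p,
        n=n,
        cramers_v=v,
        cohen_label=label,
        strata_used=int(counts.shape[0]),
    )


def cmh_test(z, y, strata) -> CITestResult:
    """Generalized CMH general-association test of a stratified 2×C table.

    Q = U' V⁻ U with U the summed deviations of the first row's category
    counts from their conditional expectations and V the summed multivariate
    hypergeometric covariances; df = C−1.  No continuity correction.
    """
    counts = stratified_counts(z, y, strata)
    K, R, C = counts.shape
    if R < 2:
        raise DegenerateTableError("z has fewer than 2 observed levels")
    if C < 2:
        raise DegenerateTableError("y has fewer than 2 observed levels")
    if R != 2:
        raise ValueError("cmh engine requires a binary z")
    u = np.zeros(C - 1)
    v = np.zeros((C - 1, C - 1))
    for tab in counts:
        n_s = tab.sum()
        if n_s < 2:
            continue
        row1 = tab[1]  # counts for z = 1
        n1 = tab[1].sum()
        n0 = tab[0].sum()
        col = tab.sum(axis=0)
        if n1 == 0 or n0 == 0:
            continue
        p_col = col / n_s
        u += row1[:-1] - n1 * p_col[:-1]
        # multivariate hypergeometric covariance of row1[:-1]
        pc = p_col[:-1]
        v += (n1 * n0 / (n_s - 1)) * (np.diag(pc) - np.outer(pc, pc))
    if not np.any(np.abs(v) > 0):
        raise DegenerateTableError("no stratum contributes information")
    stat = float(u @ np.linalg.pinv(v) @ u)
    df = C - 1
    n = int(counts.sum())
    p = float(stats.chi2.sf(stat, df))
    vv, label = cramers_v(stat, n, R, C)
    return CITestResult(
        engine="cmh",
        statistic=stat,
        df=df,
        p_value=p,
        n=n,
        cramers_v=vv,
        cohen_label=label,
        strata_used=K,
    )


ENGINES = {"mi_g2": conditional_mi_test, "cmh": cmh_test}
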