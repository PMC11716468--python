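"""Multiple imputation of categorical confounders and p-value pooling.

Missing confounder cells are filled by chained equations: each incomplete
categorical confounder is modelled by multinomial logistic regression on the
other confounders plus the instrument Z, the intervention T and the outcomes,
cycled for a fixed number of iterations, with imputed categories drawn from
the fitted class probabilities.  Z, T and the outcomes are never imputed;
rows missing them are handled downstream.  Repeating this m times with
different seeds yields an :class:`ImputationSet`; the conditional independence
tests run on every completed table and their p-values are pooled (median by
default) so that no single imputation drives the conclusion.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats
from sklearn.linear_model import LogisticRegression

from .errors import ConfigurationError
from .survey import StudyTable

__all__ = ["ImputationSet", "mice_impute", "pool_pvalues"]

_NA_TOKEN = "__na__"  # missing-indicator category for non-imputed predictors


@dataclass
class ImputationSet:
    """m completed copies of a study table, differing only in imputed cells."""

    tables: list[StudyTable]
    seeds: list[int]
    imputed_columns: list[str]
    trace: dict = field(default_factory=dict)

    @property
    def m(self) -> int:
        return len(self.tables)

    def __iter__(self):
        return iter(self.tables)


def _predictor_frame(
    df: pd.DataFrame, target: str, predictor_cols: Sequence[str]
) -> pd.DataFrame:
    """Dummy-encoded predictors with missing-as-category for non-imputed ones."""
    cols = [c for c in predictor_cols if c != target]
    sub = df[cols].copy()
    for c in cols:
        sub[c] = sub[c].astype(object).where(sub[c].notna(), _NA_TOKEN).astype(str)
    return pd.get_dummies(sub.astype("category"), drop_first=True, dtype=float)


def mice_impute(
    table: StudyTable,
    m: int = 100,
    seeds: Sequence[int] | None = None,
    iterations: int = 10,
    base_seed: int = 0,
) -> ImputationSet:
    """Chained-equation multiple imputation of the categorical confounders.

    Parameters
    ----------
    table : StudyTable
        Table whose confounder columns may contain NaN.
    m : int
        Number of completed datasets (survey analyses typically use 100).
    seeds : sequence of int, optional
        One seed per completed dataset; defaults to ``base_seed + 1..m``.
    iterations : int
        Chained-equation cycles per dataset.

    Returns
    -------
    ImputationSet
        All m tables share every observed cell bit-for-bit; only cells that
        were missing in a confounder differ.
    """
    if m <= 0:
        raise ValueError("m must be positive")
    if seeds is None:
        seeds = [base_seed + k for k in range(1, m + 1)]
    seeds = list(seeds)
    if len(seeds) != m:
        raise ValueError("need exactly m seeds")

    df = table.df
    targets = [c for c in table.confounders if df[c].isna().any()]
    for c in table.confounders:
        if df[c].dropna().nunique() < 2 and df[c].isna().any():
            raise ConfigurationError(
                f"confounder {c!r} has a single observed level; cannot impute"
            )

    if not targets:
        return ImputationSet(
            tables=[table.copy() for _ in range(m)],
            seeds=seeds,
            imputed_columns=[],
        )

    predictor_cols = (
        list(table.confounders)
        + [table.iv, table.intervention]
        + list(table.outcomes)
    )

    completed: list[StudyTable] = []
    trace: dict[str, list[int]] = {c: [int(df[c].isna().sum())] for c in targets}
    for seed in seeds:
        rng = np.random.default_rng(seed)
        work = df.copy()
        # initialize each missing cell from the observed marginal
        for c in targets:
            miss = work[c].isna()
            obs = work.loc[~miss, c].to_numpy()
            work.loc[miss, c] = rng.choice(obs, size=int(miss.sum()), replace=True)
        for _ in range(iterations):
            for c in targets:
                miss = df[c].isna()
                X = _predictor_frame(work, c, predictor_cols)
                y_obs = df.loc[~miss, c].astype(float)
                clf = LogisticRegression(max_iter=500)
                clf.fit(X.loc[~miss].to_numpy(), y_obs.to_numpy())
                probs = clf.predict_proba(X.loc[miss].to_numpy())
                # draw from fitted category probabilities
                cum = probs.cumsum(axis=1)
                u = rng.random((probs.shape[0], 1))
                idx = (u > cum).sum(axis=1)
                work.loc[miss, c] = clf.classes_[idx]
        completed.append(table.with_df(work))
    return ImputationSet(
        tables=completed, seeds=seeds, imputed_columns=targets, trace=trace
    )


def pool_pvalues(pvals: Sequence[float], rule: str = "median") -> float:
    """Pool m per-imputation p-values into one reported p-value.

    Rules
    -----
    ``median`` (default)
        The sample median; valid without distributional assumptions and
        insensitive to a single unstable imputation.
    ``mean``
        The arithmetic mean.
    ``licht_rubin``
        Probit transform z_i = Φ⁻¹(1−p_i), Rubin's rules on z (within-
        imputation variance 1), pooled p = 1 − Φ(z̄ / sqrt(T)).
    """
    p = np.asarray(list(pvals), dtype=float)
    if p.size == 0:
        raise ValueError("need at least one p-value")
    if np.any((p < 0) | (p > 1)) or np.any(np.isnan(p)):
        raise ValueError("p-values must lie in [0, 1]")
    if rule == "median":
        return float(np.median(p))
    if rule == "mean":
        return float(np.mean(p))
    if rule == "licht_rubin":
        if p.size == 1:
            return float(p[0])
        z = stats.norm.isf(np.clip(p, 1e-15, 1 - 1e-15))
        zbar = z.mean()
        b = z.var(ddof=1)
        total = 1.0 + (1.0 + 1.0 / p.size) * b
        return float(stats.norm.sf(zbar / np.sqrt(total)))
    raise ValueError(f"unknown pooling rule {rule!r}")
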