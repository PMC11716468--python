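"""Propensity-score estimation for the instrument and quantile stratification.

Two scores are used as conditioning sets: ``π_X1 = P(Z=1 | X1)`` and
``π_X1T = P(Z=1 | X1, T)``.  Each is fitted by maximum-likelihood logistic
regression on dummy-encoded categorical predictors (T enters as a five-level
categorical, not a numeric score) and then discretized at empirical quantiles
into K strata (default 5).  Strata that are too small or degenerate on Z are
merged with their nearest neighbour so every retained stratum carries
information about the instrument.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from sklearn.exceptions import ConvergenceWarning
from sklearn.linear_model import LogisticRegression

from .errors import EstimationError
from .survey import StudyTable

__all__ = ["PropensityModel", "StratumAssignment", "fit_propensity", "assign_strata"]

_SCORE_EPS = 1e-12


@dataclass
class PropensityModel:
    """Fitted logistic propensity model for the binary instrument."""

    include_T: bool
    feature_names: list[str]
    coef: pd.Series  # intercept + dummy coefficients
    scores: np.ndarray  # fitted P(Z=1 | predictors), strictly in (0,1)
    z: np.ndarray  # observed instrument, aligned with scores
    converged: bool
    ridge_used: bool


@dataclass
class StratumAssignment:
    """Discretized propensity score: the conditioning variable of the tests."""

    K_requested: int
    K_final: int
    breakpoints: np.ndarray
    labels: np.ndarray  # stratum index per record, 0..K_final-1
    counts: np.ndarray = field(default_factory=lambda: np.array([]))


def _design(
    table: StudyTable, include_T: bool
) -> tuple[pd.DataFrame, np.ndarray, pd.DataFrame]:
    df = table.df
    cols = list(table.confounders)
    if include_T:
        cols = cols + [table.intervention]
    sub = df[cols + [table.iv]]
    if sub.isna().any().any():
        raise ValueError(
            "propensity fit requires complete Z, predictors (run on imputed "
            "tables with missing T/outcome rows already excluded)"
        )
    cat = sub[cols].astype("category")
    for c in cols:
        if cat[c].nunique() < 2:
            raise ValueError(f"predictor {c!r} has a single observed level")
    X = pd.get_dummies(cat, drop_first=True, dtype=float)
    z = sub[table.iv].to_numpy(dtype=float)
    return X, z, sub


def fit_propensity(
    table: StudyTable,
    include_T: bool = False,
    ridge_penalty: float = 1.0,
    max_iter: int = 1000,
) -> PropensityModel:
    """ML logistic regression of Z on X1 (and categorical T when requested).

    On non-convergence or quasi-separation the fit falls back to a small L2
    ridge penalty; if the fallback also fails an :class:`EstimationError`
    carrying diagnostics is raised.  Fitted scores are clipped strictly
    inside (0, 1).
    """
    X, z, _ = _design(table, include_T)
    xmat = X.to_numpy()

    def _fit(penalized: bool):
        kwargs = (
            {"penalty": "l2", "C": 1.0 / ridge_penalty}
            if penalized
            else {"penalty": None}
        )
        clf = LogisticRegression(solver="lbfgs", max_iter=max_iter, **kwargs)
        with warnings.catch_warnings(record=True) as caught:
            warnings.simplefilter("always", ConvergenceWarning)
            clf.fit(xmat, z)
            conv = not any(
                issubclass(w.category, ConvergenceWarning) for w in caught
            )
        # huge coefficients signal (quasi-)separation even when lbfgs "converges"
        separated = np.max(np.abs(clf.coef_)) > 8.0
        return clf, conv and not separated

    clf, ok = _fit(penalized=False)
    ridge_used = False
    if not ok:
        clf, ok = _fit(penalized=True)
        ridge_used = True
        if not ok:
            raise EstimationError(
                "propensity model did not converge even with ridge fallback "
                f"(include_T={include_T}, p={xmat.shape[1]} predictors, "
                f"n={len(z)})"
            )
    scores = np.clip(clf.predict_proba(xmat)[:, 1], _SCORE_EPS, 1 - _SCORE_EPS)
    coef = pd.Series(
        np.concatenate([clf.intercept_, clf.coef_.ravel()]),
        index=["(intercept)"] + list(X.columns),
    )
    return PropensityModel(
        include_T=include_T,
        feature_names=list(X.columns),
        coef=coef,
        scores=scores,
        z=z,
        converged=True,
        ridge_used=ridge_used,
    )


def assign_strata(
    model: PropensityModel | np.ndarray,
    K: int = 5,
    min_stratum_size: int = 20,
    z: np.ndarray | None = None,
) -> StratumAssignment:
    """Bin propensity scores into K quantile strata, merging thin strata.

    Breakpoints are the linearly interpolated empirical quantiles at
    j/K (j = 1..K−1); bins are left-closed, right-open, with the top bin
    closed.  Duplicate breakpoints collapse (ties share a bin).  Strata with
    fewer than ``min_stratum_size`` records, or where Z takes a single value,
    are merged into the nearest (smaller-count) neighbour; the final number
    of strata K' ≤ K is reported.
    """
    if K < 1:
        raise ValueError("K must be >= 1")
    if isinstance(model, PropensityModel):
        scores = model.scores
        if z is None:
            z = model.z
    else:
        scores = np.asarray(model, dtype=float)
    if K == 1:
        labels = np.zeros(len(scores), dtype=int)
        return StratumAssignment(1, 1, np.array([]), labels, np.array([len(scores)]))

    q = np.quantile(scores, np.arange(1, K) / K)
    breakpoints = np.unique(q)
    labels = np.searchsorted(breakpoints, scores, side="right")
    labels = _relabel(labels)

    # merge thin or Z-degenerate strata into the nearest neighbour
    while True:
        uniq = np.unique(labels)
        if len(uniq) <= 1:
            break
        counts = np.array([(labels == u).sum() for u in uniq])
        bad = None
        for i, u in enumerate(uniq):
            thin = counts[i] < min_stratum_size
            degen = z is not None and len(np.unique(z[labels == u])) < 2
            if thin or degen:
                bad = i
                break
        if bad is None:
            break
        neighbours = [j for j in (bad - 1, bad + 1) if 0 <= j < len(uniq)]
        target = min(neighbours, key=lambda j: counts[j])
        labels[labels == uniq[bad]] = uniq[target]
        labels = _relabel(labels)

    uniq = np.unique(labels)
    counts = np.array([(labels == u).sum() for u in uniq])
    return StratumAssignment(
        K_requested=K,
        K_final=len(uniq),
        breakpoints=breakpoints,
        labels=labels,
        counts=counts,
    )


def _relabel(labels: np.ndarray) -> np.ndarray:
    """Compact stratum labels to consecutive integers preserving order."""
    uniq = np.unique(labels)
    lookup = {u: i for i, u in enumerate(uniq)}
    return np.array([lookup[v] for v in labels], dtype=int)
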