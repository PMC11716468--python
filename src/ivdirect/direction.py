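"""Causal-direction testing: Test A / Test B, the decision rule and subgroups.

For an instrument Z, ordinal intervention T and ordinal outcome Y, the
procedure runs two conditional independence tests per outcome:

* **Test B**: ``Z ⊥ Y | π̄_X1`` — conditioning on stratified P(Z=1|X1).
  Rejecting it is necessary for the expected direction T → Y: if T causes Y,
  the instrument's influence flows through T into Y, so Z and Y stay
  associated once only the confounders are adjusted for.
* **Test A**: ``Z ⊥ Y | π̄_X1T`` — conditioning on stratified P(Z=1|X1,T).
  Rejecting it is necessary for the reverse direction Y → T: if T causes Y,
  adjusting additionally for T blocks every path from Z to Y.

The rejection pattern at level α maps to a verdict:

====================  ====================  =======================
Test A (p_A)          Test B (p_B)          verdict
====================  ====================  =======================
retain (p_A ≥ α)      reject (p_B < α)      expected (T → Y)
reject (p_A < α)      retain (p_B ≥ α)      reverse (Y → T)
reject                reject                heterogeneous
retain                retain                inconclusive
====================  ====================  =======================

The boundary p = α counts as non-rejection.  When both tests reject, the
population plausibly mixes subgroups with opposite causal directions, and the
same pair of tests is rerun within pre-specified subgroups (the full pipeline
— propensity fits, stratification, tests, pooling — is repeated per group).

All tests run on every multiply-imputed table; p-values are pooled (median by
default) and Cramér's V is pooled as the median across imputations.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np

from .citest import ENGINES, CITestResult
from .errors import AnalysisError, DegenerateTableError
from .imputation import ImputationSet, pool_pvalues
from .propensity import assign_strata, fit_propensity
from .survey import StudyTable

__all__ = [
    "DirectionConfig",
    "DirectionTestPair",
    "DirectionVerdict",
    "decide_direction",
    "run_direction_tests",
    "subgroup_analysis",
]

VERDICTS = ("expected", "reverse", "heterogeneous", "inconclusive")


@dataclass
class DirectionConfig:
    """Knobs of the testing pipeline (defaults match the survey analysis)."""

    engine: str = "mi_g2"  # or "cmh"
    n_strata: int = 5
    min_stratum_size: int = 20
    alpha: float = 0.05
    pooling_rule: str = "median"
    ridge_penalty: float = 1.0
    min_subgroup_n: int = 200


@dataclass
class DirectionVerdict:
    verdict: str  # one of VERDICTS
    p_A: float
    p_B: float
    alpha: float
    effect_A: float = float("nan")
    effect_B: float = float("nan")
    subgroup_verdicts: dict = field(default_factory=dict)

    def __str__(self) -> str:
        return self.verdict


@dataclass
class DirectionTestPair:
    """Pooled Test A / Test B results for one outcome."""

    outcome: str
    test_A: CITestResult
    test_B: CITestResult
    alpha: float
    n_effective: int
    m_used: int
    m_dropped: int
    per_imputation: dict = field(default_factory=dict)

    @property
    def verdict(self) -> DirectionVerdict:
        v = decide_direction(self.test_A.p_value, self.test_B.p_value, self.alpha)
        v.effect_A = self.test_A.cramers_v
        v.effect_B = self.test_B.cramers_v
        return v


def decide_direction(p_A: float, p_B: float, alpha: float = 0.05) -> DirectionVerdict:
    """Map the (p_A, p_B) rejection pattern to a causal-direction verdict.

    Rejection is strict (p < α); p = α retains the null.
    """
    for name, p in (("p_A", p_A), ("p_B", p_B)):
        if not (0.0 <= p <= 1.0) or np.isnan(p):
            raise ValueError(f"{name}={p} outside [0, 1]")
    if not (0.0 < alpha < 1.0):
        raise ValueError(f"alpha={alpha} outside (0, 1)")
    reject_A = p_A < alpha
    reject_B = p_B < alpha
    if reject_A and reject_B:
        verdict = "heterogeneous"
    elif reject_B:
        verdict = "expected"
    elif reject_A:
        verdict = "reverse"
    else:
        verdict = "inconclusive"
    return DirectionVerdict(verdict=verdict, p_A=p_A, p_B=p_B, alpha=alpha)


def _single_table_tests(
    table: StudyTable, outcome: str, config: DirectionConfig
) -> tuple[CITestResult, CITestResult, int]:
    """Both tests on one completed table; returns (A, B, n_used)."""
    df = table.df
    keep = df[outcome].notna() & df[table.intervention].notna() & df[table.iv].notna()
    sub = table.with_df(df.loc[keep].reset_index(drop=True))
    engine = ENGINES[config.engine]

    model_b = fit_propensity(sub, include_T=False, ridge_penalty=config.ridge_penalty)
    strata_b = assign_strata(
        model_b, K=config.n_strata, min_stratum_size=config.min_stratum_size
    )
    model_a = fit_propensity(sub, include_T=True, ridge_penalty=config.ridge_penalty)
    strata_a = assign_strata(
        model_a, K=config.n_strata, min_stratum_size=config.min_stratum_size
    )

    z = sub.df[sub.iv].to_numpy()
    y = sub.df[outcome].to_numpy()
    test_a = engine(z, y, strata_a)
    test_b = engine(z, y, strata_b)
    return test_a, test_b, int(keep.sum())


def _pool(results: list[CITestResult], rule: str) -> CITestResult:
    p = pool_pvalues([r.p_value for r in results], rule=rule)
    return CITestResult(
        engine=results[0].engine,
        statistic=float(np.median([r.statistic for r in results])),
        df=int(np.median([r.df for r in results])),
        p_value=p,
        n=results[0].n,
        cramers_v=float(np.median([r.cramers_v for r in results])),
        cohen_label=results[len(results) // 2].cohen_label,
        strata_used=int(np.median([r.strata_used for r in results])),
    )


def run_direction_tests(
    imps: ImputationSet | StudyTable,
    outcome: str,
    config: DirectionConfig | None = None,
) -> DirectionTestPair:
    """Run Tests A and B for one outcome across all imputed tables and pool.

    A complete (unimputed) table may be passed directly and is treated as a
    single-imputation set.  Imputations whose tests are degenerate are
    dropped with a warning; losing more than half of them aborts with an
    :class:`AnalysisError`.
    """
    config = config or DirectionConfig()
    if isinstance(imps, StudyTable):
        imps = ImputationSet(tables=[imps], seeds=[0], imputed_columns=[])
    if outcome not in imps.tables[0].df.columns:
        raise KeyError(f"outcome column {outcome!r} not in table")

    res_a: list[CITestResult] = []
    res_b: list[CITestResult] = []
    n_eff = 0
    dropped = 0
    for tab in imps:
        try:
            a, b, n_used = _single_table_tests(tab, outcome, config)
        except DegenerateTableError as exc:
            dropped += 1
            warnings.warn(f"imputation dropped ({exc})", stacklevel=2)
            continue
        res_a.append(a)
        res_b.append(b)
        n_eff = n_used
    if dropped > imps.m / 2:
        raise AnalysisError(
            f"{dropped}/{imps.m} imputations degenerate; analysis aborted"
        )

    pooled_a = _pool(res_a, config.pooling_rule)
    pooled_b = _pool(res_b, config.pooling_rule)
    return DirectionTestPair(
        outcome=outcome,
        test_A=pooled_a,
        test_B=pooled_b,
        alpha=config.alpha,
        n_effective=n_eff,
        m_used=len(res_a),
        m_dropped=dropped,
        per_imputation={
            "p_A": [r.p_value for r in res_a],
            "p_B": [r.p_value for r in res_b],
            "v_A": [r.cramers_v for r in res_a],
            "v_B": [r.cramers_v for r in res_b],
        },
    )


def subgroup_analysis(
    imps: ImputationSet | StudyTable,
    outcome: str,
    grouping: str,
    config: DirectionConfig | None = None,
) -> dict[str, dict]:
    """Rerun the full direction pipeline independently within each subgroup.

    Returns ``{level: {"pair", "verdict", "n", "underpowered"}}``.  Levels
    with fewer records than ``config.min_subgroup_n`` are flagged
    underpowered (their tests still run when possible); empty or degenerate
    levels are reported, never raised.
    """
    config = config or DirectionConfig()
    if isinstance(imps, StudyTable):
        imps = ImputationSet(tables=[imps], seeds=[0], imputed_columns=[])
    base = imps.tables[0].df
    if grouping not in base.columns:
        raise KeyError(f"grouping column {grouping!r} not in table")
    levels = sorted(base[grouping].dropna().unique())
    if len(levels) < 2:
        raise ValueError(f"grouping {grouping!r} is constant; cannot subgroup")

    out: dict[str, dict] = {}
    for lev in levels:
        masks = [t.df[grouping] == lev for t in imps.tables]
        n_lev = int(masks[0].sum())
        entry: dict = {"n": n_lev, "underpowered": n_lev < config.min_subgroup_n}
        if n_lev == 0:
            entry.update(pair=None, verdict=None, note="empty level")
            out[str(lev)] = entry
            continue
        sub_imps = ImputationSet(
            tables=[
                t.with_df(t.df.loc[m].reset_index(drop=True))
                for t, m in zip(imps.tables, masks)
            ],
            seeds=imps.seeds,
            imputed_columns=imps.imputed_columns,
        )
        try:
            pair = run_direction_tests(sub_imps, outcome, config)
        except (AnalysisError, DegenerateTableError, ValueError) as exc:
            entry.update(pair=None, verdict=None, note=f"not testable: {exc}")
            out[str(lev)] = entry
            continue
        entry.update(pair=pair, verdict=pair.verdict)
        out[str(lev)] = entry
    return out
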