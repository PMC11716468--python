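"""Model/Results interface tying the pipeline together.

:class:`CausalDirectionModel` is constructed from a respondent-level table
(a :class:`~ivdirect.survey.StudyTable` or a plain DataFrame plus role
names); ``fit()`` executes imputation → propensity stratification → Tests
A/B → pooling → verdict (→ subgroups when both tests reject) and returns a
:class:`CausalDirectionResults` with the pooled statistics, effect sizes,
verdicts and a ``summary()`` table.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .direction import (
    DirectionConfig,
    DirectionTestPair,
    run_direction_tests,
    subgroup_analysis,
)
from .imputation import ImputationSet, mice_impute
from .survey import StudyTable

__all__ = ["CausalDirectionModel", "CausalDirectionResults"]


class CausalDirectionModel:
    """Causal-direction testing model for an instrumented ordinal survey.

    Parameters
    ----------
    data : StudyTable or pandas.DataFrame
        Respondent-level table.  When a DataFrame is given, role columns
        must be named via the keyword arguments.
    outcomes : list of str, optional
        Outcome columns to test (default: the table's outcome roles).
    subgroup_vars : list of str, optional
        Pre-specified subgroup columns examined when both tests reject
        (default: the table's subgroup roles).

    Examples
    --------
    >>> from ivdirect.simulate import preset, generate_dataset
    >>> table, _ = generate_dataset(preset("forward_strong", seed=42))
    >>> res = CausalDirectionModel(table).fit(m=1)
    >>> res.verdicts["Y"].verdict
    'expected'
    """

    def __init__(
        self,
        data: StudyTable | pd.DataFrame,
        outcomes: list[str] | None = None,
        subgroup_vars: list[str] | None = None,
        confounders: list[str] | None = None,
        iv: str = "Z",
        intervention: str = "T",
        config: DirectionConfig | None = None,
    ) -> None:
        if isinstance(data, pd.DataFrame):
            data = StudyTable(
                df=data.astype(float),
                outcomes=outcomes or [],
                confounders=confounders or [],
                subgroups=subgroup_vars or [],
                iv=iv,
                intervention=intervention,
            )
        self.table = data
        self.outcomes = outcomes or list(data.outcomes)
        if not self.outcomes:
            raise ValueError("no outcome columns specified")
        self.subgroup_vars = (
            subgroup_vars if subgroup_vars is not None else list(data.subgroups)
        )
        self.config = config or DirectionConfig()

    @classmethod
    def from_dataframe(cls, df: pd.DataFrame, **kwargs) -> "CausalDirectionModel":
        return cls(df, **kwargs)

    def fit(
        self,
        m: int = 100,
        iterations: int = 10,
        base_seed: int = 0,
        subgroups: str = "auto",
    ) -> "CausalDirectionResults":
        """Run the full testing pipeline.

        ``subgroups`` is "auto" (descend only on a heterogeneous verdict),
        "always", or "never".  With no missing confounder cells the
        imputation collapses to the single complete dataset regardless of m.
        """
        has_missing = self.table.df[self.table.confounders].isna().any().any()
        if has_missing:
            imps: ImputationSet | StudyTable = mice_impute(
                self.table, m=m, iterations=iterations, base_seed=base_seed
            )
        else:
            imps = self.table  # single complete dataset

        pairs: dict[str, DirectionTestPair] = {}
        verdicts = {}
        subgroup_results: dict[str, dict[str, dict]] = {}
        for outcome in self.outcomes:
            pair = run_direction_tests(imps, outcome, self.config)
            pairs[outcome] = pair
            verdict = pair.verdict
            trigger = subgroups == "always" or (
                subgroups == "auto" and verdict.verdict == "heterogeneous"
            )
            if trigger and self.subgroup_vars:
                per_var = {}
                for gvar in self.subgroup_vars:
                    per_var[gvar] = subgroup_analysis(
                        imps, outcome, gvar, self.config
                    )
                subgroup_results[outcome] = per_var
                verdict.subgroup_verdicts = {
                    gvar: {
                        lev: (e["verdict"].verdict if e["verdict"] else None)
                        for lev, e in groups.items()
                    }
                    for gvar, groups in per_var.items()
                }
            verdicts[outcome] = verdict
        return CausalDirectionResults(
            model=self,
            pairs=pairs,
            verdicts=verdicts,
            subgroup_results=subgroup_results,
            m=getattr(imps, "m", 1),
        )


@dataclass
class CausalDirectionResults:
    """Fitted results: pooled tests, verdicts and reporting helpers."""

    model: CausalDirectionModel
    pairs: dict[str, DirectionTestPair]
    verdicts: dict
    subgroup_results: dict = field(default_factory=dict)
    m: int = 1

    def to_frame(self) -> pd.DataFrame:
        """Report table: one row per outcome × (population + subgroups)."""
        rows = []

        def add(outcome, scope, pair, verdict):
            rows.append(
                {
                    "outcome": outcome,
                    "scope": scope,
                    "n": pair.n_effective if pair else np.nan,
                    "p_A": pair.test_A.p_value if pair else np.nan,
                    "effect_A": pair.test_A.cramers_v if pair else np.nan,
                    "p_B": pair.test_B.p_value if pair else np.nan,
                    "effect_B": pair.test_B.cramers_v if pair else np.nan,
                    "label_B": pair.test_B.cohen_label if pair else "",
                    "verdict": verdict if verdict else "",
                }
            )

        for outcome, pair in self.pairs.items():
            add(outcome, "population", pair, self.verdicts[outcome].verdict)
            for gvar, groups in self.subgroup_results.get(outcome, {}).items():
                for lev, entry in groups.items():
                    v = entry["verdict"].verdict if entry["verdict"] else None
                    add(outcome, f"{gvar}={lev}", entry["pair"], v)
        return pd.DataFrame(rows)

    def summary(self) -> str:
        """Publication-style text table of the pooled tests and verdicts."""
        frame = self.to_frame()
        lines = [
            "Causal direction tests "
            f"(engine={self.model.config.engine}, "
            f"alpha={self.model.config.alpha}, m={self.m})",
            "Test A: Z ⊥ Y | strat(P(Z=1|X1,T)) — rejection necessary "
            "for reverse (Y→T)",
            "Test B: Z ⊥ Y | strat(P(Z=1|X1))   — rejection necessary "
            "for expected (T→Y)",
            "",
        ]
        with pd.option_context("display.float_format", "{:0.4g}".format):
            lines.append(frame.to_string(index=False))
        return "\n".join(lines)

    def to_json(self) -> str:
        out = {}
        for outcome, pair in self.pairs.items():
            out[outcome] = {
                "p_A": pair.test_A.p_value,
                "p_B": pair.test_B.p_value,
                "effect_A": pair.test_A.cramers_v,
                "effect_B": pair.test_B.cramers_v,
                "n": pair.n_effective,
                "m_used": pair.m_used,
                "verdict": self.verdicts[outcome].verdict,
                "per_imputation": pair.per_imputation,
                "subgroups": self.verdicts[outcome].subgroup_verdicts,
            }
        return json.dumps(out, indent=2)
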