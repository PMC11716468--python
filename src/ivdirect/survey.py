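"""Survey-table loading, recoding, filtering and marginal association diagnostics.

The analysis data model is a :class:`StudyTable`: one row per survey
respondent, with a binary instrument ``Z`` (internet savviness), a five-level
ordinal intervention ``T`` (portal-access frequency: 0, 1–2, 3–5, 6–9, 10+
accesses in the past year), one or more five-point Likert outcomes, a set of
named categorical confounders, optional subgroup labels, and a binary cancer
history flag.  Missing entries are ``NaN`` throughout; public-use survey files
encode missingness with negative sentinel codes, which :func:`load_study_table`
converts on the way in.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field, replace
from typing import Any, Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
import yaml
from scipy import stats

from .errors import ConfigurationError, DegenerateTableError, InputError

__all__ = [
    "StudyTable",
    "VariableMap",
    "LoadReport",
    "load_study_table",
    "derive_internet_savvy",
    "filter_population",
    "crosstab",
    "chi_square_test",
]

#: levels of the portal-use intervention and of a 5-point Likert outcome
T_LEVELS = (0, 1, 2, 3, 4)
Y_LEVELS = (1, 2, 3, 4, 5)


@dataclass
class StudyTable:
    """Respondent-level analysis table with role metadata.

    Parameters
    ----------
    df : pandas.DataFrame
        Columns named by role: ``Z``, ``T``, one column per outcome id,
        one per confounder, optional subgroup columns and ``cancer``.
        Missing values are NaN.
    outcomes : list of str
        Outcome column names (e.g. ``["OATCH", "QC"]`` or ``["Y"]``).
    confounders : list of str
        Observed categorical confounder column names (the X1 set).
    subgroups : list of str
        Derived subgroup label columns (e.g. gender, education split).
    """

    df: pd.DataFrame
    outcomes: list[str] = field(default_factory=list)
    confounders: list[str] = field(default_factory=list)
    subgroups: list[str] = field(default_factory=list)
    iv: str = "Z"
    intervention: str = "T"
    cancer_col: str = "cancer"

    @property
    def n(self) -> int:
        return len(self.df)

    def with_df(self, df: pd.DataFrame) -> "StudyTable":
        return replace(self, df=df)

    def copy(self) -> "StudyTable":
        return self.with_df(self.df.copy())

    def validate(self) -> None:
        """Check the coded-range invariants on Z, T and the outcomes."""
        z = self.df[self.iv].dropna()
        if not z.isin([0, 1]).all():
            raise ValueError("Z contains values outside {0, 1}")
        t = self.df[self.intervention].dropna()
        if not t.isin(T_LEVELS).all():
            raise ValueError("T contains values outside {0..4}")
        for y in self.outcomes:
            yy = self.df[y].dropna()
            if not yy.isin(Y_LEVELS).all():
                raise ValueError(f"outcome {y!r} contains values outside {{1..5}}")

    def equals(self, other: "StudyTable") -> bool:
        a = self.df.reset_index(drop=True).astype(float)
        b = other.df[self.df.columns].reset_index(drop=True).astype(float)
        return a.shape == b.shape and bool(
            ((a == b) | (a.isna() & b.isna())).all().all()
        )

    def to_csv(self, path) -> None:
        self.df.to_csv(path, index=False)


@dataclass
class LoadReport:
    n_rows: int
    missing_counts: dict[str, int]

    def to_json(self) -> str:
        return json.dumps({"n_rows": self.n_rows, "missing": self.missing_counts})


@dataclass
class VariableMap:
    """Binding from raw file columns to analysis roles, with recode rules.

    ``iv_items`` lists the four internet-access venue columns from which
    savviness is derived; alternatively ``iv`` names a pre-computed binary
    instrument column.  Negative numeric codes are treated as missing when
    ``negative_missing`` is set (the public-use survey convention), plus any
    codes listed per column in ``missing_codes``.
    """

    intervention: str = "T"
    iv: str | None = None
    iv_items: Sequence[str] = ()
    outcomes: Mapping[str, str] = field(default_factory=dict)  # id -> column
    confounders: Mapping[str, str] = field(default_factory=dict)  # name -> column
    cancer_flag: str | None = None
    subgroups: Mapping[str, str] = field(default_factory=dict)
    recodes: Mapping[str, Mapping[Any, Any]] = field(default_factory=dict)
    missing_codes: Mapping[str, Sequence[Any]] = field(default_factory=dict)
    negative_missing: bool = True
    daily_code: Any = 1  # venue-item code meaning "Daily"

    def __post_init__(self) -> None:
        bound: list[str] = [self.intervention]
        if self.iv:
            bound.append(self.iv)
        bound += list(self.iv_items)
        bound += list(self.outcomes.values())
        bound += list(self.confounders.values())
        if self.cancer_flag:
            bound.append(self.cancer_flag)
        dupes = {c for c in bound if bound.count(c) > 1}
        if dupes:
            raise ConfigurationError(
                f"columns bound to more than one role: {sorted(dupes)}"
            )

    @property
    def mapped_columns(self) -> list[str]:
        cols = [self.intervention]
        if self.iv:
            cols.append(self.iv)
        cols += list(self.iv_items)
        cols += list(self.outcomes.values())
        cols += list(self.confounders.values())
        if self.cancer_flag:
            cols.append(self.cancer_flag)
        cols += list(self.subgroups.values())
        return cols

    @classmethod
    def from_file(cls, path) -> "VariableMap":
        with open(path) as fh:
            raw = yaml.safe_load(fh)
        return cls(**raw)


def _apply_missing(s: pd.Series, vmap: VariableMap, col: str) -> pd.Series:
    s = pd.to_numeric(s, errors="coerce")
    if vmap.negative_missing:
        s = s.mask(s < 0)
    codes = vmap.missing_codes.get(col)
    if codes:
        s = s.mask(s.isin(list(codes)))
    return s


def _recode(s: pd.Series, mapping: Mapping[Any, Any] | None) -> pd.Series:
    if not mapping:
        return s
    return s.map(lambda v: mapping.get(v, v))


def load_study_table(path, vmap: VariableMap) -> StudyTable:
    """Read a delimited survey file and recode it into a :class:`StudyTable`.

    Out-of-range intervention/outcome codes and missing-coded entries become
    NaN.  A :class:`LoadReport` with row and per-variable missingness counts
    is attached as ``table.load_report``.
    """
    try:
        raw = pd.read_csv(path, sep=None, engine="python")
    except Exception as exc:  # noqa: BLE001 - wrap any parser failure
        raise InputError(f"could not parse {path}: {exc}") from exc

    absent = [c for c in vmap.mapped_columns if c not in raw.columns]
    if absent:
        raise ConfigurationError(f"mapped column(s) absent from file: {absent}")

    df = pd.DataFrame(index=raw.index)

    def col(raw_name: str) -> pd.Series:
        s = _apply_missing(raw[raw_name], vmap, raw_name)
        return _recode(s, vmap.recodes.get(raw_name))

    t = col(vmap.intervention)
    df["T"] = t.where(t.isin(T_LEVELS))

    if vmap.iv:
        z = col(vmap.iv)
        df["Z"] = z.where(z.isin([0, 1]))
    elif vmap.iv_items:
        items = pd.concat([col(c) for c in vmap.iv_items], axis=1)
        df["Z"] = derive_internet_savvy(items, daily_code=vmap.daily_code)
    else:
        raise ConfigurationError("VariableMap binds neither iv nor iv_items")

    outcomes = []
    for oid, c in vmap.outcomes.items():
        y = col(c)
        df[oid] = y.where(y.isin(Y_LEVELS))
        outcomes.append(oid)

    confounders = []
    for name, c in vmap.confounders.items():
        df[name] = col(c)
        confounders.append(name)

    subgroups = []
    for name, c in vmap.subgroups.items():
        df[name] = col(c)
        subgroups.append(name)

    if vmap.cancer_flag:
        cz = col(vmap.cancer_flag)
        df["cancer"] = cz.where(cz.isin([0, 1]))
    else:
        df["cancer"] = 1.0

    table = StudyTable(
        df=df.astype(float),
        outcomes=outcomes,
        confounders=confounders,
        subgroups=subgroups,
    )
    table.validate()
    table.load_report = LoadReport(  # type: ignore[attr-defined]
        n_rows=len(df),
        missing_counts={c: int(df[c].isna().sum()) for c in df.columns},
    )
    return table


def derive_internet_savvy(items: pd.DataFrame, daily_code: Any = 1) -> pd.Series:
    """Collapse the four internet-venue frequency items to a binary instrument.

    Returns 1 where any item equals the "Daily" code, 0 where at least one
    item was answered and none is Daily, and NaN where all four are missing.
    """
    any_daily = (items == daily_code).any(axis=1)
    any_answered = items.notna().any(axis=1)
    z = pd.Series(np.nan, index=items.index, dtype=float)
    z[any_answered] = 0.0
    z[any_daily] = 1.0
    return z


def filter_population(table: StudyTable) -> StudyTable:
    """Restrict to respondents with a cancer history and a defined instrument.

    Rows are kept when ``cancer == 1`` and ``Z`` is non-missing (i.e. at
    least one internet-venue item was answered).  Kept/dropped counts are
    attached as ``filter_report``; an empty result raises a warning only.
    """
    df = table.df
    keep = (df[table.cancer_col] == 1) & df[table.iv].notna()
    out = table.with_df(df.loc[keep].reset_index(drop=True))
    out.filter_report = {  # type: ignore[attr-defined]
        "kept": int(keep.sum()),
        "dropped": int((~keep).sum()),
    }
    if keep.sum() == 0:
        warnings.warn("filter_population produced an empty table", stacklevel=2)
    return out


def crosstab(
    a: pd.Series,
    b: pd.Series,
    drop_missing: bool = True,
    missing_label: str = "missing",
) -> pd.DataFrame:
    """Integer contingency table of two categorical columns.

    With ``drop_missing=False`` the missing category is retained as an extra
    row/column (descriptive tables print it; causal tests never see it).
    """
    a = a.reset_index(drop=True)
    b = b.reset_index(drop=True)
    if drop_missing:
        mask = a.notna() & b.notna()
        tab = pd.crosstab(a[mask], b[mask])
    else:
        tab = pd.crosstab(
            a.fillna(missing_label).astype(object),
            b.fillna(missing_label).astype(object),
        )
    if tab.shape[0] < 2 or tab.shape[1] < 2:
        raise DegenerateTableError(
            f"contingency table is {tab.shape[0]}x{tab.shape[1]}; "
            "need at least 2 levels on each margin"
        )
    return tab.astype(int)


def chi_square_test(tab: pd.DataFrame | np.ndarray):
    """Pearson chi-square independence test of a two-way table.

    Returns a :class:`~ivdirect.citest.CITestResult` with Cramér's V and its
    Cohen label attached.  Uses no continuity correction.
    """
    from .citest import CITestResult, cramers_v  # local import, avoids cycle

    arr = np.asarray(tab, dtype=float)
    if arr.ndim != 2 or arr.shape[0] < 2 or arr.shape[1] < 2:
        raise DegenerateTableError("need a table with >= 2 rows and columns")
    if (arr.sum(axis=0) == 0).any() or (arr.sum(axis=1) == 0).any():
        raise DegenerateTableError("zero marginal row or column")
    stat, p, dof, _ = stats.chi2_contingency(arr, correction=False)
    n = int(arr.sum())
    v, label = cramers_v(stat, n, arr.shape[0], arr.shape[1])
    return CITestResult(
        engine="pearson_chi2",
        statistic=float(stat),
        df=int(dof),
        p_value=float(p),
        n=n,
        cramers_v=v,
        cohen_label=label,
        strata_used=1,
    )
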