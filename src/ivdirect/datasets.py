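"""Small reference tables bundled for worked examples and sanity checks."""

from __future__ import annotations

import pandas as pd

__all__ = ["portal_use_by_internet_savvy"]

#: Portal-access frequency (columns: 0, 1–2, 3–5, 6–9, 10+ accesses/year,
#: plus item non-response) cross-tabulated against internet savviness among
#: the 2,579 HINTS 5 (2017–2020) respondents reporting a cancer history.
_COUNTS = {
    "t0": [769, 709],
    "t1_2": [58, 284],
    "t3_5": [52, 312],
    "t6_9": [20, 124],
    "t10p": [20, 135],
    "nonresponse": [64, 32],
}


def portal_use_by_internet_savvy(include_nonresponse: bool = True) -> pd.DataFrame:
    """The reference instrument × intervention cross-tabulation.

    Rows are internet savviness (0 = not savvy, 1 = savvy); columns are
    portal-access frequency levels.  ``include_nonresponse=False`` drops the
    item non-response column, leaving the 2×5 table the causal pipeline
    would test.
    """
    tab = pd.DataFrame(_COUNTS, index=pd.Index([0, 1], name="savvy"))
    if not include_nonresponse:
        tab = tab.drop(columns="nonresponse")
    return tab
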