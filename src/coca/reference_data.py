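"""Published reference contingency tables for a five-subgroup HCC cohort.

These are the printed subgroup x covariate counts and the TP53/CTNNB1
mutation tallies from a published TCGA hepatocellular-carcinoma cohort of
~256 samples classified into five molecular subgroups (S1-S5). They serve
as fixed inputs for validating the proportion and association utilities:
the quoted summary percentages (e.g. 70% TP53 mutation in S1) must be
recoverable from them exactly.
"""

from __future__ import annotations

import pandas as pd

# subgroup -> level -> count
GENDER = {
    "S1": {"Female": 2, "Male": 14},
    "S2": {"Female": 27, "Male": 45},
    "S3": {"Female": 18, "Male": 39},
    "S4": {"Female": 19, "Male": 15},
    "S5": {"Female": 8, "Male": 3},
}

ALCOHOL = {
    "S1": {"NO": 7, "YES": 5},
    "S2": {"NO": 41, "YES": 26},
    "S3": {"NO": 41, "YES": 13},
    "S4": {"NO": 25, "YES": 7},
    "S5": {"NO": 2, "YES": 7},
}

CHILD_PUGH = {
    "S1": {"Low(1)": 4, "High(>1)": 3},
    "S2": {"Low(1)": 31, "High(>1)": 5},
    "S3": {"Low(1)": 30, "High(>1)": 2},
    "S4": {"Low(1)": 15, "High(>1)": 2},
    "S5": {"Low(1)": 6, "High(>1)": 0},
}

AFP = {
    "S1": {"Low(<20)": 4, "High(>20)": 8},
    "S2": {"Low(<20)": 27, "High(>20)": 23},
    "S3": {"Low(<20)": 31, "High(>20)": 10},
    "S4": {"Low(<20)": 9, "High(>20)": 17},
    "S5": {"Low(<20)": 3, "High(>20)": 2},
}

AJCC_STAGE = {
    "S1": {"1": 2, ">1": 14},
    "S2": {"1": 34, ">1": 37},
    "S3": {"1": 30, ">1": 26},
    "S4": {"1": 13, ">1": 21},
    "S5": {"1": 1, ">1": 10},
}

HCV = {
    "S1": {"No": 0, "Yes": 12},
    "S2": {"No": 4, "Yes": 27},
    "S3": {"No": 4, "Yes": 24},
    "S4": {"No": 3, "Yes": 15},
    "S5": {"No": 0, "Yes": 8},
}

VASCULAR_INVASION = {
    "S1": {"NO": 11, "YES": 2},
    "S2": {"NO": 44, "YES": 22},
    "S3": {"NO": 31, "YES": 20},
    "S4": {"NO": 19, "YES": 13},
    "S5": {"NO": 8, "YES": 1},
}

# mutated / wild-type counts, focus subgroup vs all others
TP53 = {"S1": {"mutated": 16, "wildtype": 7}, "others": {"mutated": 39, "wildtype": 123}}
CTNNB1 = {"S3": {"mutated": 23, "wildtype": 30}, "others": {"mutated": 27, "wildtype": 105}}


def expand_counts(table: dict[str, dict[str, int]]) -> tuple[pd.Series, pd.Series]:
    """Expand a {subgroup: {level: count}} table into per-sample series.

    Returns (labels, covariate), both indexed by generated sample ids, so
    the count table can be fed through the per-sample utilities.
    """
    labels, levels, idx = [], [], []
    i = 0
    for group in table:
        for level, count in table[group].items():
            for _ in range(count):
                idx.append(f"ref{i:04d}")
                labels.append(group)
                levels.append(level)
                i += 1
    return pd.Series(labels, index=idx), pd.Series(levels, index=idx)
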