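"""Two-sample comparison layer with the figure-panel conventions.

Per-stereocilium metrics (heights, steps, diameters, wedge-tip heights) are
summarised as mean +/- SD and compared with Welch's unequal-variance t test;
per-cell percentages (tip links) are summarised as mean +/- SE and compared
with Student's pooled t test.  All tests are two-sided; p-values come from
the t distribution, and no multiple-testing correction is applied — panels
report per-contrast uncorrected stars, which is a documented limitation.
"""

from __future__ import annotations

import logging
import math
import warnings
from dataclasses import dataclass
from typing import Literal, Optional, Sequence

import numpy as np
import pandas as pd
from scipy import stats as sps

__all__ = [
    "GroupSummary",
    "GroupComparison",
    "summarize",
    "welch_t",
    "student_t",
    "significance_stars",
    "compare_groups",
]

logger = logging.getLogger(__name__)

STAR_THRESHOLDS = ((0.0001, "****"), (0.001, "***"), (0.01, "**"), (0.05, "*"))


@dataclass(frozen=True)
class GroupSummary:
    label: str
    n: int
    mean: float
    dispersion_value: float
    dispersion_kind: Literal["SD", "SE"] = "SD"


@dataclass(frozen=True)
class GroupComparison:
    summary_a: GroupSummary
    summary_b: GroupSummary
    test: Literal["welch", "student"]
    t_statistic: float
    degrees_of_freedom: float
    p_value: float
    stars: str


def summarize(values: Sequence[float], label: str = "",
              dispersion: Literal["SD", "SE"] = "SD") -> GroupSummary:
    """Mean with SD or SE dispersion for one group."""
    x = np.asarray(values, dtype=float)
    if x.size < 1:
        raise ValueError("empty sample")
    sd = float(x.std(ddof=1)) if x.size > 1 else 0.0
    disp = sd / math.sqrt(x.size) if dispersion == "SE" else sd
    return GroupSummary(label=label, n=int(x.size), mean=float(x.mean()),
                        dispersion_value=disp, dispersion_kind=dispersion)


def _two_sample(a, b, equal_var: bool, test: str,
                labels=("a", "b"), dispersion="SD") -> GroupComparison:
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if a.size < 2 or b.size < 2:
        raise ValueError(
            f"both samples need n >= 2 (got {a.size} and {b.size})")
    va, vb = a.var(ddof=1), b.var(ddof=1)
    if va == 0.0 and vb == 0.0:
        if a.mean() == b.mean():
            t, p = 0.0, 1.0
            df = (a.size + b.size - 2) if equal_var else float("inf")
        else:
            raise ValueError("both variances zero with unequal means: "
                             "t statistic undefined")
    else:
        res = sps.ttest_ind(a, b, equal_var=equal_var)
        t, p, df = float(res.statistic), float(res.pvalue), float(res.df)
    return GroupComparison(
        summary_a=summarize(a, labels[0], dispersion),
        summary_b=summarize(b, labels[1], dispersion),
        test=test,
        t_statistic=t,
        degrees_of_freedom=df,
        p_value=p,
        stars=significance_stars(p),
    )


def welch_t(sample_a, sample_b, labels=("a", "b"),
            dispersion="SD") -> GroupComparison:
    """Welch's unequal-variance two-sample t test (two-sided), with
    Welch–Satterthwaite degrees of freedom."""
    return _two_sample(sample_a, sample_b, equal_var=False, test="welch",
                       labels=labels, dispersion=dispersion)


def student_t(sample_a, sample_b, labels=("a", "b"),
              dispersion="SE") -> GroupComparison:
    """Student's pooled-variance two-sample t test (two-sided),
    df = n_a + n_b - 2."""
    return _two_sample(sample_a, sample_b, equal_var=True, test="student",
                       labels=labels, dispersion=dispersion)


def significance_stars(p: float) -> str:
    """Panel star label: ****p<0.0001, ***p<0.001, **p<0.01, *p<0.05,
    otherwise 'n.s.'."""
    if not 0.0 <= p <= 1.0 or math.isnan(p):
        raise ValueError(f"p must be in [0, 1], got {p}")
    for threshold, label in STAR_THRESHOLDS:
        if p < threshold:
            return label
    return "n.s."


# ---------------------------------------------------------------------------
# Comparison tables
# ---------------------------------------------------------------------------

#: measure name -> (test, dispersion); anything not listed defaults to
#: per-stereocilium conventions (Welch, SD).
_PER_CELL_MEASURES = {"tip_link_pct", "n_supernumerary"}

_COMPARISON_COLUMNS = [
    "measure", "row", "group_a", "group_b", "n_a", "n_b", "mean_a", "mean_b",
    "dispersion_a", "dispersion_b", "dispersion_kind", "test", "t_statistic",
    "df", "p_value", "stars",
]


def compare_groups(
    table: pd.DataFrame,
    group_col: str = "group",
    measures: Optional[Sequence[str]] = None,
    row_col: str = "row",
    groups: Optional[tuple[str, str]] = None,
) -> pd.DataFrame:
    """Per-(row, measure) two-group comparison table from a tidy
    morphometry table.

    ``table`` has one row per stereocilium (or per cell for percentage
    measures), a grouping column, a row-rank column and one column per
    measure.  Numeric per-stereocilium measures get Welch tests with SD
    summaries; measures named in ``_PER_CELL_MEASURES`` get Student tests
    with SE summaries.  Contrasts with a missing group or fewer than two
    finite values per group are skipped with a logged warning.  The output
    is sorted, hence invariant to input row order.
    """
    if group_col not in table.columns:
        raise ValueError(f"missing grouping column {group_col!r}")
    present = list(pd.unique(table[group_col].astype(str)))
    if groups is None:
        if len(present) < 2:
            logger.warning("fewer than two groups present (%s): empty "
                           "comparison table", present)
            return pd.DataFrame(columns=_COMPARISON_COLUMNS)
        groups = tuple(sorted(present)[:2])
    ga, gb = groups

    if measures is None:
        skip = {group_col, row_col}
        measures = [c for c in table.columns
                    if c not in skip and pd.api.types.is_numeric_dtype(table[c])
                    and not c.endswith("_id")]

    out = []
    row_values = sorted(pd.unique(table[row_col]), key=str) if row_col in table.columns else [None]
    for measure in measures:
        for row in row_values:
            sub = table if row is None else table[table[row_col] == row]
            a = sub.loc[sub[group_col].astype(str) == ga, measure].dropna().to_numpy(float)
            b = sub.loc[sub[group_col].astype(str) == gb, measure].dropna().to_numpy(float)
            if a.size == 0 and b.size == 0:
                continue  # measure undefined for this row in both groups
            if a.size < 2 or b.size < 2:
                logger.warning("contrast skipped (measure=%s, row=%s): group "
                               "sizes %d vs %d", measure, row, a.size, b.size)
                continue
            try:
                if measure in _PER_CELL_MEASURES:
                    cmp_ = student_t(a, b, labels=(ga, gb), dispersion="SE")
                else:
                    cmp_ = welch_t(a, b, labels=(ga, gb), dispersion="SD")
            except ValueError as err:
                logger.warning("contrast skipped (measure=%s, row=%s): %s",
                               measure, row, err)
                continue
            out.append(dict(
                measure=measure, row=row, group_a=ga, group_b=gb,
                n_a=cmp_.summary_a.n, n_b=cmp_.summary_b.n,
                mean_a=cmp_.summary_a.mean, mean_b=cmp_.summary_b.mean,
                dispersion_a=cmp_.summary_a.dispersion_value,
                dispersion_b=cmp_.summary_b.dispersion_value,
                dispersion_kind=cmp_.summary_a.dispersion_kind,
                test=cmp_.test, t_statistic=cmp_.t_statistic,
                df=cmp_.degrees_of_freedom, p_value=cmp_.p_value,
                stars=cmp_.stars,
            ))
    return pd.DataFrame(out, columns=_COMPARISON_COLUMNS)
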