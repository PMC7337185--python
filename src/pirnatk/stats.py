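"""Statistical layer: copy-number class comparisons and the trait correlation web.

Links normalized piRNA output to the genomic traits of TE families: mRNA
level, copy number, median insertion length, and nucleotide diversity pi.
Pearson correlations are computed after a log10(x+1) transform of count-like
variables; copy-number classes (>= 20 vs < 20 copies) are compared with a
two-sided Wilcoxon rank-sum test, exact by enumeration for small groups.
"""

from __future__ import annotations

import itertools
import math
from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats as sps

__all__ = [
    "CorrelationResult",
    "pearson",
    "correlation_web",
    "rank_sum_test",
    "copy_class_compare",
    "assign_copy_class",
]

COPY_CLASS_BOUNDARY = 20
EXACT_MAX_GROUP = 10
WEB_VARIABLES = ("pirna_level", "mrna_level", "copy_number", "median_length", "pi")
LOG_TRANSFORMED = {"pirna_level", "mrna_level", "copy_number"}


@dataclass(frozen=True)
class CorrelationResult:
    var_x: str
    var_y: str
    r: float
    p_value: float
    n: int

    @property
    def significant(self) -> bool:
        return not math.isnan(self.p_value) and self.p_value < 0.05


def pearson(x: Sequence[float], y: Sequence[float], var_x: str = "x", var_y: str = "y") -> CorrelationResult:
    """Product-moment correlation with a two-sided p from the t transform (n-2 df)."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size != y.size:
        raise ValueError("x and y must have equal length")
    if x.size < 3:
        raise ValueError("need at least 3 observations")
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        raise ValueError("undefined correlation: constant vector")
    res = sps.pearsonr(x, y)
    return CorrelationResult(var_x, var_y, float(res.statistic), float(res.pvalue), int(x.size))


def correlation_web(
    table: pd.DataFrame,
    variables: Sequence[str] = WEB_VARIABLES,
    transform: bool = True,
) -> pd.DataFrame:
    """Pairwise Pearson correlations among the family trait variables.

    Count-like variables (piRNA level, mRNA level, copy number) are
    log10(x+1)-transformed when ``transform`` is on; pi and median length are
    used untransformed.  A pair involving a constant column is reported with
    r and p as NaN; a Benjamini-Hochberg q-value column is added for
    transparency (no correction is applied to the significance flag).
    """
    if len(table) < 3:
        raise ValueError("need at least 3 families")
    cols = {}
    for v in variables:
        x = table[v].to_numpy(dtype=float)
        if transform and v in LOG_TRANSFORMED:
            x = np.log10(x + 1.0)
        cols[v] = x
    rows = []
    for vx, vy in itertools.combinations(variables, 2):
        x, y = cols[vx], cols[vy]
        if np.ptp(x) == 0 or np.ptp(y) == 0:
            rows.append(
                {"var_x": vx, "var_y": vy, "r": math.nan, "p_value": math.nan,
                 "n": len(x), "significant": False}
            )
            continue
        res = pearson(x, y, vx, vy)
        rows.append(
            {"var_x": vx, "var_y": vy, "r": res.r, "p_value": res.p_value,
             "n": res.n, "significant": res.significant}
        )
    out = pd.DataFrame(rows)
    out["bh_q"] = _bh_adjust(out["p_value"].to_numpy())
    return out


def _bh_adjust(p: np.ndarray) -> np.ndarray:
    q = np.full(p.shape, np.nan)
    ok = ~np.isnan(p)
    if ok.sum():
        q[ok] = sps.false_discovery_control(p[ok], method="bh")
    return q


def _midranks(values: np.ndarray) -> np.ndarray:
    return sps.rankdata(values, method="average")


def _exact_rank_sum_p(a: np.ndarray, b: np.ndarray) -> float:
    """Exact two-sided rank-sum p by exhaustive enumeration of group labelings.

    Uses midranks for ties; p = min(1, 2 * min(P(W <= w), P(W >= w))) over
    all C(n, n_a) assignments of the pooled values to group A.
    """
    pooled = np.concatenate([a, b])
    ranks = _midranks(pooled)
    n, na = len(pooled), len(a)
    w_obs = ranks[:na].sum()
    w_all = np.array(
        [ranks[list(idx)].sum() for idx in itertools.combinations(range(n), na)]
    )
    eps = 1e-9
    p_le = np.mean(w_all <= w_obs + eps)
    p_ge = np.mean(w_all >= w_obs - eps)
    return float(min(1.0, 2.0 * min(p_le, p_ge)))


def rank_sum_test(
    a: Sequence[float], b: Sequence[float], exact_max: int = EXACT_MAX_GROUP
) -> float:
    """Two-sided Wilcoxon rank-sum p value.

    Exact by exhaustive enumeration when both groups have at most
    ``exact_max`` observations; otherwise the normal approximation with tie
    correction (Mann-Whitney asymptotic form).
    """
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if a.size == 0 or b.size == 0:
        raise ValueError("both groups must be non-empty")
    if a.size <= exact_max and b.size <= exact_max:
        return _exact_rank_sum_p(a, b)
    return float(
        sps.mannwhitneyu(a, b, alternative="two-sided", method="asymptotic").pvalue
    )


def assign_copy_class(copy_number: int, boundary: int = COPY_CLASS_BOUNDARY) -> str:
    return "ge20" if copy_number >= boundary else "lt20"


def copy_class_compare(
    table: pd.DataFrame,
    value_col: str = "pirna_level",
    class_col: str = "expression_class",
    copy_col: str = "copy_number",
    boundary: int = COPY_CLASS_BOUNDARY,
) -> pd.DataFrame:
    """Compare piRNA levels between high- and low-copy families per expression class.

    Within each expression class, families with >= ``boundary`` copies are
    tested against families with fewer, two-sided Wilcoxon rank-sum.  Classes
    with an empty group are skipped (reported with NaN p).
    """
    rows = []
    copy_class = table[copy_col].apply(lambda c: assign_copy_class(c, boundary))
    for klass, sub in table.groupby(class_col, sort=True):
        hi = sub.loc[copy_class[sub.index] == "ge20", value_col].to_numpy(dtype=float)
        lo = sub.loc[copy_class[sub.index] == "lt20", value_col].to_numpy(dtype=float)
        if hi.size == 0 or lo.size == 0:
            rows.append(
                {"expression_class": klass, "n_ge20": hi.size, "n_lt20": lo.size,
                 "median_ge20": float(np.median(hi)) if hi.size else math.nan,
                 "median_lt20": float(np.median(lo)) if lo.size else math.nan,
                 "p_value": math.nan}
            )
            continue
        rows.append(
            {"expression_class": klass, "n_ge20": hi.size, "n_lt20": lo.size,
             "median_ge20": float(np.median(hi)), "median_lt20": float(np.median(lo)),
             "p_value": rank_sum_test(hi, lo)}
        )
    return pd.DataFrame(rows)
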