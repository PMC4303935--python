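"""Statistics linking distance-from-normal to group identity and survival.

Two questions are answered here.  First, do two sample groups sit at
different distances from the homeostatic (normal) center?  That is a
plain two-sample location test on the distance values — Welch's unequal-
variance t-test by default, Mann-Whitney as the rank-based alternative.
Second, does distance-from-normal predict survival?  That is an ordinary
least-squares fit of observed survival time (days) on distance; the
slope's two-sided t-test and the squared correlation R² summarize it.

Censoring is deliberately NOT modeled: survival enters as an observed
number of days, so any censoring indicator present in the metadata is
ignored with a warning.  Cox or Kaplan-Meier analyses are out of scope.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass
from itertools import combinations
from pathlib import Path
from typing import Optional, Sequence

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .errors import ConfigurationError, DegenerateDataError

logger = logging.getLogger(__name__)

TESTS = ("welch", "mannwhitney")


@dataclass(frozen=True)
class GroupComparison:
    """Result of a two-group distance comparison.

    ``statistic`` is signed so that a positive value means group A lies
    farther (greater mean/median) than group B.
    """

    group_a: str
    group_b: str
    statistic: float
    p_value: float
    test_name: str
    n_a: int
    n_b: int

    def __post_init__(self) -> None:
        if not (0.0 <= self.p_value <= 1.0):
            raise DegenerateDataError(f"p-value {self.p_value} outside [0, 1]")


@dataclass(frozen=True)
class SurvivalFit:
    """OLS fit of survival (days) on distance-from-normal."""

    slope: float            # days per unit distance
    intercept: float        # days
    p_value: float          # two-sided test of slope = 0
    r_squared: float
    n: int
    stderr: float           # standard error of the slope

    def conf_int(self, alpha: float = 0.05) -> tuple[float, float]:
        """Two-sided (1 − alpha) confidence interval for the slope."""
        t = stats.t.ppf(1.0 - alpha / 2.0, self.n - 2)
        return (self.slope - t * self.stderr, self.slope + t * self.stderr)

    def summary(self) -> str:
        lo, hi = self.conf_int()
        return (
            "survival ~ distance (OLS)\n"
            f"  n          {self.n}\n"
            f"  slope      {self.slope:.6g} days per unit distance "
            f"(95% CI {lo:.6g} .. {hi:.6g})\n"
            f"  intercept  {self.intercept:.6g} days\n"
            f"  p (slope)  {self.p_value:.3g}\n"
            f"  R^2        {self.r_squared:.4g}\n"
        )


def compare_groups(
    distances_a: Sequence[float],
    distances_b: Sequence[float],
    test: str = "welch",
    group_a: str = "a",
    group_b: str = "b",
) -> GroupComparison:
    """Two-sided test of whether two groups' distances differ in location.

    ``welch`` (default) is the unequal-variance t-test; ``mannwhitney``
    is the rank-sum alternative, preferable when both groups are constant
    or heavily skewed.
    """
    a = np.asarray(distances_a, dtype=float)
    b = np.asarray(distances_b, dtype=float)
    if a.size < 2 or b.size < 2 or not (np.isfinite(a).all() and np.isfinite(b).all()):
        raise DegenerateDataError(
            "each group needs >= 2 finite distance values"
        )
    if test == "welch":
        if a.std() == 0.0 and b.std() == 0.0:
            raise DegenerateDataError(
                "both groups have zero variance; Welch's t is undefined — "
                "use test='mannwhitney'"
            )
        res = stats.ttest_ind(a, b, equal_var=False)
        statistic, p = float(res.statistic), float(res.pvalue)
    elif test == "mannwhitney":
        res = stats.mannwhitneyu(a, b, alternative="two-sided")
        # center U so the sign says which group is larger
        statistic = float(res.statistic - a.size * b.size / 2.0)
        p = float(res.pvalue)
    else:
        raise ConfigurationError(f"unknown test {test!r}; expected one of {TESTS}")
    return GroupComparison(group_a=group_a, group_b=group_b,
                           statistic=statistic, p_value=p,
                           test_name=test, n_a=int(a.size), n_b=int(b.size))


def compare_all_groups(
    distance_to_normal: pd.Series,
    groups: pd.Series,
    test: str = "welch",
    exclude: Sequence[str] = (),
) -> pd.DataFrame:
    """All pairwise group comparisons of distance-to-normal.

    Raw p-values are primary; Benjamini-Hochberg adjusted values are
    reported alongside whenever more than one pair is tested.
    """
    groups = groups.reindex(distance_to_normal.index)
    labels = [g for g in sorted(groups.dropna().unique()) if g not in set(exclude)]
    rows = []
    for ga, gb in combinations(labels, 2):
        comp = compare_groups(
            distance_to_normal[groups == ga],
            distance_to_normal[groups == gb],
            test=test, group_a=ga, group_b=gb,
        )
        rows.append(comp)
    if not rows:
        raise DegenerateDataError("fewer than 2 groups to compare")
    out = pd.DataFrame(
        {
            "group_a": [c.group_a for c in rows],
            "group_b": [c.group_b for c in rows],
            "n_a": [c.n_a for c in rows],
            "n_b": [c.n_b for c in rows],
            "test": [c.test_name for c in rows],
            "statistic": [c.statistic for c in rows],
            "p_value": [c.p_value for c in rows],
        }
    )
    if len(rows) > 1:
        out["p_adj_bh"] = multipletests(out["p_value"], method="fdr_bh")[1]
    else:
        out["p_adj_bh"] = out["p_value"]
    return out


def fit_survival(
    distances: Sequence[float],
    survival_days: Sequence[float],
) -> SurvivalFit:
    """OLS fit ``survival = intercept + slope * distance``.

    Pairs with a missing value on either side are dropped.  At least 3
    complete pairs and a non-constant distance column are required.
    R² equals the squared Pearson correlation of the two columns.
    """
    x = np.asarray(distances, dtype=float)
    y = np.asarray(survival_days, dtype=float)
    if x.shape != y.shape:
        raise ConfigurationError("distances and survival must be paired")
    keep = np.isfinite(x) & np.isfinite(y)
    x, y = x[keep], y[keep]
    n = int(x.size)
    if n < 3:
        raise DegenerateDataError(f"need >= 3 complete pairs, got {n}")
    if np.ptp(x) == 0.0:
        raise DegenerateDataError("constant distances: degenerate design")
    res = stats.linregress(x, y)
    # constant response: correlation is 0/0, read as "nothing explained"
    r2 = float(res.rvalue ** 2) if math.isfinite(res.rvalue) else 0.0
    p = float(res.pvalue) if math.isfinite(res.pvalue) else 1.0
    return SurvivalFit(slope=float(res.slope), intercept=float(res.intercept),
                       p_value=p, r_squared=r2, n=n, stderr=float(res.stderr))


def write_association_report(
    comparisons: pd.DataFrame,
    fit: Optional[SurvivalFit],
    comparisons_path: str | Path,
    fit_path: Optional[str | Path] = None,
) -> None:
    """Write the comparison table (TSV) and, if fitted, the fit summary."""
    comparisons.to_csv(Path(comparisons_path), sep="\t", index=False,
                       float_format="%.6g")
    if fit is not None and fit_path is not None:
        Path(fit_path).write_text(fit.summary())
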