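"""Group comparisons and significance annotation.

Two tests cover the study's conventions: the classical equal-variance
unpaired Student t test (Welch available by flag) and one-way ANOVA.  No
multiple-testing correction is applied anywhere — each comparison stands on
its own, and reported p-values are raw.  Significance stars follow the
strict-inequality convention p < 0.05 (*), < 0.01 (**), < 0.001 (***),
< 0.0001 (****); p exactly at a cutoff is annotated at the weaker level.

For chord-conductance curves compared across voltages, per-voltage multiple
t tests are the default, with a two-factor (group x voltage) ANOVA offered
as an alternative; neither is privileged.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats as sps

__all__ = [
    "GroupComparison",
    "t_unpaired",
    "anova_oneway",
    "star_annotation",
    "compare_chord_curves",
]

_STAR_CUTOFFS = ((0.0001, "****"), (0.001, "***"), (0.01, "**"), (0.05, "*"))


@dataclass(frozen=True)
class GroupComparison:
    """Result of one group comparison."""

    groups: tuple[str, ...]
    n_per_group: tuple[int, ...]
    statistic: float
    p_value: float
    stars: str
    test: str

    def as_row(self) -> dict:
        return {
            "groups": " vs ".join(self.groups),
            "n": ",".join(str(n) for n in self.n_per_group),
            "test": self.test,
            "statistic": self.statistic,
            "p_value": self.p_value,
            "stars": self.stars,
        }


def star_annotation(p: float) -> str:
    """Map a p-value to its significance stars (strict inequality)."""
    if not np.isfinite(p) or p < 0.0 or p > 1.0:
        raise ValueError(f"p-value {p!r} outside [0, 1]")
    for cutoff, stars in _STAR_CUTOFFS:
        if p < cutoff:
            return stars
    return "ns"


def _check_group(x, name: str) -> np.ndarray:
    arr = np.asarray(x, dtype=float)
    if arr.ndim != 1 or arr.size < 2:
        raise ValueError(f"group {name} needs at least 2 observations")
    if not np.all(np.isfinite(arr)):
        raise ValueError(f"group {name} contains non-finite values")
    return arr


def t_unpaired(
    a: Sequence[float],
    b: Sequence[float],
    labels: tuple[str, str] = ("a", "b"),
    welch: bool = False,
) -> GroupComparison:
    """Two-sided unpaired Student t test (pooled variance by default)."""
    x = _check_group(a, labels[0])
    y = _check_group(b, labels[1])
    t, p = sps.ttest_ind(x, y, equal_var=not welch)
    # identical samples: scipy returns nan at zero variance; by convention
    # no difference means t = 0, p = 1
    if not np.isfinite(t) and np.isclose(x.mean(), y.mean()) and x.std() == y.std() == 0:
        t, p = 0.0, 1.0
    return GroupComparison(
        groups=labels,
        n_per_group=(x.size, y.size),
        statistic=float(t),
        p_value=float(p),
        stars=star_annotation(float(p)),
        test="t_welch" if welch else "t_unpaired",
    )


def anova_oneway(
    groups: Sequence[Sequence[float]] | dict[str, Sequence[float]],
) -> GroupComparison:
    """One-way ANOVA from between/within mean squares.

    Degenerate variance cases follow the natural conventions: all
    observations identical across groups gives F = 0, p = 1; distinct group
    means with zero within-group scatter give F = inf, p = 0.
    """
    if isinstance(groups, dict):
        labels = tuple(groups)
        data = [_check_group(groups[k], k) for k in labels]
    else:
        data = [_check_group(g, str(i)) for i, g in enumerate(groups)]
        labels = tuple(f"group{i + 1}" for i in range(len(data)))
    if len(data) < 2:
        raise ValueError("one-way ANOVA needs at least 2 groups")
    k = len(data)
    n_total = sum(g.size for g in data)
    grand = np.concatenate(data).mean()
    ss_between = sum(g.size * (g.mean() - grand) ** 2 for g in data)
    ss_within = sum(((g - g.mean()) ** 2).sum() for g in data)
    df_between = k - 1
    df_within = n_total - k
    if df_within <= 0:
        raise ValueError("not enough observations for within-group variance")
    if ss_within == 0.0:
        f = 0.0 if ss_between == 0.0 else float("inf")
        p = 1.0 if ss_between == 0.0 else 0.0
    else:
        f = (ss_between / df_between) / (ss_within / df_within)
        p = float(sps.f.sf(f, df_between, df_within))
    return GroupComparison(
        groups=labels,
        n_per_group=tuple(g.size for g in data),
        statistic=float(f),
        p_value=p,
        stars=star_annotation(p),
        test="anova_oneway",
    )


def compare_chord_curves(
    curves_a: pd.DataFrame,
    curves_b: pd.DataFrame,
    labels: tuple[str, str] = ("a", "b"),
    method: str = "t_multiple",
) -> pd.DataFrame | GroupComparison:
    """Compare chord-conductance curves between two groups.

    Inputs are long tables with columns ``v`` (mV) and ``g`` (nS), one row
    per cell per voltage.  ``method='t_multiple'`` runs an unpaired t test at
    each voltage present in both groups and returns one row per voltage
    (p-values uncorrected); ``method='anova_twoway'`` fits a two-factor
    ANOVA (group x voltage) via statsmodels and returns the group effect.
    """
    if method == "t_multiple":
        rows = []
        common = sorted(set(curves_a["v"]).intersection(curves_b["v"]))
        for v in common:
            ga = curves_a.loc[curves_a["v"] == v, "g"].to_numpy()
            gb = curves_b.loc[curves_b["v"] == v, "g"].to_numpy()
            if ga.size < 2 or gb.size < 2:
                continue
            cmp = t_unpaired(ga, gb, labels=labels)
            rows.append({"v_mv": v, **cmp.as_row()})
        if not rows:
            raise ValueError("no common voltages with n >= 2 per group")
        return pd.DataFrame(rows)
    if method == "anova_twoway":
        import statsmodels.api as sm
        from statsmodels.formula.api import ols

        df = pd.concat(
            [curves_a.assign(group=labels[0]), curves_b.assign(group=labels[1])],
            ignore_index=True,
        )
        model = ols("g ~ C(group) + C(v)", data=df).fit()
        table = sm.stats.anova_lm(model, typ=2)
        f = float(table.loc["C(group)", "F"])
        p = float(table.loc["C(group)", "PR(>F)"])
        return GroupComparison(
            groups=labels,
            n_per_group=(
                int((df["group"] == labels[0]).sum()),
                int((df["group"] == labels[1]).sum()),
            ),
            statistic=f,
            p_value=p,
            stars=star_annotation(p),
            test="anova_twoway_group_effect",
        )
    raise ValueError(f"unknown method {method!r}")
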