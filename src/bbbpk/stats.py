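"""Group-comparison statistics for regression lines and factorial designs.

Two families of tests:

* equality of regression lines across k >= 2 groups, by the extra-sum-of-
  squares F test: first slope homogeneity (separate lines vs common slope
  with separate intercepts), then, given a common slope, elevation
  (intercept) equality — the classical ANCOVA decomposition used to compare
  Patlak lines (Ki, then Vi) between groups;
* balanced two-way ANOVA with Sidak-adjusted pairwise post-hoc comparisons,
  used for brain-weight comparisons across genotype x sex.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats as sps
import statsmodels.api as sm
import statsmodels.formula.api as smf


@dataclass(frozen=True)
class GroupComparisonResult:
    """One F test comparing regression lines between groups."""

    test: str                      # "slope_homogeneity" or "elevation"
    F: float
    df: tuple[int, int]
    p: float
    groups: tuple[str, ...]
    #: For the elevation test: whether its premise (a common slope) was not
    #: rejected at alpha by the slope-homogeneity test.
    premise_ok: bool = True


def _rss_line(x: np.ndarray, y: np.ndarray) -> float:
    """Residual sum of squares of a simple OLS line."""
    X = np.column_stack([np.ones_like(x), x])
    resid = y - X @ np.linalg.lstsq(X, y, rcond=None)[0]
    return float(resid @ resid)


def compare_regression_lines(
    groups: dict[str, tuple[Sequence[float], Sequence[float]]],
    alpha: float = 0.05,
) -> list[GroupComparisonResult]:
    """Extra-sum-of-squares F tests for equality of regression lines.

    Parameters
    ----------
    groups:
        Mapping label -> (x, y); each group needs >= 3 points and
        non-constant x.
    alpha:
        Level used only to flag whether the elevation test's common-slope
        premise holds.

    Returns
    -------
    ``[slope_homogeneity, elevation]`` results.  For two groups the slope
    test is the textbook two-slope t test squared (F = t^2).
    """
    if len(groups) < 2:
        raise ValueError("need at least 2 groups to compare")
    labels = tuple(groups)
    xs, ys, gs = [], [], []
    for label in labels:
        x = np.asarray(groups[label][0], dtype=float)
        y = np.asarray(groups[label][1], dtype=float)
        if len(x) != len(y):
            raise ValueError(f"group {label!r}: x and y lengths differ")
        if len(x) < 3:
            raise ValueError(f"group {label!r}: need >= 3 points")
        if np.ptp(x) == 0:
            raise ValueError(f"group {label!r}: constant x, regression undefined")
        xs.append(x)
        ys.append(y)
        gs.append(np.full(len(x), labels.index(label)))
    x = np.concatenate(xs)
    y = np.concatenate(ys)
    g = np.concatenate(gs).astype(int)
    n, k = len(x), len(labels)

    # separate lines: per-group intercept and slope
    rss_sep = sum(_rss_line(xi, yi) for xi, yi in zip(xs, ys))
    df_sep = n - 2 * k

    # common slope, separate intercepts
    X_cs = np.zeros((n, k + 1))
    X_cs[np.arange(n), g] = 1.0
    X_cs[:, k] = x
    resid = y - X_cs @ np.linalg.lstsq(X_cs, y, rcond=None)[0]
    rss_cs = float(resid @ resid)
    df_cs = n - (k + 1)

    # single line
    rss_single = _rss_line(x, y)

    if df_sep <= 0:
        raise ValueError("not enough points for the separate-lines model")

    def ftest(rss0: float, rss1: float, q: int, df1: int) -> tuple[float, float]:
        num = max(rss0 - rss1, 0.0) / q
        den = rss1 / df1
        if den == 0.0:
            f = 0.0 if num == 0.0 else math.inf
        else:
            f = num / den
        return f, float(sps.f.sf(f, q, df1)) if math.isfinite(f) else 0.0

    f_slope, p_slope = ftest(rss_cs, rss_sep, k - 1, df_sep)
    slope_res = GroupComparisonResult(
        test="slope_homogeneity", F=f_slope, df=(k - 1, df_sep), p=p_slope,
        groups=labels,
    )
    f_elev, p_elev = ftest(rss_single, rss_cs, k - 1, df_cs)
    elev_res = GroupComparisonResult(
        test="elevation", F=f_elev, df=(k - 1, df_cs), p=p_elev, groups=labels,
        premise_ok=bool(p_slope >= alpha),
    )
    return [slope_res, elev_res]


# ---------------------------------------------------------------------------
# two-way ANOVA
# ---------------------------------------------------------------------------

@dataclass
class AnovaTable:
    """Classical two-way ANOVA decomposition (balanced design).

    ``table`` rows: factor A, factor B, interaction, residual; columns
    SS, df, MS, F, p.  ``degenerate`` marks an all-constant response, whose
    F ratios are undefined (NaN).
    """

    table: pd.DataFrame
    factor_a: str
    factor_b: str
    degenerate: bool = False

    def row(self, which: str) -> pd.Series:
        return self.table.loc[which]

    @property
    def residual_ms(self) -> float:
        return float(self.table.loc["residual", "MS"])

    @property
    def residual_df(self) -> int:
        return int(self.table.loc["residual", "df"])


def two_way_anova(
    data: pd.DataFrame,
    response: str,
    factor_a: str,
    factor_b: str,
) -> AnovaTable:
    """Balanced two-way ANOVA with interaction.

    Requires >= 2 levels per factor, every cell non-empty, and equal cell
    sizes (unbalanced designs are out of scope and rejected).  In a
    balanced design the decomposition satisfies
    SS_A + SS_B + SS_AB + SS_resid = SS_total.
    """
    df = data[[response, factor_a, factor_b]].dropna()
    counts = df.groupby([factor_a, factor_b], observed=True).size()
    a_levels = df[factor_a].unique()
    b_levels = df[factor_b].unique()
    if len(a_levels) < 2 or len(b_levels) < 2:
        raise ValueError("each factor needs >= 2 levels")
    if len(counts) < len(a_levels) * len(b_levels):
        raise ValueError("empty cell in the factorial design")
    if counts.nunique() != 1:
        raise ValueError(
            "unbalanced design (unequal cell sizes) is out of scope for the "
            "classical decomposition"
        )
    y = df[response].to_numpy(dtype=float)
    degenerate = bool(np.ptp(y) == 0)
    if degenerate:
        # all responses equal: zero SS everywhere, F undefined
        n = len(y)
        dfa, dfb = len(a_levels) - 1, len(b_levels) - 1
        rows = {
            factor_a: (0.0, dfa), factor_b: (0.0, dfb),
            f"{factor_a}:{factor_b}": (0.0, dfa * dfb),
            "residual": (0.0, n - len(a_levels) * len(b_levels)),
        }
        tab = pd.DataFrame(
            {
                "SS": [v[0] for v in rows.values()],
                "df": [v[1] for v in rows.values()],
                "MS": [0.0 if v[1] else math.nan for v in rows.values()],
                "F": math.nan,
                "p": math.nan,
            },
            index=list(rows),
        )
        return AnovaTable(tab, factor_a, factor_b, degenerate=True)

    model = smf.ols(
        f"Q('{response}') ~ C(Q('{factor_a}')) * C(Q('{factor_b}'))", data=df
    ).fit()
    aov = sm.stats.anova_lm(model, typ=2)  # equals classical SS when balanced
    name_a = f"C(Q('{factor_a}'))"
    name_b = f"C(Q('{factor_b}'))"
    name_ab = f"{name_a}:{name_b}"
    order = [name_a, name_b, name_ab, "Residual"]
    aov = aov.loc[order]
    tab = pd.DataFrame(
        {
            "SS": aov["sum_sq"].to_numpy(),
            "df": aov["df"].to_numpy(dtype=int),
            "MS": (aov["sum_sq"] / aov["df"]).to_numpy(),
            "F": aov["F"].to_numpy(),
            "p": aov["PR(>F)"].to_numpy(),
        },
        index=[factor_a, factor_b, f"{factor_a}:{factor_b}", "residual"],
    )
    return AnovaTable(tab, factor_a, factor_b)


def sidak_posthoc(
    data: pd.DataFrame,
    response: str,
    factor_a: str,
    factor_b: str,
    comparisons: Sequence[tuple[tuple, tuple]],
    anova: AnovaTable | None = None,
) -> pd.DataFrame:
    """Sidak-adjusted pairwise cell-mean comparisons after a two-way ANOVA.

    Each comparison is a pair of cells ``((a_level, b_level), (a_level,
    b_level))``.  The t statistic uses the ANOVA residual mean square;
    the adjustment is ``p_adj = 1 - (1 - p)^m`` for m comparisons.
    """
    if anova is None:
        anova = two_way_anova(data, response, factor_a, factor_b)
    ms = anova.residual_ms
    dof = anova.residual_df
    # guard against an exactly-saturated model, allowing for the ~1e-30
    # rounding residue a least-squares fit leaves behind
    total_ss = float(anova.table["SS"].sum())
    if not (math.isfinite(ms) and ms > max(total_ss, 1.0) * 1e-12):
        raise ValueError("residual mean square is zero; post-hoc t undefined")
    cells = data.groupby([factor_a, factor_b], observed=True)[response]
    means = cells.mean()
    ns = cells.size()
    m = len(comparisons)
    rows = []
    for c1, c2 in comparisons:
        mean1, mean2 = means[tuple(c1)], means[tuple(c2)]
        n1, n2 = ns[tuple(c1)], ns[tuple(c2)]
        t = (mean1 - mean2) / math.sqrt(ms * (1.0 / n1 + 1.0 / n2))
        p = float(2.0 * sps.t.sf(abs(t), dof))
        p_adj = float(min(1.0, 1.0 - (1.0 - p) ** m))
        rows.append(
            {
                "cell_1": " ".join(map(str, c1)),
                "cell_2": " ".join(map(str, c2)),
                "mean_diff": float(mean1 - mean2),
                "t": float(t),
                "df": dof,
                "p": p,
                "p_sidak": p_adj,
                "m": m,
            }
        )
    return pd.DataFrame(rows)


def sidak_adjust(p: float, m: int) -> float:
    """Sidak family-wise adjustment: 1 - (1 - p)^m, capped at 1."""
    if not 0 <= p <= 1:
        raise ValueError("p must be in [0, 1]")
    if m < 1:
        raise ValueError("m must be >= 1")
    return min(1.0, 1.0 - (1.0 - p) ** m)
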