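"""Statistical layer: outlier exclusion and group comparisons.

Derived scalars (regression slopes, beta, d100, rectilinearity, ...) are
compared between genotype/treatment groups after Grubbs (maximum
normalized residual) outlier exclusion. Supported designs: Student and
Welch t tests, Mann-Whitney U, one-way ANOVA with Sidak-adjusted pairwise
comparisons, and two-way ANOVA (group x within-curve factor such as
pressure) with Sidak-adjusted per-level comparisons. Results are
summarized as mean +/- SEM; significance is declared at p < 0.05.
"""

from __future__ import annotations

import itertools
import warnings
from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats as sps
import statsmodels.api as sm
import statsmodels.formula.api as smf

__all__ = [
    "GrubbsResult",
    "grubbs_critical",
    "grubbs_exclude",
    "sidak_adjust",
    "group_summary",
    "compare_groups",
    "compare_slopes",
]

ALPHA = 0.05


@dataclass(frozen=True)
class GrubbsResult:
    retained: np.ndarray
    excluded_indices: tuple[int, ...]  # indices into the original array
    excluded_values: tuple[float, ...]


def grubbs_critical(n: int, alpha: float = ALPHA) -> float:
    """Two-sided Grubbs critical value for sample size n.

    ``G_c = ((n-1)/sqrt(n)) * sqrt(t^2 / (n-2+t^2))`` with t the upper
    ``alpha/(2n)`` quantile of Student's t with n-2 degrees of freedom.
    """
    if n < 3:
        raise ValueError("Grubbs test needs n >= 3")
    t = sps.t.ppf(1.0 - alpha / (2.0 * n), n - 2)
    return (n - 1) / np.sqrt(n) * np.sqrt(t**2 / (n - 2 + t**2))


def grubbs_exclude(
    values: Sequence[float],
    alpha: float = ALPHA,
    max_removals: int | None = None,
) -> GrubbsResult:
    """Iterative two-sided Grubbs exclusion.

    At each pass the point with the maximum normalized residual
    ``G = max|x - mean| / sd`` is removed if G exceeds the critical value;
    iteration stops when nothing is flagged, fewer than 3 points remain, or
    the removal cap (default ``floor(n/5)``, a safety limit against
    degenerate repeated exclusion) is reached. A zero-variance sample
    excludes nothing and emits a warning.
    """
    x = np.asarray(values, dtype=float)
    n0 = x.size
    if n0 < 3:
        raise ValueError("Grubbs test needs n >= 3")
    if max_removals is None:
        max_removals = n0 // 5
    active = np.arange(n0)
    excluded: list[int] = []
    while active.size >= 3 and len(excluded) < max_removals:
        sub = x[active]
        s = sub.std(ddof=1)
        if s == 0:
            warnings.warn("zero variance: Grubbs test excludes nothing")
            break
        resid = np.abs(sub - sub.mean())
        i_max = int(np.argmax(resid))
        g = resid[i_max] / s
        if g <= grubbs_critical(active.size, alpha):
            break
        excluded.append(int(active[i_max]))
        active = np.delete(active, i_max)
    return GrubbsResult(
        retained=x[active],
        excluded_indices=tuple(excluded),
        excluded_values=tuple(float(x[i]) for i in excluded),
    )


def sidak_adjust(p: float | np.ndarray, k: int) -> float | np.ndarray:
    """Sidak adjustment for k planned comparisons: ``p' = 1 - (1-p)^k``."""
    if k < 1:
        raise ValueError("k must be >= 1")
    return 1.0 - (1.0 - np.asarray(p, dtype=float)) ** k if np.ndim(p) else float(
        1.0 - (1.0 - p) ** k
    )


def group_summary(values: Sequence[float]) -> tuple[float, float]:
    """(mean, SEM) of a sample."""
    x = np.asarray(values, dtype=float)
    sem = x.std(ddof=1) / np.sqrt(x.size) if x.size > 1 else float("nan")
    return float(x.mean()), float(sem)


def _check_groups(groups: dict[str, np.ndarray]) -> None:
    for name, vals in groups.items():
        if vals.size < 2:
            raise ValueError(f"group {name!r} has fewer than 2 values")


def compare_groups(
    table: pd.DataFrame,
    metric: str | None = None,
    design: str = "t",
    alpha: float = ALPHA,
    value_col: str = "value",
    group_col: str = "group",
    factor_col: str | None = None,
) -> pd.DataFrame:
    """Compare a metric between groups under a named design.

    ``table`` holds one row per animal (and, for ``anova2+sidak``, per
    level of the within-curve factor, e.g. pressure) with columns
    ``group_col`` and ``value_col``; if ``metric`` is given the table is
    first filtered on its ``metric`` column. Designs:

    - ``"t"`` / ``"welch-t"``: pairwise Student / Welch t tests,
    - ``"mann-whitney"``: pairwise Mann-Whitney U,
    - ``"anova1+sidak"``: one-way ANOVA, then pairwise t tests with Sidak
      adjustment over the number of comparisons,
    - ``"anova2+sidak"``: two-way ANOVA (group x factor, with interaction)
      followed by per-factor-level group t tests, Sidak-adjusted over the
      number of levels.

    Returns one row per comparison with the effect (difference of means),
    raw and adjusted p-values, and a significance flag at ``alpha``.
    """
    if metric is not None:
        table = table[table["metric"] == metric]
    if table.empty:
        raise ValueError("no rows to compare")
    if design == "anova2+sidak":
        return _anova2_sidak(table, value_col, group_col, factor_col, alpha)
    groups = {
        str(name): g[value_col].to_numpy(float)
        for name, g in table.groupby(group_col, sort=True)
    }
    _check_groups(groups)
    pairs = list(itertools.combinations(sorted(groups), 2))
    rows = []
    k = len(pairs)
    f_p = np.nan
    if design == "anova1+sidak":
        f_stat, f_p = sps.f_oneway(*groups.values())
    for a, b in pairs:
        xa, xb = groups[a], groups[b]
        if design in ("t", "anova1+sidak"):
            stat, p = sps.ttest_ind(xa, xb, equal_var=True)
        elif design == "welch-t":
            stat, p = sps.ttest_ind(xa, xb, equal_var=False)
        elif design == "mann-whitney":
            stat, p = sps.mannwhitneyu(xa, xb, alternative="two-sided")
        else:
            raise ValueError(f"unknown design {design!r}")
        p = float(p)
        p_adj = sidak_adjust(p, k) if design == "anova1+sidak" else p
        rows.append(
            {
                "group_a": a,
                "group_b": b,
                "n_a": xa.size,
                "n_b": xb.size,
                "mean_a": xa.mean(),
                "mean_b": xb.mean(),
                "effect": xa.mean() - xb.mean(),
                "statistic": float(stat),
                "p": p,
                "p_adjusted": float(p_adj),
                "anova_p": float(f_p),
                "significant": float(p_adj) < alpha,
            }
        )
    return pd.DataFrame(rows)


def _anova2_sidak(
    table: pd.DataFrame,
    value_col: str,
    group_col: str,
    factor_col: str | None,
    alpha: float,
) -> pd.DataFrame:
    if factor_col is None:
        raise ValueError("anova2+sidak needs factor_col (e.g. pressure)")
    df = table.rename(
        columns={value_col: "y", group_col: "grp", factor_col: "fac"}
    )[["y", "grp", "fac"]].copy()
    model = smf.ols("y ~ C(grp) * C(fac)", data=df).fit()
    anova = sm.stats.anova_lm(model, typ=2)
    levels = sorted(df["fac"].unique())
    k = len(levels)
    rows = []
    for level in levels:
        sub = df[df["fac"] == level]
        groups = {
            str(name): g["y"].to_numpy(float) for name, g in sub.groupby("grp")
        }
        _check_groups(groups)
        names = sorted(groups)
        for a, b in itertools.combinations(names, 2):
            stat, p = sps.ttest_ind(groups[a], groups[b], equal_var=True)
            p_adj = sidak_adjust(float(p), k)
            rows.append(
                {
                    "factor_level": level,
                    "group_a": a,
                    "group_b": b,
                    "effect": groups[a].mean() - groups[b].mean(),
                    "statistic": float(stat),
                    "p": float(p),
                    "p_adjusted": float(p_adj),
                    "anova_group_p": float(anova.loc["C(grp)", "PR(>F)"]),
                    "anova_interaction_p": float(
                        anova.loc["C(grp):C(fac)", "PR(>F)"]
                    ),
                    "significant": float(p_adj) < alpha,
                }
            )
    return pd.DataFrame(rows)


def compare_slopes(
    fits_a: Sequence, fits_b: Sequence, method: str = "per-animal"
) -> dict:
    """Compare wire-myography regression slopes between two groups.

    ``method="per-animal"`` (default): Student t test on per-segment fitted
    slopes, matching the one-regression-per-vessel design.
    ``method="ancova"``: pool the raw diameter-tension points and test the
    group x diameter interaction (common-slope test) in an OLS model.
    """

    def slopes(fits):
        return np.array([f.slope for f in fits], dtype=float)

    if method == "per-animal":
        sa, sb = slopes(fits_a), slopes(fits_b)
        if sa.size < 2 or sb.size < 2:
            raise ValueError("need at least 2 fits per group")
        if np.ptp(np.concatenate([sa, sb])) == 0:
            # degenerate but well-defined: identical slopes everywhere
            stat, p = 0.0, 1.0
        else:
            stat, p = sps.ttest_ind(sa, sb, equal_var=True)
        return {
            "method": "per-animal",
            "mean_slope_a": float(sa.mean()),
            "mean_slope_b": float(sb.mean()),
            "statistic": float(stat),
            "p": float(p),
        }
    if method == "ancova":
        frames = []
        for label, curves in (("A", fits_a), ("B", fits_b)):
            if len(curves) < 2:
                raise ValueError("need at least 2 curves per group")
            for c in curves:
                frames.append(
                    pd.DataFrame(
                        {
                            "d": c.diameters_um,
                            "t": c.tensions_mn_per_mm,
                            "grp": label,
                        }
                    )
                )
        df = pd.concat(frames, ignore_index=True)
        model = smf.ols("t ~ d * C(grp)", data=df).fit()
        term = "d:C(grp)[T.B]"
        return {
            "method": "ancova",
            "interaction_coef": float(model.params[term]),
            "statistic": float(model.tvalues[term]),
            "p": float(model.pvalues[term]),
        }
    raise ValueError("method must be 'per-animal' or 'ancova'")
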