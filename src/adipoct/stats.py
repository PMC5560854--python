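"""Method-agreement and group-comparison statistics.

Pearson correlation and least-squares regression (scipy) for comparing fat
estimates between methods, plus classical fixed-effects ANOVA tables.
ANOVA sums of squares are computed from the definitional decompositions so
degenerate designs have controlled conventions: an effect with zero sum of
squares gets F = 0, and a positive effect over a zero residual gets
F = inf with p = 0. Two-way tables are restricted to balanced complete
designs, where Type I/II/III sums of squares coincide.
"""

from __future__ import annotations

import dataclasses

import numpy as np
import pandas as pd
from scipy import stats as sps

from .volume_io import DataError


@dataclasses.dataclass(frozen=True)
class RegressionFit:
    """Least-squares fit / correlation between two variables."""

    slope: float | None
    intercept: float | None
    r: float
    n: int
    p_value: float
    slope_se: float | None = None

    def __post_init__(self):
        if not (-1.0 - 1e-12 <= self.r <= 1.0 + 1e-12):
            raise DataError(f"correlation out of [-1, 1]: {self.r}")

    def slope_ci(self, level: float = 0.95) -> tuple[float, float]:
        """Two-sided t confidence interval for the slope."""
        if self.slope is None or self.slope_se is None:
            raise DataError("no slope available: this fit is correlation-only")
        t = sps.t.ppf(0.5 + level / 2.0, self.n - 2)
        return (self.slope - t * self.slope_se, self.slope + t * self.slope_se)


def _check_xy(x, y) -> tuple[np.ndarray, np.ndarray]:
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or x.ndim != 1:
        raise DataError("x and y must be 1-D arrays of equal length")
    if x.size < 3:
        raise DataError(f"need at least 3 paired values, got {x.size}")
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        raise DataError("correlation is undefined for a constant input")
    return x, y


def pearson_r(x, y) -> RegressionFit:
    """Product-moment correlation with a two-sided p from the t transform."""
    x, y = _check_xy(x, y)
    res = sps.pearsonr(x, y)
    return RegressionFit(slope=None, intercept=None, r=float(res.statistic),
                         n=int(x.size), p_value=float(res.pvalue))


def linfit(x, y) -> RegressionFit:
    """Ordinary least-squares line y = slope * x + intercept."""
    x, y = _check_xy(x, y)
    res = sps.linregress(x, y)
    return RegressionFit(
        slope=float(res.slope),
        intercept=float(res.intercept),
        r=float(res.rvalue),
        n=int(x.size),
        p_value=float(res.pvalue),
        slope_se=float(res.stderr),
    )


def _f_and_p(ss_effect: float, df_effect: float, ss_resid: float, df_resid: float):
    """F statistic with explicit degenerate conventions."""
    if ss_effect <= 0:
        return 0.0, 1.0
    if ss_resid <= 0 or df_resid <= 0:
        return float("inf"), 0.0
    f = (ss_effect / df_effect) / (ss_resid / df_resid)
    return float(f), float(sps.f.sf(f, df_effect, df_resid))


def anova_one_way(groups) -> pd.DataFrame:
    """One-way fixed-effects ANOVA table (between/within decomposition).

    Returns a DataFrame indexed by effect with columns sum_sq, df, F, p;
    degrees of freedom sum to n - 1.
    """
    arrays = [np.asarray(g, dtype=float) for g in groups]
    if len(arrays) < 2:
        raise DataError("one-way ANOVA needs at least 2 groups")
    if any(a.size < 2 for a in arrays):
        raise DataError("every group needs at least 2 values")
    all_values = np.concatenate(arrays)
    grand = all_values.mean()
    n = all_values.size
    k = len(arrays)
    ss_between = float(sum(a.size * (a.mean() - grand) ** 2 for a in arrays))
    ss_within = float(sum(((a - a.mean()) ** 2).sum() for a in arrays))
    df_between, df_within = k - 1, n - k
    f, p = _f_and_p(ss_between, df_between, ss_within, df_within)
    return pd.DataFrame(
        {
            "sum_sq": [ss_between, ss_within],
            "df": [df_between, df_within],
            "F": [f, np.nan],
            "p": [p, np.nan],
        },
        index=["between", "within"],
    )


def anova_two_way(
    data: pd.DataFrame,
    value: str,
    factor_a: str,
    factor_b: str,
    alpha: float = 0.05,
) -> pd.DataFrame:
    """Two-way fixed-effects ANOVA with interaction, balanced designs only.

    Returns a DataFrame indexed by effect (factor names, ``A:B``,
    ``residual``) with columns sum_sq, df, F, p and a boolean
    ``significant`` at the requested alpha.
    """
    for col in (value, factor_a, factor_b):
        if col not in data.columns:
            raise DataError(f"column {col!r} absent from the data")
    df = data[[factor_a, factor_b, value]].dropna()
    a_levels = sorted(df[factor_a].unique().tolist())
    b_levels = sorted(df[factor_b].unique().tolist())
    if len(a_levels) < 2 or len(b_levels) < 2:
        raise DataError("both factors need at least 2 levels")
    counts = df.groupby([factor_a, factor_b], sort=True)[value].count()
    if counts.size != len(a_levels) * len(b_levels) or counts.nunique() != 1:
        raise DataError("two-way ANOVA requires a balanced complete design")
    n_cell = int(counts.iloc[0])
    if n_cell < 1:
        raise DataError("empty cells in the design")

    y = df[value].to_numpy(dtype=float)
    grand = y.mean()
    cell_means = df.groupby([factor_a, factor_b], sort=True)[value].mean()
    a_means = df.groupby(factor_a, sort=True)[value].mean()
    b_means = df.groupby(factor_b, sort=True)[value].mean()

    nb, na = len(b_levels), len(a_levels)
    ss_a = float(n_cell * nb * ((a_means - grand) ** 2).sum())
    ss_b = float(n_cell * na * ((b_means - grand) ** 2).sum())
    ss_ab = float(
        n_cell
        * sum(
            (cell_means[(a, b)] - a_means[a] - b_means[b] + grand) ** 2
            for a in a_levels
            for b in b_levels
        )
    )
    resid = df[value] - df.set_index([factor_a, factor_b]).index.map(cell_means)
    ss_resid = float((resid.to_numpy() ** 2).sum())

    df_a, df_b = na - 1, nb - 1
    df_ab = df_a * df_b
    df_resid = y.size - na * nb
    rows = []
    for name, ss, d in ((factor_a, ss_a, df_a), (factor_b, ss_b, df_b),
                        (f"{factor_a}:{factor_b}", ss_ab, df_ab)):
        f, p = _f_and_p(ss, d, ss_resid, df_resid)
        rows.append({"effect": name, "sum_sq": ss, "df": d, "F": f, "p": p,
                     "significant": bool(p < alpha)})
    rows.append({"effect": "residual", "sum_sq": ss_resid, "df": df_resid,
                 "F": np.nan, "p": np.nan, "significant": False})
    return pd.DataFrame(rows).set_index("effect")
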