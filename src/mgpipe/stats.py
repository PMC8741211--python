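"""Group-level statistics for the imaging experiments.

Paired odour comparisons are normality-gated: the D'Agostino-Pearson test on
the within-pair differences decides between a paired t-test and the Wilcoxon
matched-pairs signed-rank test.  Distribution comparisons use the two-sample
Kolmogorov-Smirnov test on raw pooled peak values (histograms are
presentation-only).  The APL-silencing design is analysed with a two-factor
ANOVA plus Tukey-adjusted within-condition contrasts.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats as sps

log = logging.getLogger("mgpipe.stats")

__all__ = [
    "TestReport",
    "paired_compare",
    "ks_compare",
    "response_distance",
    "distance_compare",
    "two_factor_compare",
    "ols_slope_interaction",
]


@dataclass
class TestReport:
    test_name: str
    statistic: float
    p_value: float
    n: int
    normality_p: float | None = None
    degenerate: bool = False

    def to_dict(self) -> dict:
        return {
            "test": self.test_name,
            "statistic": self.statistic,
            "p": self.p_value,
            "n": self.n,
            "normality_p": self.normality_p,
            "degenerate": self.degenerate,
        }


def paired_compare(a, b, alpha_norm: float = 0.05) -> TestReport:
    """Paired two-odour comparison with a normality gate on the differences.

    Differences passing the D'Agostino-Pearson test at ``alpha_norm`` are
    analysed with a paired t-test, otherwise with the Wilcoxon matched-pairs
    signed-rank test.  Zero-variance differences yield a degenerate report
    (p = 1 when all differences are exactly zero).
    """
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if a.shape != b.shape:
        raise ValueError("paired samples must have equal length")
    n = len(a)
    if n < 3:
        raise ValueError("paired comparison requires n >= 3")
    d = a - b
    if np.ptp(d) == 0:
        p = 1.0 if np.all(d == 0) else float("nan")
        return TestReport("degenerate (zero-variance differences)", 0.0, p, n,
                          degenerate=True)
    with warnings.catch_warnings():
        # the omnibus test warns below n=20; the gate is still usable there
        warnings.simplefilter("ignore")
        _, p_norm = sps.normaltest(d)
    if p_norm >= alpha_norm:
        t, p = sps.ttest_rel(a, b)
        return TestReport("paired t-test", float(t), float(p), n,
                          normality_p=float(p_norm))
    w, p = sps.wilcoxon(a, b)
    return TestReport("Wilcoxon matched-pairs", float(w), float(p), n,
                      normality_p=float(p_norm))


def ks_compare(a, b) -> TestReport:
    """Two-sample Kolmogorov-Smirnov test on raw pooled values."""
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if len(a) == 0 or len(b) == 0:
        raise ValueError("both samples must be nonempty")
    res = sps.ks_2samp(a, b)
    return TestReport("Kolmogorov-Smirnov", float(res.statistic),
                      float(res.pvalue), len(a) + len(b))


def response_distance(
    summaries: pd.DataFrame, odour_a: str, odour_b: str, value: str = "mean_peak"
) -> pd.DataFrame:
    """Per-fly response distance ``delta = value(B) - value(A)``.

    ``summaries`` holds one row per (fly, odour, trial); trials are averaged
    within fly and odour first.  Flies missing either odour are excluded
    (logged).  Returns a per-fly frame with a ``delta`` column.
    """
    per_fly = (summaries.groupby(["fly", "odour"])[value].mean().unstack())
    missing = per_fly.index[per_fly[[odour_a, odour_b]].isna().any(axis=1)]
    if len(missing):
        log.warning("response_distance: excluding flies without both odours: %s",
                    list(missing))
        per_fly = per_fly.drop(index=missing)
    delta = per_fly[odour_b] - per_fly[odour_a]
    return pd.DataFrame({
        "fly": per_fly.index,
        odour_a: per_fly[odour_a].to_numpy(),
        odour_b: per_fly[odour_b].to_numpy(),
        "delta": delta.to_numpy(),
    }).reset_index(drop=True)


def distance_compare(delta_1, delta_2) -> TestReport:
    """Unpaired comparison of two groups of per-fly distances
    (Welch-corrected t-test, the unequal-variance analogue of the group
    comparison of odour-pair gaps)."""
    t, p = sps.ttest_ind(np.asarray(delta_1, float), np.asarray(delta_2, float),
                         equal_var=False)
    return TestReport("Welch t-test", float(t), float(p),
                      len(delta_1) + len(delta_2))


def two_factor_compare(
    summaries: pd.DataFrame,
    value: str = "mean_peak",
    condition_col: str = "condition",
    odour_col: str = "odour",
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Two-factor (condition x odour) ANOVA with Tukey contrasts.

    Returns ``(anova_table, contrasts)`` where ``contrasts`` holds the
    Tukey-HSD-adjusted pairwise odour comparisons within each condition
    (adjustment is over all cell pairs, as in a standard interaction
    follow-up).  Raises when a design cell is empty.
    """
    import statsmodels.api as sm
    from statsmodels.formula.api import ols
    from statsmodels.stats.multicomp import pairwise_tukeyhsd

    df = summaries.rename(columns={condition_col: "condition",
                                   odour_col: "odour"}).copy()
    df = df.dropna(subset=[value])
    cells = df.groupby(["condition", "odour"], observed=True)[value].count()
    conditions = df["condition"].unique()
    odours = df["odour"].unique()
    for c in conditions:
        for o in odours:
            if (c, o) not in cells.index or cells[(c, o)] == 0:
                raise ValueError(f"empty design cell: condition={c!r}, odour={o!r}")
            if cells[(c, o)] < 2:
                raise ValueError(f"design cell condition={c!r}, odour={o!r} "
                                 "needs >= 2 observations")

    model = ols(f"{value} ~ C(condition) * C(odour)", data=df).fit()
    anova = sm.stats.anova_lm(model, typ=2)

    cell = df["condition"].astype(str) + "|" + df["odour"].astype(str)
    tukey = pairwise_tukeyhsd(df[value].to_numpy(), cell.to_numpy())
    rows = []
    res = tukey.summary().data[1:]
    for g1, g2, meandiff, p_adj, lower, upper, reject in res:
        c1, o1 = str(g1).split("|")
        c2, o2 = str(g2).split("|")
        if c1 == c2:  # within-condition odour contrast
            rows.append({
                "condition": c1, "odour_1": o1, "odour_2": o2,
                "mean_diff": float(meandiff), "p_adj": float(p_adj),
                "reject": bool(reject),
            })
    return anova, pd.DataFrame(rows)


def ols_slope_interaction(
    z1: np.ndarray, y1: np.ndarray, z2: np.ndarray, y2: np.ndarray
) -> tuple[float, float, float]:
    """Slopes of two groups and the p-value of their difference.

    Pooled OLS ``y ~ 1 + z + group + z:group`` with a t-test on the
    interaction coefficient; built on a plain design matrix so thousands of
    Monte-Carlo calls stay cheap.
    """
    z = np.concatenate([z1, z2]).astype(float)
    y = np.concatenate([y1, y2]).astype(float)
    g = np.concatenate([np.zeros(len(z1)), np.ones(len(z2))])
    X = np.column_stack([np.ones_like(z), z, g, z * g])
    n, k = X.shape
    if n <= k:
        raise ValueError("not enough points for the pooled slope model")
    beta, _, rank, _ = np.linalg.lstsq(X, y, rcond=None)
    if rank < k:
        raise ValueError("degenerate design (need >= 2 distinct z per group)")
    resid = y - X @ beta
    sigma2 = resid @ resid / (n - k)
    slope1 = float(beta[1])
    slope2 = float(beta[1] + beta[3])
    scale = max(1.0, float(np.abs(y).max()))
    if sigma2 <= (1e-12 * scale) ** 2:  # exact fit: no residual error to test against
        p_int = 1.0 if abs(beta[3]) <= 1e-12 * scale else 0.0
        return slope1, slope2, p_int
    cov = sigma2 * np.linalg.inv(X.T @ X)
    t_int = beta[3] / np.sqrt(cov[3, 3])
    p_int = 2.0 * sps.t.sf(abs(t_int), df=n - k)
    return slope1, slope2, float(p_int)
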