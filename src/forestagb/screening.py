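"""Outlier removal and Pearson screening of candidate predictors.

The screening stage (i) drops plots whose recorded biomass is a gross
outlier, (ii) correlates every catalogue variable against plot biomass
with the two-pass Pearson estimator, (iii) attaches two-sided p-values
from the exact t transform and (iv) selects the predictors significant at
a chosen level, ordered by |r|.

No multiple-testing correction is applied — the correlation table records
the number of tests performed so users can judge the family-wise risk
themselves.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "remove_outliers",
    "pearson_r",
    "pearson_p",
    "correlation_table",
    "select_predictors",
]


def remove_outliers(
    plots: pd.DataFrame,
    column: str = "agb",
    rule: str = "mean_sd_iterative",
    k: float = 3.0,
    max_iter: int = 200,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Drop plots whose ``column`` value lies outside mean ± k·SD.

    rule="mean_sd" applies the band once; the default
    "mean_sd_iterative" recomputes mean and SD on the retained set and
    repeats until no further plot is excluded, which is robust to heavy
    one-sided contamination where a single pass removes nothing.

    Returns ``(retained plots, removal log)``; the log records plot_id,
    value and the band that excluded it.  Raises if fewer than 3 plots are
    given or if the rule would remove everything.
    """
    if len(plots) < 3:
        raise ValueError("outlier removal needs at least 3 plots")
    x = plots[column].to_numpy(dtype=float)
    keep = np.ones(len(x), dtype=bool)
    n_pass = 1 if rule == "mean_sd" else max_iter
    if rule not in ("mean_sd", "mean_sd_iterative"):
        raise ValueError(f"unknown outlier rule {rule!r}")
    lo = hi = np.nan
    for _ in range(n_pass):
        m = x[keep].mean()
        s = x[keep].std(ddof=1)
        lo, hi = m - k * s, m + k * s
        new = keep & (x >= lo) & (x <= hi)
        if new.sum() == 0:
            raise ValueError("outlier rule removed every plot")
        if new.sum() == keep.sum():
            break
        keep = new
    log = pd.DataFrame(
        {
            "plot_id": plots.loc[~keep, "plot_id"].to_numpy(),
            column: x[~keep],
            "reason": [f"outside [{lo:.6g}, {hi:.6g}] ({rule}, k={k})"] * int((~keep).sum()),
        }
    )
    return plots.loc[keep].reset_index(drop=True), log


def pearson_r(x, y) -> float:
    """Pearson product-moment correlation, two-pass form.

    r = sum((x-x̄)(y-ȳ)) / (sqrt(sum((x-x̄)²)) * sqrt(sum((y-ȳ)²)))

    Returns NaN when either vector has zero variance.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or x.ndim != 1:
        raise ValueError("x and y must be 1-D and the same length")
    if len(x) < 3:
        raise ValueError("need at least 3 observations")
    xc = x - x.mean()
    yc = y - y.mean()
    den = np.sqrt((xc**2).sum()) * np.sqrt((yc**2).sum())
    if den == 0:
        return float("nan")
    return float((xc * yc).sum() / den)


def pearson_p(r: float, n: int) -> float:
    """Two-sided p-value for a Pearson r at sample size n.

    Uses t = r * sqrt((n-2) / (1-r²)) against Student's t with n-2 df.
    |r| = 1 returns 0 by convention; NaN r propagates.
    """
    if n < 3:
        raise ValueError("need n >= 3")
    if np.isnan(r):
        return float("nan")
    if abs(r) >= 1.0:
        return 0.0
    t = r * np.sqrt((n - 2) / (1.0 - r * r))
    return float(2.0 * stats.t.sf(abs(t), df=n - 2))


def _tier(p: float) -> str:
    if np.isnan(p):
        return "none"
    if p < 0.01:
        return "p<0.01"
    if p < 0.05:
        return "p<0.05"
    return "none"


def correlation_table(features: pd.DataFrame, biomass: pd.Series | np.ndarray) -> pd.DataFrame:
    """Pearson r, two-sided p and significance tier of every feature column.

    ``features`` holds numeric predictor columns (a leading ``plot_id``
    column is ignored).  Zero-variance features get NaN r/p and tier
    "none".  The result carries ``attrs["n_tests"]``.
    """
    y = np.asarray(biomass, dtype=float)
    cols = [c for c in features.columns if c != "plot_id"]
    recs = []
    for c in cols:
        x = features[c].to_numpy(dtype=float)
        r = pearson_r(x, y)
        p = pearson_p(r, len(x)) if not np.isnan(r) else float("nan")
        recs.append({"feature": c, "r": r, "p": p, "n": len(x), "tier": _tier(p)})
    out = pd.DataFrame(recs)
    out.attrs["n_tests"] = len(cols)
    return out


def select_predictors(table: pd.DataFrame, alpha: float = 0.01) -> list[str]:
    """Features with p < alpha, ordered by |r| descending."""
    sel = table.dropna(subset=["p"])
    sel = sel[sel["p"] < alpha]
    sel = sel.reindex(sel["r"].abs().sort_values(ascending=False).index)
    return sel["feature"].tolist()
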