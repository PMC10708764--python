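"""Held-out model comparison: R² variants, relative errors, mean deviation.

Two R² conventions circulate in the inversion literature and they differ
whenever predictions are biased: the squared Pearson correlation between
predictions and observations ("corr", invariant to affine rescaling of
the predictions) and the coefficient of determination 1 - SSres/SStot
("cod").  Both are always computed and reports label which one a
comparison uses.

Relative errors are signed percentages 100*(pred-obs)/obs; the mean
deviation is the mean absolute relative error after discarding entries
whose magnitude exceeds a threshold (100% by default).
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .screening import pearson_r

__all__ = [
    "r_squared",
    "relative_errors",
    "mean_deviation_after_discard",
    "compare_models",
]


def r_squared(pred, obs, variant: str = "cod") -> float:
    """R² of predictions against observations.

    variant="corr": squared Pearson correlation; variant="cod":
    1 - SSres/SStot.  NaN when the observations have zero variance.
    """
    p = np.asarray(pred, dtype=float)
    o = np.asarray(obs, dtype=float)
    if len(p) != len(o) or len(o) < 3:
        raise ValueError("pred and obs must have equal length >= 3")
    sstot = float(((o - o.mean()) ** 2).sum())
    if sstot == 0:
        return float("nan")
    if variant == "corr":
        r = pearson_r(p, o)
        return float("nan") if np.isnan(r) else r * r
    if variant == "cod":
        ssres = float(((o - p) ** 2).sum())
        return 1.0 - ssres / sstot
    raise ValueError(f"unknown R² variant {variant!r}")


def relative_errors(pred, obs) -> np.ndarray:
    """Signed relative errors in percent, 100*(pred-obs)/obs.

    Entries with obs == 0 are NaN (flagged, never silently zero).
    """
    p = np.asarray(pred, dtype=float)
    o = np.asarray(obs, dtype=float)
    with np.errstate(divide="ignore", invalid="ignore"):
        out = np.where(o == 0, np.nan, 100.0 * (p - o) / np.where(o == 0, np.nan, o))
    return out


def mean_deviation_after_discard(rel_errors, threshold: float = 100.0):
    """Mean absolute relative error after discarding |error| > threshold.

    Returns ``(mean_abs_percent, n_discarded)``; NaN entries are not
    counted as discards but are excluded from the mean.  If everything is
    discarded the mean is NaN.
    """
    e = np.asarray(rel_errors, dtype=float)
    if e.size == 0:
        raise ValueError("empty relative-error vector")
    finite = e[~np.isnan(e)]
    kept = finite[np.abs(finite) <= threshold]
    n_disc = int(len(finite) - len(kept))
    mean = float(np.mean(np.abs(kept))) if len(kept) else float("nan")
    return mean, n_disc


def compare_models(predictions: dict[str, np.ndarray], obs, threshold: float = 100.0) -> pd.DataFrame:
    """Table-style comparison of several models on one shared test set.

    ``predictions`` maps model name -> prediction vector; all vectors must
    match the observation length.  One row per model with both R²
    variants, the extreme signed relative errors, the count discarded by
    the |error| > threshold rule and the mean deviation after discard.
    """
    o = np.asarray(obs, dtype=float)
    rows = []
    for name, pred in predictions.items():
        p = np.asarray(pred, dtype=float)
        if p.shape != o.shape:
            raise ValueError(f"model {name!r} predictions do not match the test set")
        rel = relative_errors(p, o)
        mean_dev, n_disc = mean_deviation_after_discard(rel, threshold)
        rows.append(
            {
                "model": name,
                "r2_cod": r_squared(p, o, "cod"),
                "r2_corr": r_squared(p, o, "corr"),
                "max_rel_err_pct": float(np.nanmax(rel)),
                "min_rel_err_pct": float(np.nanmin(rel)),
                "n_discarded": n_disc,
                "mean_deviation_pct": mean_dev,
                "n_negative_pred": int((p < 0).sum()),
            }
        )
    return pd.DataFrame(rows)
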