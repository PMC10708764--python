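"""Per-tree allometric above-ground biomass and plot/species aggregation.

The biomass of a single tree is modelled by the power-law allometric
equation

    W = a * D**b * H**c

where D is the diameter at breast height (cm), H the tree height (m) and
(a, b, c) empirical parameters.  The default parameter set is the
published mixed-species calibration used throughout this package
(a=0.0470, b=2.1181, c=0.7088).  The output unit is carried as opaque
"biomass units" per tree: the source calibration does not state the unit
and the package never converts it silently.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

__all__ = [
    "AllometryParams",
    "DEFAULT_PARAMS",
    "tree_agb",
    "plot_biomass",
    "species_share",
]

TREE_COLUMNS = ["plot_id", "species", "dbh_cm", "height_m"]


@dataclass(frozen=True)
class AllometryParams:
    """Power-law coefficients W = a * D**b * H**c."""

    a: float = 0.0470
    b: float = 2.1181
    c: float = 0.7088

    def __post_init__(self) -> None:
        if self.a < 0:
            raise ValueError(f"scale coefficient a must be >= 0, got {self.a}")


DEFAULT_PARAMS = AllometryParams()


def tree_agb(dbh_cm, height_m, params: AllometryParams = DEFAULT_PARAMS):
    """Above-ground biomass of one tree (or an array of trees).

    Parameters
    ----------
    dbh_cm : float or array-like
        Diameter at breast height, cm, strictly positive.
    height_m : float or array-like
        Tree height, m, strictly positive.
    params : AllometryParams
        Allometric coefficients.

    Returns
    -------
    float or ndarray
        Biomass W = a * D**b * H**c in model units.
    """
    d = np.asarray(dbh_cm, dtype=float)
    h = np.asarray(height_m, dtype=float)
    if np.any(d <= 0):
        raise ValueError("dbh must be strictly positive")
    if np.any(h <= 0):
        raise ValueError("height must be strictly positive")
    w = params.a * d**params.b * h**params.c
    return float(w) if np.isscalar(dbh_cm) and np.isscalar(height_m) else w


def plot_biomass(trees: pd.DataFrame, params: AllometryParams = DEFAULT_PARAMS) -> pd.DataFrame:
    """Sum per-tree biomass within each plot.

    ``trees`` needs columns plot_id, dbh_cm, height_m.  Returns a frame
    with one row per plot_id: columns ``agb`` and ``n_trees``.
    """
    if trees.empty:
        return pd.DataFrame({"plot_id": [], "agb": [], "n_trees": []}).astype(
            {"plot_id": object, "agb": float, "n_trees": int}
        )
    w = tree_agb(trees["dbh_cm"].to_numpy(), trees["height_m"].to_numpy(), params)
    out = (
        trees.assign(_w=w)
        .groupby("plot_id", sort=True)
        .agg(agb=("_w", "sum"), n_trees=("_w", "size"))
        .reset_index()
    )
    return out


def species_share(trees: pd.DataFrame, params: AllometryParams = DEFAULT_PARAMS) -> pd.DataFrame:
    """Total biomass per species and its fraction of the grand total.

    Returns a frame (species, agb, fraction) sorted by biomass descending;
    fractions sum to 1.  Empty input yields an empty frame.
    """
    if trees.empty:
        return pd.DataFrame({"species": [], "agb": [], "fraction": []})
    w = tree_agb(trees["dbh_cm"].to_numpy(), trees["height_m"].to_numpy(), params)
    tot = trees.assign(_w=w).groupby("species")["_w"].sum().sort_values(ascending=False)
    return pd.DataFrame(
        {"species": tot.index, "agb": tot.to_numpy(), "fraction": tot.to_numpy() / tot.sum()}
    )
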