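"""Synthetic plot inventory and raster stack with known ground truth.

The study data this package targets — a continuous forest resource
inventory of 354 fixed plots plus co-registered Landsat-8 OLI reflectance
and Sentinel-1A VV/VH backscatter — are confidential.  This module
generates a stand-in with a fully known biomass-feature link so every
downstream stage (allometry, screening, model fits, mapping) is testable
and parameter recovery can be checked against truth.

Construction, per plot:

1. a latent above-ground biomass W is drawn from a truncated normal
   (opaque "biomass units per plot"; the source reports an implausible
   unit range, so no physical unit is claimed);
2. trees are generated (species from a fixed mix, height tied to DBH by a
   power law with lognormal noise) and rescaled so that their allometric
   biomass sum equals W exactly — the inventory and the latent truth are
   consistent by construction;
3. remote-sensing features are affine in a saturating transform
   v = (u + s*tanh(1.5 u)) / (1 + s) of the standardized biomass u, plus
   independent Gaussian noise.  With nonlinearity_strength s = 0 the
   biomass is affine in every noise-free feature; with s > 0 recovering
   biomass from the features requires inverting a saturating map, which
   linear models cannot do exactly — the qualitative nonlinearity the
   package's model comparison is designed to expose.  The blue band (B2)
   decreases with biomass, the NIR band (B5) increases, so NDVI-like
   ratios increase;
4. a configurable fraction of plots has its *recorded* biomass corrupted
   by a gross one-sided factor 10**U(1, 6) (decimal/unit-style data
   errors), which the screening module's iterative 3-sigma rule removes.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict

import numpy as np
import pandas as pd
from scipy import ndimage

from .allometry import DEFAULT_PARAMS, AllometryParams
from .mapping import DEFAULT_CRS, DEFAULT_NODATA, DEFAULT_TRANSFORM, RasterStack

__all__ = ["SimulationConfig", "SyntheticTruth", "generate_inventory", "generate_raster_stack"]

#: species mix loosely matching a temperate NE-China mixed forest: one
#: dominant oak around a quarter of the biomass, several 3-7% species,
#: and a long tail pooled as "Other".
DEFAULT_SPECIES_MIX = (
    ("Quercus mongolica", 0.24),
    ("Populus davidiana", 0.07),
    ("Quercus aliena", 0.06),
    ("Betula platyphylla", 0.06),
    ("Larix gmelinii", 0.05),
    ("Pinus sylvestris", 0.05),
    ("Ulmus pumila", 0.04),
    ("Fraxinus mandshurica", 0.04),
    ("Acer mono", 0.03),
    ("Tilia amurensis", 0.03),
    ("Other", 0.33),
)

# feature link: name -> (base level, coefficient on v, clip range)
_OPTICAL_LINK = {
    "B2": (0.080, -0.010, (0.001, 0.999)),
    "B3": (0.090, -0.008, (0.001, 0.999)),
    "B4": (0.100, -0.012, (0.001, 0.999)),
    "B5": (0.350, 0.050, (0.001, 0.999)),
    "B6": (0.180, -0.020, (0.001, 0.999)),
    "B7": (0.140, -0.015, (0.001, 0.999)),
}
_SAR_LINK = {
    "VV": (-12.0, 1.5, (-30.0, 0.0)),
    "VH": (-18.0, 2.0, (-30.0, 0.0)),
}


@dataclass
class SimulationConfig:
    """All knobs of the generator; outputs are pure functions of this."""

    n_plots: int = 354
    trees_per_plot: tuple[int, int] = (8, 25)
    species_mix: tuple = DEFAULT_SPECIES_MIX
    dbh_range_cm: tuple[float, float] = (5.0, 45.0)
    # height-DBH link: H = alpha * D**beta * lognormal(sigma)
    height_alpha: float = 1.3
    height_beta: float = 0.6
    height_sigma: float = 0.08
    altitude_range: tuple[float, float] = (200.0, 1200.0)
    slope_range: tuple[float, float] = (0.0, 35.0)
    canopy_range: tuple[float, float] = (0.20, 0.95)
    biomass_mean: float = 100.0
    biomass_sd: float = 25.0
    biomass_trunc: float = 2.2  # latent truncation, in SDs
    noise_scale: float = 0.15  # feature noise as a fraction of the link slope
    terrain_link: float = 0.6  # weight of v in altitude / canopy closure
    outlier_fraction: float = (354 - 162) / 354
    outlier_exponent_range: tuple[float, float] = (1.0, 6.0)
    nonlinearity_strength: float = 1.0
    allometry: AllometryParams = field(default_factory=AllometryParams)
    seed: int = 0

    def __post_init__(self) -> None:
        total = sum(p for _, p in self.species_mix)
        if abs(total - 1.0) > 1e-9:
            raise ValueError(f"species proportions must sum to 1, got {total}")
        if not (0.0 <= self.outlier_fraction < 0.6):
            raise ValueError("outlier_fraction must lie in [0, 0.6)")
        if self.nonlinearity_strength < 0:
            raise ValueError("nonlinearity_strength must be >= 0")
        for name in ("trees_per_plot", "dbh_range_cm", "altitude_range", "slope_range", "canopy_range"):
            lo, hi = getattr(self, name)
            if not hi > lo:
                raise ValueError(f"degenerate range {name}: ({lo}, {hi})")
        if self.biomass_sd <= 0 or self.biomass_trunc <= 0:
            raise ValueError("biomass_sd and biomass_trunc must be > 0")
        if self.n_plots < 3:
            raise ValueError("need at least 3 plots")


@dataclass
class SyntheticTruth:
    """Ground truth exported for parameter-recovery tests."""

    latent_biomass: np.ndarray  # per-plot W, before any corruption
    recorded_biomass: np.ndarray  # what the plot table reports
    outlier_flags: np.ndarray  # True where recorded biomass was corrupted
    u: np.ndarray  # standardized latent biomass
    v: np.ndarray  # saturating transform actually exposed to the features
    link: dict  # all link parameters, incl. nonlinearity strength
    spectra: pd.DataFrame  # noise-free-pixel values per plot (B2..B7, VV, VH)

    def biomass_to_v(self, w: np.ndarray) -> np.ndarray:
        """The exact latent->feature-scale link used by the generator."""
        s = self.link["nonlinearity_strength"]
        u = (np.asarray(w, dtype=float) - self.link["biomass_mean"]) / self.link["biomass_sd"]
        return (u + s * np.tanh(1.5 * u)) / (1.0 + s)

    def to_json(self) -> str:
        d = {
            "latent_biomass": self.latent_biomass.tolist(),
            "recorded_biomass": self.recorded_biomass.tolist(),
            "outlier_flags": self.outlier_flags.astype(int).tolist(),
            "link": self.link,
        }
        return json.dumps(d, indent=2)


def _truncated_normal(rng: np.random.Generator, n: int, trunc: float) -> np.ndarray:
    out = np.empty(n)
    filled = 0
    while filled < n:
        draw = rng.normal(size=2 * (n - filled) + 8)
        draw = draw[np.abs(draw) <= trunc]
        take = min(len(draw), n - filled)
        out[filled : filled + take] = draw[:take]
        filled += take
    return out


def _v_transform(u: np.ndarray, s: float) -> np.ndarray:
    return (u + s * np.tanh(1.5 * u)) / (1.0 + s)


def generate_inventory(
    config: SimulationConfig,
) -> tuple[pd.DataFrame, pd.DataFrame, SyntheticTruth]:
    """Generate (tree table, plot table, truth), reproducibly from the seed.

    The tree table has columns plot_id, species, dbh_cm, height_m; the plot
    table plot_id, lon, lat, altitude, slope, canopy_closure, agb, n_trees.
    The plot table's ``agb`` is the *recorded* biomass (corrupted on
    outlier plots); summing tree-level allometric biomass reproduces the
    latent truth exactly on every plot.
    """
    rng = np.random.default_rng(config.seed)
    n = config.n_plots
    p = config.allometry
    s = config.nonlinearity_strength

    w = config.biomass_mean + config.biomass_sd * _truncated_normal(rng, n, config.biomass_trunc)
    u = (w - config.biomass_mean) / config.biomass_sd
    v = _v_transform(u, s)
    v_unit = v / _v_transform(np.array([config.biomass_trunc]), s)[0]  # roughly [-1, 1]

    # terrain: altitude and canopy closure share the v signal, slope does not
    def terrain(range_, link_weight):
        lo, hi = range_
        mid, half = (lo + hi) / 2.0, (hi - lo) / 2.0
        mix = link_weight * v_unit + (1.0 - link_weight) * rng.uniform(-1, 1, n)
        return np.clip(mid + half * mix, lo, hi)

    altitude = terrain(config.altitude_range, config.terrain_link)
    canopy = terrain(config.canopy_range, config.terrain_link)
    slope = rng.uniform(*config.slope_range, n)

    # per-plot spectral samples: affine in v + noise, clipped to valid ranges
    spectra = {"plot_id": [f"P{i + 1:04d}" for i in range(n)]}
    for name, (base, coef, clip) in {**_OPTICAL_LINK, **_SAR_LINK}.items():
        vals = base + coef * v + config.noise_scale * abs(coef) * rng.normal(size=n)
        spectra[name] = np.clip(vals, *clip)
    spectra_df = pd.DataFrame(spectra)

    # trees: rescale DBH so allometric sums hit the latent biomass exactly.
    # With H = alpha * D**beta * exp(eps), tree biomass is
    # a * alpha**c * exp(c*eps) * D**(b + c*beta), so scaling all DBH by f
    # scales the plot sum by f**(b + c*beta).
    expo = p.b + p.c * config.height_beta
    tree_rows = []
    n_trees = rng.integers(config.trees_per_plot[0], config.trees_per_plot[1] + 1, n)
    names = [m[0] for m in config.species_mix]
    probs = np.array([m[1] for m in config.species_mix])
    for i in range(n):
        k = int(n_trees[i])
        d0 = rng.uniform(*config.dbh_range_cm, k)
        eps = rng.normal(0.0, config.height_sigma, k)
        w0 = p.a * config.height_alpha**p.c * np.exp(p.c * eps) * d0**expo
        f = (w[i] / w0.sum()) ** (1.0 / expo)
        d = f * d0
        h = config.height_alpha * d**config.height_beta * np.exp(eps)
        sp = rng.choice(names, size=k, p=probs)
        for j in range(k):
            tree_rows.append((f"P{i + 1:04d}", sp[j], d[j], h[j]))
    trees = pd.DataFrame(tree_rows, columns=["plot_id", "species", "dbh_cm", "height_m"])

    # corrupt the recorded biomass of the outlier plots (one-sided gross
    # factors, log-spread so iterative 3-sigma clipping peels them exactly)
    n_out = int(round(config.outlier_fraction * n))
    flags = np.zeros(n, dtype=bool)
    recorded = w.copy()
    if n_out:
        idx = rng.choice(n, size=n_out, replace=False)
        flags[idx] = True
        lo_e, hi_e = config.outlier_exponent_range
        recorded[idx] = w[idx] * 10.0 ** rng.uniform(lo_e, hi_e, n_out)

    plots = pd.DataFrame(
        {
            "plot_id": spectra_df["plot_id"],
            "lon": rng.uniform(119.5, 125.5, n),
            "lat": rng.uniform(38.7, 43.4, n),
            "altitude": altitude,
            "slope": slope,
            "canopy_closure": canopy,
            "agb": recorded,
            "n_trees": n_trees,
        }
    )
    link = {
        "biomass_mean": config.biomass_mean,
        "biomass_sd": config.biomass_sd,
        "nonlinearity_strength": s,
        "optical": {k: val[:2] for k, val in _OPTICAL_LINK.items()},
        "sar": {k: val[:2] for k, val in _SAR_LINK.items()},
        "terrain_link": config.terrain_link,
        "noise_scale": config.noise_scale,
    }
    truth = SyntheticTruth(
        latent_biomass=w,
        recorded_biomass=recorded,
        outlier_flags=flags,
        u=u,
        v=v,
        link=link,
        spectra=spectra_df,
    )
    return trees, plots, truth


def generate_raster_stack(
    config: SimulationConfig,
    grid_shape: tuple[int, int] = (64, 64),
    inventory=None,
    margin: int = 3,
) -> tuple[RasterStack, pd.DataFrame]:
    """Raster stack hosting every plot at a distinct interior pixel.

    Bands: B2..B7 (reflectance), VV/VH (dB), Altitude, Slope and
    "Canopy closure".  Backgrounds are smooth correlated fields within
    each band's plausible range; the pixel under each plot is stamped with
    the plot's exact sample values, so sampling the raster at plot pixels
    reproduces the plot/spectra tables bit-for-bit.

    ``inventory`` may be the (trees, plots, truth) triple from
    :func:`generate_inventory`; if omitted it is regenerated from the
    config (deterministic).  Returns ``(stack, plot_pixels)`` where
    plot_pixels maps plot_id -> (row, col).  ``margin`` keeps every plot
    far enough from the edge for a full texture window.
    """
    rows, cols = grid_shape
    interior = (rows - 2 * margin) * (cols - 2 * margin)
    if interior < config.n_plots:
        raise ValueError(
            f"grid {grid_shape} with margin {margin} has {interior} interior pixels "
            f"< {config.n_plots} plots"
        )
    if inventory is None:
        inventory = generate_inventory(config)
    _, plots, truth = inventory
    rng = np.random.default_rng(np.random.SeedSequence([config.seed, 7919]))

    flat = rng.choice(interior, size=config.n_plots, replace=False)
    r_idx = flat // (cols - 2 * margin) + margin
    c_idx = flat % (cols - 2 * margin) + margin

    def smooth_field(lo, hi):
        base = ndimage.gaussian_filter(rng.normal(size=grid_shape), sigma=3.0)
        span = base.max() - base.min()
        unit = (base - base.min()) / span if span > 0 else base * 0
        return lo + (hi - lo) * unit

    bands: dict[str, np.ndarray] = {}
    for name, (base, coef, clip) in _OPTICAL_LINK.items():
        amp = 3.0 * abs(coef)
        bands[name] = smooth_field(max(clip[0], base - amp), min(clip[1], base + amp))
    for name, (base, coef, clip) in _SAR_LINK.items():
        amp = 3.0 * abs(coef)
        bands[name] = smooth_field(max(clip[0], base - amp), min(clip[1], base + amp))
    bands["Altitude"] = smooth_field(*config.altitude_range)
    bands["Slope"] = smooth_field(*config.slope_range)
    bands["Canopy closure"] = smooth_field(*config.canopy_range)

    for i in range(config.n_plots):
        r, c = r_idx[i], c_idx[i]
        for name in _OPTICAL_LINK:
            bands[name][r, c] = truth.spectra[name].iloc[i]
        for name in _SAR_LINK:
            bands[name][r, c] = truth.spectra[name].iloc[i]
        bands["Altitude"][r, c] = plots["altitude"].iloc[i]
        bands["Slope"][r, c] = plots["slope"].iloc[i]
        bands["Canopy closure"][r, c] = plots["canopy_closure"].iloc[i]

    stack = RasterStack(
        bands=bands, transform=DEFAULT_TRANSFORM, crs=DEFAULT_CRS, nodata=DEFAULT_NODATA
    )
    plot_pixels = pd.DataFrame(
        {"plot_id": plots["plot_id"], "row": r_idx, "col": c_idx}
    )
    return stack, plot_pixels
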