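"""Candidate-predictor catalogue: bands, vegetation indices, GLCM textures.

Per plot the catalogue holds 86 named variables:

* 6 optical surface-reflectance bands B2..B7 (Landsat-8 OLI convention:
  BLUE=B2, GREEN=B3, RED=B4, NIR=B5, SWIR1=B6, SWIR2=B7);
* 7 vegetation indices (ARVI, DVI, EVI, NDPI, NDVI, RVI, SAVI);
* 48 optical texture measures — 8 Haralick statistics per band
  (Mean, Variance, Homogeneity, Contrast, Dissimilarity, Entropy,
  SecondMoment, Correlation);
* 2 SAR backscatter coefficients (VH, VV, dB);
* 20 SAR texture measures — 10 statistics per polarization (the optical
  eight with SecondMoment labelled ASM, plus MAX and Energy);
* 3 plot variables: Altitude, Slope, Canopy closure.

Texture statistics come from a grey-level co-occurrence matrix (GLCM)
computed on a quantized window around the plot pixel, symmetrized and
averaged over a set of pixel offsets.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = [
    "VegetationIndices",
    "vegetation_indices",
    "quantize",
    "glcm_from_window",
    "texture_measures",
    "assemble_catalogue",
    "catalogue_names",
    "OPTICAL_BANDS",
    "SAR_BANDS",
    "INDEX_NAMES",
    "OPTICAL_TEXTURES",
    "SAR_TEXTURES",
    "TERRAIN_NAMES",
    "DEFAULT_OFFSETS",
]

OPTICAL_BANDS = ["B2", "B3", "B4", "B5", "B6", "B7"]
SAR_BANDS = ["VH", "VV"]
INDEX_NAMES = ["ARVI", "DVI", "EVI", "NDPI", "NDVI", "RVI", "SAVI"]
#: Haralick statistics retained for optical bands (8 per band).
OPTICAL_TEXTURES = [
    "Mean",
    "Variance",
    "Homogeneity",
    "Contrast",
    "Dissimilarity",
    "Entropy",
    "SecondMoment",
    "Correlation",
]
#: SAR statistics (10 per polarization); ASM is the angular second moment,
#: i.e. the same quantity as the optical "SecondMoment".
SAR_TEXTURES = [
    "Mean",
    "Variance",
    "Homogeneity",
    "Contrast",
    "Dissimilarity",
    "Entropy",
    "Correlation",
    "ASM",
    "MAX",
    "Energy",
]
TERRAIN_NAMES = ["Altitude", "Slope", "Canopy closure"]

# band roles for the vegetation indices
BLUE, RED, NIR, SWIR = "B2", "B4", "B5", "B6"

#: default pixel offsets (row, col) averaged in the GLCM: E, S, SE, NE.
DEFAULT_OFFSETS = ((0, 1), (1, 0), (1, 1), (1, -1))


def catalogue_names() -> list[str]:
    """The 86 canonical catalogue variable names, in stable order."""
    names = list(OPTICAL_BANDS)
    names += INDEX_NAMES
    for b in OPTICAL_BANDS:
        names += [b + t for t in OPTICAL_TEXTURES]
    names += SAR_BANDS
    for b in SAR_BANDS:
        names += [b + t for t in SAR_TEXTURES]
    names += TERRAIN_NAMES
    return names


@dataclass
class VegetationIndices:
    ndvi: float
    savi: float
    dvi: float
    rvi: float
    arvi: float
    evi: float
    ndpi: float

    def as_dict(self) -> dict[str, float]:
        return {
            "ARVI": self.arvi,
            "DVI": self.dvi,
            "EVI": self.evi,
            "NDPI": self.ndpi,
            "NDVI": self.ndvi,
            "RVI": self.rvi,
            "SAVI": self.savi,
        }


def vegetation_indices(
    b2, b4, b5, b6, soil_l: float = 0.5, standard: bool = False
) -> VegetationIndices:
    """Seven vegetation indices from BLUE (B2), RED (B4), NIR (B5), SWIR1 (B6).

    With ``standard=False`` (default) EVI and ARVI follow the exact printed
    forms used by this package's source calibration: EVI carries a
    coefficient of 7 on the blue band and ARVI is
    (NIR - 2*RED - BLUE) / (NIR + 2*RED - BLUE).  ``standard=True`` switches
    to the conventional definitions (7.5 on blue; NIR - (2*RED - BLUE)).

    Zero denominators yield NaN entries rather than silent zeros.
    """
    blue = np.asarray(b2, dtype=float)
    red = np.asarray(b4, dtype=float)
    nir = np.asarray(b5, dtype=float)
    swir = np.asarray(b6, dtype=float)

    def safe_div(num, den):
        den = np.asarray(den, dtype=float)
        with np.errstate(divide="ignore", invalid="ignore"):
            out = np.where(den == 0, np.nan, num / np.where(den == 0, np.nan, den))
        return out

    ndvi = safe_div(nir - red, nir + red)
    savi = (1.0 + soil_l) * safe_div(nir - red, nir + red + soil_l)
    dvi = nir - red
    rvi = safe_div(nir, red)
    if standard:
        rb = 2.0 * red - blue
        arvi = safe_div(nir - rb, nir + rb)
        evi = 2.5 * safe_div(nir - red, nir + 6.0 * red - 7.5 * blue + 1.0)
    else:
        arvi = safe_div(nir - 2.0 * red - blue, nir + 2.0 * red - blue)
        evi = 2.5 * safe_div(nir - red, nir + 6.0 * red - 7.0 * blue + 1.0)
    mix = 0.74 * red + 0.26 * swir
    ndpi = safe_div(nir - mix, nir + mix)

    if np.isscalar(b2):
        return VegetationIndices(
            float(ndvi), float(savi), float(dvi), float(rvi), float(arvi), float(evi), float(ndpi)
        )
    return VegetationIndices(ndvi, savi, dvi, rvi, arvi, evi, ndpi)


def quantize(image: np.ndarray, levels: int) -> np.ndarray:
    """Linearly quantize a float image to integer grey levels 0..levels-1.

    A constant image maps to level 0 everywhere.
    """
    img = np.asarray(image, dtype=float)
    lo, hi = np.nanmin(img), np.nanmax(img)
    if hi == lo:
        return np.zeros(img.shape, dtype=np.intp)
    q = np.floor((img - lo) / (hi - lo) * levels).astype(np.intp)
    return np.clip(q, 0, levels - 1)


def glcm_from_window(
    window: np.ndarray, levels: int, offsets=DEFAULT_OFFSETS
) -> np.ndarray:
    """Normalized symmetric grey-level co-occurrence matrix of a window.

    ``window`` holds integer grey levels in [0, levels).  Pairs are counted
    for every offset, the count matrix is symmetrized (each pair counted in
    both directions) and the average over offsets is normalized to sum to 1.
    """
    win = np.asarray(window)
    if win.ndim != 2:
        raise ValueError("window must be 2-D")
    if win.min() < 0 or win.max() >= levels:
        raise ValueError("window values must lie in [0, levels)")
    acc = np.zeros((levels, levels), dtype=float)
    any_pairs = False
    for dr, dc in offsets:
        rows, cols = win.shape
        if abs(dr) >= rows or abs(dc) >= cols:
            raise ValueError(f"window {win.shape} too small for offset {(dr, dc)}")
        r0, r1 = max(0, -dr), rows - max(0, dr)
        c0, c1 = max(0, -dc), cols - max(0, dc)
        a = win[r0:r1, c0:c1].ravel()
        b = win[r0 + dr : r1 + dr, c0 + dc : c1 + dc].ravel()
        counts = np.zeros((levels, levels), dtype=float)
        np.add.at(counts, (a, b), 1.0)
        counts = counts + counts.T  # symmetrize
        if counts.sum() > 0:
            acc += counts / counts.sum()
            any_pairs = True
    if not any_pairs:
        raise ValueError("no co-occurring pairs for the given offsets")
    return acc / len(offsets)


def texture_measures(glcm: np.ndarray) -> dict[str, float]:
    """Haralick statistics of a normalized (symmetric) GLCM.

    Returns mean, variance, homogeneity, contrast, dissimilarity, entropy
    (natural log, 0*ln0 := 0), second moment (= ASM), correlation, max
    probability and energy (= sqrt(ASM)).  For a degenerate GLCM with zero
    marginal variance the correlation is reported as 1.0 (perfectly
    concentrated distribution).
    """
    p = np.asarray(glcm, dtype=float)
    n = p.shape[0]
    i = np.arange(n, dtype=float)[:, None]
    j = np.arange(n, dtype=float)[None, :]
    mean = float((i * p).sum())  # row marginal mean; equals column mean (symmetric)
    mu_j = float((j * p).sum())
    var = float(((i - mean) ** 2 * p).sum())
    var_j = float(((j - mu_j) ** 2 * p).sum())
    contrast = float(((i - j) ** 2 * p).sum())
    dissim = float((np.abs(i - j) * p).sum())
    homog = float((p / (1.0 + (i - j) ** 2)).sum())
    nz = p[p > 0]
    entropy = float(-(nz * np.log(nz)).sum())
    asm = float((p**2).sum())
    cov = float(((i - mean) * (j - mu_j) * p).sum())
    denom = math.sqrt(var * var_j)
    corr = cov / denom if denom > 0 else 1.0
    return {
        "Mean": mean,
        "Variance": var,
        "Homogeneity": homog,
        "Contrast": contrast,
        "Dissimilarity": dissim,
        "Entropy": entropy,
        "SecondMoment": asm,
        "Correlation": corr,
        "ASM": asm,
        "MAX": float(p.max()),
        "Energy": math.sqrt(asm),
    }


def _window(arr: np.ndarray, row: int, col: int, half: int) -> np.ndarray | None:
    r0, r1 = row - half, row + half + 1
    c0, c1 = col - half, col + half + 1
    if r0 < 0 or c0 < 0 or r1 > arr.shape[0] or c1 > arr.shape[1]:
        return None
    return arr[r0:r1, c0:c1]


def assemble_catalogue(
    plots: pd.DataFrame,
    stack,
    window_size: int = 7,
    levels: int = 32,
    offsets=DEFAULT_OFFSETS,
    soil_l: float = 0.5,
    standard_indices: bool = False,
) -> pd.DataFrame:
    """Build the 86-variable feature table for every plot.

    Parameters
    ----------
    plots : DataFrame
        One row per plot with columns ``plot_id``, ``row``, ``col`` (pixel
        coordinates into the stack), ``altitude``, ``slope``,
        ``canopy_closure``.
    stack : mapping of band name -> 2-D ndarray
        Must contain B2..B7, VH, VV on a common grid (a
        :class:`~forestagb.mapping.RasterStack` works directly).
    window_size : int
        Side of the square texture window centred on the plot pixel.
    levels : int
        Grey-level count for quantization (per whole band, min-max).

    Plots whose texture window falls off the grid are excluded; the return
    value's ``attrs["excluded"]`` lists their plot ids.
    """
    half = window_size // 2
    quant = {b: quantize(np.asarray(stack[b]), levels) for b in OPTICAL_BANDS + SAR_BANDS}
    rows_out: list[dict] = []
    excluded: list = []
    for rec in plots.itertuples(index=False):
        r, c = int(rec.row), int(rec.col)
        entry: dict = {"plot_id": rec.plot_id}
        ok = True
        for b in OPTICAL_BANDS + SAR_BANDS:
            entry[b] = float(np.asarray(stack[b])[r, c])
            win = _window(quant[b], r, c, half)
            if win is None:
                ok = False
                break
            tm = texture_measures(glcm_from_window(win, levels, offsets))
            names = OPTICAL_TEXTURES if b in OPTICAL_BANDS else SAR_TEXTURES
            for t in names:
                entry[b + t] = tm[t]
        if not ok:
            excluded.append(rec.plot_id)
            continue
        vi = vegetation_indices(
            entry["B2"], entry["B4"], entry["B5"], entry["B6"], soil_l, standard_indices
        )
        entry.update(vi.as_dict())
        entry["Altitude"] = float(rec.altitude)
        entry["Slope"] = float(rec.slope)
        entry["Canopy closure"] = float(rec.canopy_closure)
        rows_out.append(entry)
    cols = ["plot_id"] + catalogue_names()
    out = pd.DataFrame(rows_out, columns=cols)
    out.attrs["excluded"] = excluded
    out.attrs["window_size"] = window_size
    out.attrs["levels"] = levels
    return out
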