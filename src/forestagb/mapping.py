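"""Raster containers, TIFF I/O and pixelwise biomass inversion.

A :class:`RasterStack` is a set of named, co-registered 2-D float bands
with a GDAL-style affine geotransform, a CRS identifier and a nodata
sentinel.  Stacks are written as multi-band TIFF via ``tifffile``; the
georeferencing travels in a JSON sidecar (``<path>.aux.json``) so the
contract is explicit and text-based.  The package expects analysis-ready,
pre-aligned stacks — resolution harmonization between sensors is the
caller's responsibility.

:func:`invert_raster` applies any fitted model (published linear
regression, stepwise refit, LM- or PSO-trained network) to every pixel:
derived features (vegetation indices, GLCM textures) are computed from
the stack with the same window/levels used at training time, pixels with
any missing input are propagated as nodata, and predictions are written
as-is (negative estimates are counted, never clipped).
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import tifffile

from .features import (
    DEFAULT_OFFSETS,
    INDEX_NAMES,
    OPTICAL_BANDS,
    SAR_BANDS,
    glcm_from_window,
    quantize,
    texture_measures,
    vegetation_indices,
)

__all__ = ["RasterStack", "RasterGrid", "write_stack", "read_stack", "compute_feature_rasters", "invert_raster"]

DEFAULT_TRANSFORM = (500000.0, 30.0, 0.0, 4600000.0, 0.0, -30.0)
DEFAULT_CRS = "EPSG:32651"
DEFAULT_NODATA = -9999.0


@dataclass
class RasterStack:
    """Named co-registered bands + georeferencing."""

    bands: dict[str, np.ndarray]
    transform: tuple = DEFAULT_TRANSFORM
    crs: str = DEFAULT_CRS
    nodata: float = DEFAULT_NODATA

    def __post_init__(self) -> None:
        shapes = {b.shape for b in self.bands.values()}
        if len(shapes) > 1:
            raise ValueError(f"bands have mismatched shapes: {shapes}")

    @property
    def shape(self) -> tuple[int, int]:
        return next(iter(self.bands.values())).shape

    def __getitem__(self, name: str) -> np.ndarray:
        return self.bands[name]

    def __contains__(self, name: str) -> bool:
        return name in self.bands


@dataclass
class RasterGrid:
    """Single-band output raster (a biomass surface)."""

    values: np.ndarray
    transform: tuple = DEFAULT_TRANSFORM
    crs: str = DEFAULT_CRS
    nodata: float = DEFAULT_NODATA
    metadata: dict = field(default_factory=dict)


def write_stack(stack: RasterStack, path, metadata: dict | None = None) -> None:
    """Write a multi-band float32 TIFF plus a ``.aux.json`` sidecar."""
    path = Path(path)
    names = list(stack.bands)
    arr = np.stack([stack.bands[n].astype(np.float32) for n in names])
    tifffile.imwrite(path, arr)
    aux = {
        "bands": names,
        "transform": list(stack.transform),
        "crs": stack.crs,
        "nodata": stack.nodata,
    }
    if metadata:
        aux["metadata"] = metadata
    Path(str(path) + ".aux.json").write_text(json.dumps(aux, indent=2))


def read_stack(path) -> RasterStack:
    """Read a stack written by :func:`write_stack`."""
    path = Path(path)
    aux = json.loads(Path(str(path) + ".aux.json").read_text())
    arr = tifffile.imread(path)
    if arr.ndim == 2:
        arr = arr[None]
    bands = {n: arr[i].astype(float) for i, n in enumerate(aux["bands"])}
    return RasterStack(
        bands=bands,
        transform=tuple(aux["transform"]),
        crs=aux["crs"],
        nodata=float(aux["nodata"]),
    )


def write_grid(grid: RasterGrid, path) -> None:
    stack = RasterStack(
        bands={"agb": grid.values}, transform=grid.transform, crs=grid.crs, nodata=grid.nodata
    )
    write_stack(stack, path, metadata=grid.metadata)


def _masked_band(stack: RasterStack, name: str) -> np.ndarray:
    if name not in stack:
        raise KeyError(f"stack is missing required band {name!r}")
    a = stack[name].astype(float).copy()
    a[a == stack.nodata] = np.nan
    return a


def _texture_raster(
    band: np.ndarray, measures: list[str], window_size: int, levels: int, offsets
) -> dict[str, np.ndarray]:
    """Sliding-window Haralick measures; NaN where the window is incomplete
    or touches a missing pixel."""
    half = window_size // 2
    rows, cols = band.shape
    finite = np.isfinite(band)
    q = quantize(np.where(finite, band, np.nanmin(band)), levels)
    out = {m: np.full(band.shape, np.nan) for m in measures}
    for r in range(half, rows - half):
        for c in range(half, cols - half):
            fwin = finite[r - half : r + half + 1, c - half : c + half + 1]
            if not fwin.all():
                continue
            win = q[r - half : r + half + 1, c - half : c + half + 1]
            tm = texture_measures(glcm_from_window(win, levels, offsets))
            for m in measures:
                out[m][r, c] = tm[m]
    return out


def compute_feature_rasters(
    stack: RasterStack,
    feature_names: list[str],
    window_size: int = 7,
    levels: int = 32,
    offsets=DEFAULT_OFFSETS,
    soil_l: float = 0.5,
    standard_indices: bool = False,
) -> dict[str, np.ndarray]:
    """Per-pixel rasters for each requested catalogue feature.

    Direct bands are masked copies; vegetation indices are computed from
    the optical bands; texture features (e.g. ``B6Mean``, ``VVEntropy``)
    are sliding-window Haralick measures with the given window/levels.
    """
    out: dict[str, np.ndarray] = {}
    texture_requests: dict[str, list[str]] = {}
    need_indices = [f for f in feature_names if f in INDEX_NAMES]
    for f in feature_names:
        if f in stack:
            out[f] = _masked_band(stack, f)
        elif f in INDEX_NAMES:
            pass
        else:
            for b in OPTICAL_BANDS + SAR_BANDS:
                if f.startswith(b) and len(f) > len(b):
                    texture_requests.setdefault(b, []).append(f[len(b) :])
                    break
            else:
                raise KeyError(f"cannot derive feature {f!r} from the stack")
    if need_indices:
        vi = vegetation_indices(
            _masked_band(stack, "B2"),
            _masked_band(stack, "B4"),
            _masked_band(stack, "B5"),
            _masked_band(stack, "B6"),
            soil_l,
            standard_indices,
        ).as_dict()
        for f in need_indices:
            out[f] = vi[f]
    for band_name, measures in texture_requests.items():
        rasters = _texture_raster(
            _masked_band(stack, band_name), measures, window_size, levels, offsets
        )
        for m in measures:
            out[band_name + m] = rasters[m]
    return out


def invert_raster(
    model,
    stack: RasterStack,
    window_size: int = 7,
    levels: int = 32,
    offsets=DEFAULT_OFFSETS,
    batch_size: int = 4096,
) -> RasterGrid:
    """Apply a fitted model pixelwise to produce a biomass surface.

    ``model`` must expose ``required_features`` (catalogue names) and
    ``predict(DataFrame) -> array``.  Pixels with any missing feature
    (nodata input or incomplete texture window) are nodata in the output.
    Batched prediction is bitwise identical to whole-grid prediction.
    """
    feats = model.required_features
    if not feats:
        raise ValueError("model does not declare its required features")
    rasters = compute_feature_rasters(stack, list(feats), window_size, levels, offsets)
    mat = np.stack([rasters[f].ravel() for f in feats], axis=1)
    valid = np.isfinite(mat).all(axis=1)
    preds = np.full(mat.shape[0], np.nan)
    idx = np.flatnonzero(valid)
    for start in range(0, len(idx), batch_size):
        chunk = idx[start : start + batch_size]
        df = pd.DataFrame(mat[chunk], columns=list(feats))
        preds[chunk] = np.asarray(model.predict(df), dtype=float)
    out = np.where(np.isfinite(preds), preds, DEFAULT_NODATA if stack.nodata is None else stack.nodata)
    n_neg = int((preds[np.isfinite(preds)] < 0).sum())
    return RasterGrid(
        values=out.reshape(stack.shape),
        transform=stack.transform,
        crs=stack.crs,
        nodata=stack.nodata,
        metadata={
            "window_size": window_size,
            "levels": levels,
            "n_valid": int(valid.sum()),
            "n_negative_predictions": n_neg,
        },
    )
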