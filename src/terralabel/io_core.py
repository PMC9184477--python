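"""Raster containers, grid geometry, resampling, and scene I/O.

Conventions used throughout the package: rasters are row-major with the map
origin at the top-left corner, pixel coordinates are 0-based, extents are
half-open, and a pixel's value is located at its center.  Map coordinates are
planar with east = +x and north = +y, so row index increases southward.
Rasters are written as single-band TIFF files; the grid geometry and scene
metadata live in a JSON sidecar.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, replace
from pathlib import Path

import numpy as np
import tifffile

#: Sentinel-2 L1C band inventory at native resolution (meters per pixel).
BAND_RESOLUTION = {
    "B1": 60.0, "B2": 10.0, "B3": 10.0, "B4": 10.0,
    "B5": 20.0, "B6": 20.0, "B7": 20.0, "B8": 10.0,
    "B8A": 20.0, "B9": 60.0, "B10": 60.0, "B11": 20.0, "B12": 20.0,
}
ALL_BANDS = tuple(BAND_RESOLUTION)

#: Bands fed to the labeling model, in fixed order (B1, B8A, B9, B10 dropped).
MODEL_BANDS = ("B2", "B3", "B4", "B5", "B6", "B7", "B8", "B11", "B12")

#: Product class names, in probability-band order; ``label`` = argmax index.
CLASS_NAMES = (
    "water", "trees", "grass", "flooded_vegetation", "crops",
    "shrub_and_scrub", "built", "bare", "snow_and_ice",
)
N_CLASSES = len(CLASS_NAMES)
#: Annotation taxonomy = the 9 land-cover classes plus cloud (class 9).
CLOUD_CLASS = 9
N_ANNOTATION_CLASSES = 10


class LoadError(RuntimeError):
    """A scene or raster could not be loaded (missing band, bad metadata...)."""


class GeometryError(ValueError):
    """Grids are misaligned or a resampling factor is not an integer."""


@dataclass
class RasterGrid:
    """A single-band raster on a planar grid.

    Parameters
    ----------
    values
        2-D array, numeric or integer-categorical.
    pixel_size
        Meters per pixel (square pixels).
    origin
        Map coordinates ``(x, y)`` of the top-left corner of the grid.
    nodata
        Optional boolean mask, ``True`` where the pixel is invalid.
    categories
        For categorical grids, the explicit set of legal values.
    """

    values: np.ndarray
    pixel_size: float
    origin: tuple[float, float] = (0.0, 0.0)
    nodata: np.ndarray | None = None
    categories: frozenset[int] | None = None

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values)
        if self.values.ndim != 2 or min(self.values.shape) < 1:
            raise GeometryError("raster values must be a non-empty 2-D array")
        if not self.pixel_size > 0:
            raise GeometryError("pixel_size must be positive")
        if self.nodata is not None:
            self.nodata = np.asarray(self.nodata, dtype=bool)
            if self.nodata.shape != self.values.shape:
                raise GeometryError("nodata mask shape mismatch")
        if self.categories is not None:
            self.categories = frozenset(int(c) for c in self.categories)
            valid = self.values if self.nodata is None else self.values[~self.nodata]
            present = set(np.unique(valid).tolist())
            if not present <= self.categories:
                raise GeometryError(
                    f"categorical grid contains illegal values {sorted(present - self.categories)}"
                )

    @property
    def shape(self) -> tuple[int, int]:
        return self.values.shape

    @property
    def extent(self) -> tuple[float, float, float, float]:
        """(xmin, ymin, xmax, ymax) of the half-open grid footprint."""
        rows, cols = self.shape
        x0, y0 = self.origin
        return (x0, y0 - rows * self.pixel_size, x0 + cols * self.pixel_size, y0)

    def pixel_center(self, row: int, col: int) -> tuple[float, float]:
        x0, y0 = self.origin
        return (x0 + (col + 0.5) * self.pixel_size, y0 - (row + 0.5) * self.pixel_size)

    def copy(self) -> "RasterGrid":
        return replace(
            self,
            values=self.values.copy(),
            nodata=None if self.nodata is None else self.nodata.copy(),
        )

    def same_extent(self, other: "RasterGrid", tol: float = 1e-6) -> bool:
        return all(abs(a - b) <= tol for a, b in zip(self.extent, other.extent))


@dataclass
class Scene:
    """A multi-resolution reflectance stack plus cloud probability and metadata."""

    bands: dict[str, RasterGrid]
    s2c: RasterGrid
    solar_azimuth_deg: float
    cloudy_pixel_percentage: float
    timestamp: str
    tile_id: str

    def __post_init__(self) -> None:
        for name in ALL_BANDS:
            if name not in self.bands:
                raise LoadError(f"scene is missing mandatory band {name}")
        ref = self.bands["B2"]
        for name, grid in self.bands.items():
            if not grid.same_extent(ref):
                raise LoadError(f"band {name} extent differs from B2")
            if np.any(grid.values < 0):
                raise LoadError(f"band {name} contains negative reflectance")
        if not self.s2c.same_extent(ref):
            raise LoadError("s2c extent differs from B2")
        s2c = self.s2c.values
        if np.any((s2c < 0) | (s2c > 1)):
            raise LoadError("s2c values outside [0, 1]")
        if not (0.0 <= self.solar_azimuth_deg < 360.0):
            raise LoadError("solar_azimuth_deg outside [0, 360)")
        if not (0.0 <= self.cloudy_pixel_percentage <= 100.0):
            raise LoadError("cloudy_pixel_percentage outside [0, 100]")


def _integer_factor(a: float, b: float) -> int:
    """Integer ratio a / b, or raise GeometryError."""
    f = a / b
    if abs(f - round(f)) > 1e-9 or round(f) < 1:
        raise GeometryError(f"{a} is not an integer multiple of {b}")
    return int(round(f))


def _sample_coords(n_out: int, out_ps: float, in_ps: float) -> np.ndarray:
    """Fractional input-pixel indices of the output pixel centers (1-D axis)."""
    centers = (np.arange(n_out) + 0.5) * out_ps
    return centers / in_ps - 0.5


def resample_bilinear(grid: RasterGrid, target_pixel_size: float) -> RasterGrid:
    """Resample a numeric grid to ``target_pixel_size`` by bilinear interpolation.

    The output covers the same extent; each output center interpolates the four
    nearest input centers (edge centers are clamped).  Nodata propagation is
    strict: an output pixel is nodata if any input pixel in its 2x2 stencil is.
    """
    if target_pixel_size == grid.pixel_size:
        return grid.copy()
    if target_pixel_size < grid.pixel_size:
        f = _integer_factor(grid.pixel_size, target_pixel_size)
        out_shape = (grid.shape[0] * f, grid.shape[1] * f)
    else:
        f = _integer_factor(target_pixel_size, grid.pixel_size)
        if grid.shape[0] % f or grid.shape[1] % f:
            raise GeometryError("grid shape not divisible by coarsening factor")
        out_shape = (grid.shape[0] // f, grid.shape[1] // f)

    rows = _sample_coords(out_shape[0], target_pixel_size, grid.pixel_size)
    cols = _sample_coords(out_shape[1], target_pixel_size, grid.pixel_size)
    nr, nc = grid.shape
    r0 = np.clip(np.floor(rows).astype(int), 0, nr - 1)
    c0 = np.clip(np.floor(cols).astype(int), 0, nc - 1)
    r1 = np.minimum(r0 + 1, nr - 1)
    c1 = np.minimum(c0 + 1, nc - 1)
    wr = np.clip(rows - r0, 0.0, 1.0)[:, None]
    wc = np.clip(cols - c0, 0.0, 1.0)[None, :]

    v = np.asarray(grid.values, dtype=float)
    out = (
        v[np.ix_(r0, c0)] * (1 - wr) * (1 - wc)
        + v[np.ix_(r0, c1)] * (1 - wr) * wc
        + v[np.ix_(r1, c0)] * wr * (1 - wc)
        + v[np.ix_(r1, c1)] * wr * wc
    )
    nodata = None
    if grid.nodata is not None:
        nd = grid.nodata
        nodata = (
            nd[np.ix_(r0, c0)] | nd[np.ix_(r0, c1)]
            | nd[np.ix_(r1, c0)] | nd[np.ix_(r1, c1)]
        )
    return RasterGrid(out, target_pixel_size, grid.origin, nodata)


def resample_nearest(grid: RasterGrid, target_pixel_size: float) -> RasterGrid:
    """Resample any grid so each output pixel takes the value of the input
    pixel containing its center."""
    if target_pixel_size == grid.pixel_size:
        return grid.copy()
    if target_pixel_size < grid.pixel_size:
        f = _integer_factor(grid.pixel_size, target_pixel_size)
        out_shape = (grid.shape[0] * f, grid.shape[1] * f)
    else:
        f = _integer_factor(target_pixel_size, grid.pixel_size)
        if grid.shape[0] % f or grid.shape[1] % f:
            raise GeometryError("grid shape not divisible by coarsening factor")
        out_shape = (grid.shape[0] // f, grid.shape[1] // f)
    nr, nc = grid.shape
    rows = np.clip(
        np.floor((np.arange(out_shape[0]) + 0.5) * target_pixel_size / grid.pixel_size).astype(int),
        0, nr - 1,
    )
    cols = np.clip(
        np.floor((np.arange(out_shape[1]) + 0.5) * target_pixel_size / grid.pixel_size).astype(int),
        0, nc - 1,
    )
    out = grid.values[np.ix_(rows, cols)]
    nodata = None if grid.nodata is None else grid.nodata[np.ix_(rows, cols)]
    return RasterGrid(out, target_pixel_size, grid.origin, nodata, grid.categories)


def coarsen_any(mask: RasterGrid, target_pixel_size: float) -> RasterGrid:
    """Coarsen a boolean mask; an output cell is True iff ANY covered source
    cell is True (conservative over-masking)."""
    if mask.values.dtype != bool:
        raise GeometryError("coarsen_any requires a boolean grid")
    f = _integer_factor(target_pixel_size, mask.pixel_size)
    nr, nc = mask.shape
    if nr % f or nc % f:
        raise GeometryError("mask shape not divisible by coarsening factor")
    blocks = mask.values.reshape(nr // f, f, nc // f, f)
    return RasterGrid(blocks.any(axis=(1, 3)), target_pixel_size, mask.origin)


def block_mean(values: np.ndarray, factor: int) -> np.ndarray:
    """Mean over non-overlapping factor x factor blocks."""
    nr, nc = values.shape
    if nr % factor or nc % factor:
        raise GeometryError("shape not divisible by block factor")
    return values.reshape(nr // factor, factor, nc // factor, factor).mean(axis=(1, 3))


# ---------------------------------------------------------------------------
# Scene and grid I/O: one TIFF per band + metadata.json sidecar.

def write_grid(path: Path | str, grid: RasterGrid) -> None:
    path = Path(path)
    tifffile.imwrite(path, np.asarray(grid.values), tile=(256, 256))
    sidecar = {
        "pixel_size": grid.pixel_size,
        "origin": list(grid.origin),
        "categories": sorted(grid.categories) if grid.categories is not None else None,
    }
    path.with_suffix(".json").write_text(json.dumps(sidecar))
    if grid.nodata is not None:
        tifffile.imwrite(path.with_name(path.stem + "_nodata.tif"),
                         grid.nodata.astype(np.uint8), tile=(256, 256))


def read_grid(path: Path | str) -> RasterGrid:
    path = Path(path)
    if not path.exists():
        raise LoadError(f"raster not found: {path}")
    values = tifffile.imread(path)
    meta = json.loads(path.with_suffix(".json").read_text())
    nodata_path = path.with_name(path.stem + "_nodata.tif")
    nodata = tifffile.imread(nodata_path).astype(bool) if nodata_path.exists() else None
    cats = meta.get("categories")
    return RasterGrid(values, meta["pixel_size"], tuple(meta["origin"]), nodata,
                      frozenset(cats) if cats is not None else None)


def write_scene(path: Path | str, scene: Scene) -> None:
    path = Path(path)
    path.mkdir(parents=True, exist_ok=True)
    for name, grid in scene.bands.items():
        write_grid(path / f"{name}.tif", grid)
    write_grid(path / "S2C.tif", scene.s2c)
    meta = {
        "solar_azimuth_deg": scene.solar_azimuth_deg,
        "cloudy_pixel_percentage": scene.cloudy_pixel_percentage,
        "timestamp": scene.timestamp,
        "tile_id": scene.tile_id,
    }
    (path / "metadata.json").write_text(json.dumps(meta, indent=1))


def read_scene(path: Path | str) -> Scene:
    """Load a scene directory (one TIFF per band + metadata.json)."""
    path = Path(path)
    meta_path = path / "metadata.json"
    if not meta_path.exists():
        raise LoadError(f"metadata.json not found under {path}")
    try:
        meta = json.loads(meta_path.read_text())
    except json.JSONDecodeError as exc:
        raise LoadError(f"unreadable metadata: {exc}") from exc
    bands = {}
    for name in ALL_BANDS:
        band_path = path / f"{name}.tif"
        if not band_path.exists():
            raise LoadError(f"scene is missing mandatory band {name}")
        bands[name] = read_grid(band_path)
    s2c = read_grid(path / "S2C.tif")
    for key in ("solar_azimuth_deg", "cloudy_pixel_percentage", "timestamp", "tile_id"):
        if key not in meta:
            raise LoadError(f"metadata field missing: {key}")
    return Scene(bands=bands, s2c=s2c, **{k: meta[k] for k in (
        "solar_azimuth_deg", "cloudy_pixel_percentage", "timestamp", "tile_id")})
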