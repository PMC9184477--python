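"""Reflectance normalization: log transform, then remap empirical percentiles
onto a sigmoid.

Top-of-atmosphere reflectance is heavily compressed toward the dark end of
the sensor range, with a long bright tail (snow, bare ground, specular
water).  The normalization first log-transforms reflectance to equalize that
tail, then maps fitted per-band percentiles of the log values onto fixed
sigmoid arguments by monotone piecewise-linear interpolation (linearly
extrapolated beyond the end breakpoints), and finally applies the logistic
function.  The result is bounded on (0, 1) without truncation and strictly
monotone in the input.

Stats are fitted once on a training corpus and serialized; inference loads
them and never refits per scene, matching a single global model.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
from scipy.special import expit

from .io_core import MODEL_BANDS, RasterGrid, Scene

DEFAULT_PERCENTILES = (1.0, 5.0, 50.0, 95.0, 99.0)
DEFAULT_ANCHORS = (-3.0, -1.5, 0.0, 1.5, 3.0)
DEFAULT_LOG_FLOOR = 1e-4


class FitError(RuntimeError):
    pass


@dataclass
class BandStats:
    breakpoints: np.ndarray   # strictly increasing log-reflectance values
    anchors: np.ndarray       # strictly increasing sigmoid arguments

    def __post_init__(self) -> None:
        self.breakpoints = np.asarray(self.breakpoints, dtype=float)
        self.anchors = np.asarray(self.anchors, dtype=float)
        if self.breakpoints.size != self.anchors.size or self.breakpoints.size < 2:
            raise FitError("breakpoints and anchors must have equal length >= 2")
        if np.any(np.diff(self.breakpoints) <= 0):
            raise FitError("breakpoints must be strictly increasing")
        if np.any(np.diff(self.anchors) <= 0):
            raise FitError("anchors must be strictly increasing")


@dataclass
class NormStats:
    bands: dict[str, BandStats]
    fit_percentiles: tuple[float, ...] = DEFAULT_PERCENTILES
    log_floor: float = DEFAULT_LOG_FLOOR

    def to_json(self) -> str:
        return json.dumps({
            "fit_percentiles": list(self.fit_percentiles),
            "log_floor": self.log_floor,
            "bands": {
                name: {"breakpoints": bs.breakpoints.tolist(),
                       "anchors": bs.anchors.tolist()}
                for name, bs in self.bands.items()
            },
        }, indent=1)

    @classmethod
    def from_json(cls, text: str) -> "NormStats":
        doc = json.loads(text)
        return cls(
            bands={name: BandStats(np.array(b["breakpoints"]), np.array(b["anchors"]))
                   for name, b in doc["bands"].items()},
            fit_percentiles=tuple(doc["fit_percentiles"]),
            log_floor=float(doc["log_floor"]),
        )

    def save(self, path: Path | str) -> None:
        Path(path).write_text(self.to_json())

    @classmethod
    def load(cls, path: Path | str) -> "NormStats":
        return cls.from_json(Path(path).read_text())


def fit_norm_stats(scenes: Iterable[Scene],
                   percentiles: Sequence[float] = DEFAULT_PERCENTILES,
                   anchors: Sequence[float] = DEFAULT_ANCHORS,
                   log_floor: float = DEFAULT_LOG_FLOOR,
                   band_names: Sequence[str] = MODEL_BANDS,
                   masks: Sequence[np.ndarray] | None = None) -> NormStats:
    """Fit per-band breakpoints from the pooled unmasked pixels of a corpus.

    ``masks`` (optional, one boolean array per scene at each band's native
    grid resampled by the caller) marks pixels to EXCLUDE.  Breakpoints are
    the empirical percentiles of log(max(x, log_floor)).
    """
    percentiles = tuple(float(p) for p in percentiles)
    anchors_arr = np.asarray(anchors, dtype=float)
    if len(percentiles) != anchors_arr.size:
        raise FitError("percentiles and anchors must have equal length")
    if np.any(np.diff(percentiles) <= 0) or not all(0 < p < 100 for p in percentiles):
        raise FitError("percentiles must be strictly increasing within (0, 100)")
    if np.any(np.diff(anchors_arr) <= 0):
        raise FitError("anchors must be strictly increasing")

    scenes = list(scenes)
    if not scenes:
        raise FitError("need at least one scene")
    stats: dict[str, BandStats] = {}
    for name in band_names:
        pooled = []
        for i, scene in enumerate(scenes):
            vals = np.asarray(scene.bands[name].values, dtype=float).ravel()
            if masks is not None and masks[i] is not None:
                m = np.asarray(masks[i], dtype=bool)
                if m.shape == scene.bands[name].shape:
                    vals = vals[~m.ravel()]
            pooled.append(vals)
        x = np.concatenate(pooled)
        if np.unique(x).size < 2:
            raise FitError(f"band {name} has fewer than 2 distinct values")
        y = np.log(np.maximum(x, log_floor))
        bp = np.percentile(y, percentiles)
        if np.any(np.diff(bp) <= 0):
            raise FitError(f"band {name}: fitted breakpoints are not strictly increasing")
        stats[name] = BandStats(bp, anchors_arr.copy())
    return NormStats(bands=stats, fit_percentiles=percentiles, log_floor=log_floor)


def _piecewise_linear(y: np.ndarray, bp: np.ndarray, anchors: np.ndarray) -> np.ndarray:
    """Monotone interpolation through (bp_i, anchor_i), extrapolated with the
    terminal segment slopes beyond the end breakpoints."""
    g = np.interp(y, bp, anchors)
    s_lo = (anchors[1] - anchors[0]) / (bp[1] - bp[0])
    s_hi = (anchors[-1] - anchors[-2]) / (bp[-1] - bp[-2])
    lo = y < bp[0]
    hi = y > bp[-1]
    g = np.where(lo, anchors[0] + (y - bp[0]) * s_lo, g)
    g = np.where(hi, anchors[-1] + (y - bp[-1]) * s_hi, g)
    return g


def normalize_array(x: np.ndarray, band: str, stats: NormStats) -> np.ndarray:
    """Normalize raw reflectance values for ``band`` into (0, 1)."""
    if band not in stats.bands:
        raise FitError(f"band {band} has no fitted stats")
    bs = stats.bands[band]
    y = np.log(np.maximum(np.asarray(x, dtype=float), stats.log_floor))
    return expit(_piecewise_linear(y, bs.breakpoints, bs.anchors))


def normalize(grid: RasterGrid, band: str, stats: NormStats) -> RasterGrid:
    """Normalize a raster grid; nodata is carried through unchanged."""
    out = normalize_array(grid.values, band, stats)
    return RasterGrid(out.astype(np.float32), grid.pixel_size, grid.origin,
                      None if grid.nodata is None else grid.nodata.copy())
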