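"""Cloud and cloud-shadow masking.

Three-step cloud mask: (1) threshold the scene's cloud-probability layer at
65%, (2) require a parallax signal — the Cloud Displacement Index computed
from near-infrared band ratios — so bright ground targets flagged by step (1)
are cleared, (3) add (or intersect, configurable) a cirrus-band threshold,
then take a morphological opening.  The cloud mask is computed at 20 m.
Shadows are handled geometrically: the cloud mask is extended 5 km in the
direction opposite the solar azimuth (a directional distance transform), and
the combined mask is finalized at 100 m with a conservative any-rule.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
from scipy import ndimage

from .io_core import (RasterGrid, Scene, coarsen_any,
                      resample_bilinear, resample_nearest)


class MaskingError(RuntimeError):
    pass


QA_ALGORITHM_VERSION = "terralabel-qa-0.1.0"


@dataclass
class MaskingConfig:
    s2c_threshold: float = 0.65       # cloud probability
    cdi_threshold: float = -0.5       # unitless, strict <
    cdi_window: int = 7               # odd pixel count
    cirrus_threshold: float = 0.01    # B10 reflectance
    cirrus_mode: str = "union"        # or "intersection"
    opening_radius: int = 1           # pixels (disk; radius 1 = 3x3 cross)
    shadow_distance_m: float = 5000.0
    compute_pixel_size: float = 20.0
    final_pixel_size: float = 100.0

    def __post_init__(self) -> None:
        if not (0.0 <= self.s2c_threshold <= 1.0):
            raise MaskingError("s2c_threshold outside [0, 1]")
        if not (-1.0 <= self.cdi_threshold <= 1.0):
            raise MaskingError("cdi_threshold outside [-1, 1]")
        if self.cdi_window < 1 or self.cdi_window % 2 == 0:
            raise MaskingError("cdi_window must be odd and >= 1")
        if self.cirrus_mode not in ("union", "intersection"):
            raise MaskingError("cirrus_mode must be 'union' or 'intersection'")
        if self.shadow_distance_m <= 0:
            raise MaskingError("shadow_distance_m must be positive")
        f = self.final_pixel_size / self.compute_pixel_size
        if abs(f - round(f)) > 1e-9:
            raise MaskingError("final_pixel_size must be an integer multiple of compute_pixel_size")


@dataclass
class FinalMask:
    """Cloud/shadow masks at compute resolution plus the combined 100 m mask.

    True means "exclude this pixel".
    """

    cloud: RasterGrid
    shadow: RasterGrid
    combined_final: RasterGrid
    config: MaskingConfig
    qa_algorithm_version: str = QA_ALGORITHM_VERSION


def _window_variance(x: np.ndarray, window: int) -> np.ndarray:
    """Population variance over a window x window neighbourhood (reflect edges)."""
    mean = ndimage.uniform_filter(x, size=window, mode="reflect")
    mean_sq = ndimage.uniform_filter(x * x, size=window, mode="reflect")
    return np.clip(mean_sq - mean * mean, 0.0, None)


def compute_cdi(b7: RasterGrid, b8: RasterGrid, b8a: RasterGrid,
                window: int = 7) -> RasterGrid:
    """Cloud Displacement Index over co-registered 20 m grids.

    With ratio fields r1 = B7/B8A and r2 = B8/B8A and V the windowed local
    variance, CDI = (V(r2) - V(r1)) / (V(r2) + V(r1)), defined as 0 where both
    variances vanish.  Elevated clouds introduce parallax variance between the
    near-infrared ratios that is absent over flat bright ground, driving CDI
    toward -1 over clouds while bright buildings stay near 0; clouds are
    flagged where CDI falls below a (negative) threshold.  Pixels with
    B8A = 0 are marked invalid rather than infinite.
    """
    for name, g in (("B7", b7), ("B8", b8), ("B8A", b8a)):
        if g.shape != b8a.shape or g.pixel_size != b8a.pixel_size:
            raise MaskingError(f"{name} not co-registered with B8A")
    denom = np.asarray(b8a.values, dtype=float)
    invalid = denom <= 0
    safe = np.where(invalid, 1.0, denom)
    r1 = np.asarray(b7.values, dtype=float) / safe
    r2 = np.asarray(b8.values, dtype=float) / safe
    r1[invalid] = 0.0
    r2[invalid] = 0.0
    v1 = _window_variance(r1, window)
    v2 = _window_variance(r2, window)
    denom_v = v1 + v2
    with np.errstate(invalid="ignore", divide="ignore"):
        cdi = np.where(denom_v > 0, (v2 - v1) / np.where(denom_v > 0, denom_v, 1.0), 0.0)
    nodata = invalid.copy()
    if b8a.nodata is not None:
        nodata |= b8a.nodata
    return RasterGrid(cdi, b8a.pixel_size, b8a.origin, nodata)


def _disk(radius: int) -> np.ndarray:
    yy, xx = np.mgrid[-radius:radius + 1, -radius:radius + 1]
    return (xx ** 2 + yy ** 2) <= radius ** 2


def build_cloud_mask(scene: Scene, config: MaskingConfig | None = None) -> RasterGrid:
    """Three-step cloud mask at the compute resolution (default 20 m)."""
    config = config or MaskingConfig()
    ps = config.compute_pixel_size
    try:
        s2c = resample_nearest(scene.s2c, ps)
        b7 = resample_bilinear(scene.bands["B7"], ps)
        b8 = resample_bilinear(scene.bands["B8"], ps)
        b8a = resample_bilinear(scene.bands["B8A"], ps)
        b10 = resample_bilinear(scene.bands["B10"], ps)
    except KeyError as exc:
        raise MaskingError(f"scene is missing band {exc}") from exc

    m_s2c = s2c.values >= config.s2c_threshold
    cdi = compute_cdi(b7, b8, b8a, config.cdi_window)
    m_cdi = cdi.values < config.cdi_threshold
    core = m_s2c & m_cdi
    cirrus = b10.values >= config.cirrus_threshold
    combined = core | cirrus if config.cirrus_mode == "union" else core & cirrus
    opened = ndimage.binary_opening(combined, structure=_disk(config.opening_radius))
    return RasterGrid(opened, ps, s2c.origin)


def shadow_offsets(solar_azimuth_deg: float, distance_m: float,
                   pixel_size: float) -> list[tuple[int, int]]:
    """Unique (row, col) pixel offsets covering the anti-solar ray.

    The anti-solar displacement direction is (sin(az+180), cos(az+180)) in
    (east, north) map components; row index grows southward.  Offsets are the
    rounded displacements at every whole-pixel step along the ray out to
    ``distance_m``.
    """
    theta = math.radians((solar_azimuth_deg + 180.0) % 360.0)
    de, dn = math.sin(theta), math.cos(theta)
    n_steps = int(math.floor(distance_m / pixel_size + 1e-9))
    seen: dict[tuple[int, int], None] = {}
    for t in range(1, n_steps + 1):
        off = (round(-t * dn), round(t * de))
        if off != (0, 0):
            seen.setdefault(off, None)
    return list(seen)


def _shift_or(acc: np.ndarray, mask: np.ndarray, dr: int, dc: int) -> None:
    nr, nc = mask.shape
    sr0, sr1 = max(0, dr), min(nr, nr + dr)
    sc0, sc1 = max(0, dc), min(nc, nc + dc)
    if sr0 >= sr1 or sc0 >= sc1:
        return
    acc[sr0:sr1, sc0:sc1] |= mask[sr0 - dr:sr1 - dr, sc0 - dc:sc1 - dc]


def extend_shadow_ddt(cloud: RasterGrid, solar_azimuth_deg: float,
                      config: MaskingConfig | None = None) -> RasterGrid:
    """Directional distance transform: flag every pixel that has a cloud pixel
    within ``shadow_distance_m`` behind it along the anti-solar ray.

    Implemented as a sweep of shifted copies of the cloud mask (one OR per
    unique rounded offset along the ray); equivalent to per-pixel ray casting.
    """
    config = config or MaskingConfig()
    mask = np.asarray(cloud.values, dtype=bool)
    out = np.zeros_like(mask)
    for dr, dc in shadow_offsets(solar_azimuth_deg, config.shadow_distance_m,
                                 cloud.pixel_size):
        _shift_or(out, mask, dr, dc)
    return RasterGrid(out, cloud.pixel_size, cloud.origin)


def finalize_mask(cloud: RasterGrid, shadow: RasterGrid,
                  config: MaskingConfig | None = None) -> FinalMask:
    """Combine cloud and shadow masks and coarsen to the final resolution."""
    config = config or MaskingConfig()
    if cloud.shape != shadow.shape or cloud.pixel_size != shadow.pixel_size:
        raise MaskingError("cloud and shadow masks are misaligned")
    combined = RasterGrid(np.asarray(cloud.values, bool) | np.asarray(shadow.values, bool),
                          cloud.pixel_size, cloud.origin)
    final = coarsen_any(combined, config.final_pixel_size)
    return FinalMask(cloud=cloud, shadow=shadow, combined_final=final, config=config)


def mask_scene(scene: Scene, config: MaskingConfig | None = None) -> FinalMask:
    """Full pipeline: cloud mask, shadow extension, finalization."""
    config = config or MaskingConfig()
    cloud = build_cloud_mask(scene, config)
    shadow = extend_shadow_ddt(cloud, scene.solar_azimuth_deg, config)
    return finalize_mask(cloud, shadow, config)
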