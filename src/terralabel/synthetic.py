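"""Synthetic scene generation: label worlds, reflectance rendering, clouds,
shadows, and simulated annotators.

The generator is the test substrate for the whole pipeline.  It emulates the
structure the real data has — patchy landscapes with a minimum mapping unit,
multi-resolution band stacks derived from a common 10 m field, a cloud
probability layer, clouds with parallax-like band-ratio texture, shadows
displaced anti-solar from their clouds, and polygon annotations with
controlled expert/non-expert disagreement — without attempting radiative
realism.  Everything is a pure function of (config, seed).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage
from shapely.geometry import MultiPolygon, box
from shapely.ops import unary_union

from .io_core import (ALL_BANDS, BAND_RESOLUTION, N_CLASSES, RasterGrid, Scene,
                      block_mean)
from .training_prep import AnnotationPolygon, AnnotationSet


class ConfigError(ValueError):
    pass


@dataclass
class WorldConfig:
    """Parameters of a generated label world.

    ``tile_pixels`` is the edge length in 10 m pixels (default 510, i.e. a
    5.1 km tile); ``mmu_pixels`` is the minimum patch edge (default 5 pixels =
    50 m).  ``class_mixture`` gives the target areal fraction per class.
    """

    seed: int = 0
    tile_pixels: int = 510
    class_mixture: tuple[float, ...] = tuple([1.0 / N_CLASSES] * N_CLASSES)
    blob_scale: float = 60.0
    mmu_pixels: int = 5

    def __post_init__(self) -> None:
        mix = np.asarray(self.class_mixture, dtype=float)
        if mix.size > N_CLASSES:
            raise ConfigError(f"class_mixture has {mix.size} entries; at most {N_CLASSES} classes exist")
        if np.any(mix < 0) or abs(mix.sum() - 1.0) > 1e-8:
            raise ConfigError("class_mixture must be non-negative and sum to 1")
        if self.mmu_pixels < 1:
            raise ConfigError("mmu_pixels must be >= 1")
        if self.tile_pixels < 2 * self.mmu_pixels:
            raise ConfigError("tile_pixels must be >= 2 * mmu_pixels")


# Plausible top-of-atmosphere reflectance means per class per band.  Values
# are loosely inspired by typical spectra (water dark, vegetation with a red
# edge, snow bright); exact numbers only need to make classes separable.
_BASE_MEANS = {
    # class:          B2    B3    B4    B5    B6    B7    B8    B8A   B11   B12
    0: dict(zip(("B2", "B3", "B4", "B5", "B6", "B7", "B8", "B8A", "B11", "B12"),
                (0.08, 0.06, 0.04, 0.03, 0.02, 0.02, 0.02, 0.02, 0.01, 0.01))),  # water
    1: dict(zip(("B2", "B3", "B4", "B5", "B6", "B7", "B8", "B8A", "B11", "B12"),
                (0.03, 0.05, 0.03, 0.08, 0.25, 0.32, 0.35, 0.36, 0.15, 0.07))),  # trees
    2: dict(zip(("B2", "B3", "B4", "B5", "B6", "B7", "B8", "B8A", "B11", "B12"),
                (0.06, 0.09, 0.08, 0.14, 0.25, 0.28, 0.30, 0.31, 0.25, 0.14))),  # grass
    3: dict(zip(("B2", "B3", "B4", "B5", "B6", "B7", "B8", "B8A", "B11", "B12"),
                (0.06, 0.07, 0.05, 0.08, 0.14, 0.16, 0.17, 0.17, 0.08, 0.04))),  # flooded veg
    4: dict(zip(("B2", "B3", "B4", "B5", "B6", "B7", "B8", "B8A", "B11", "B12"),
                (0.07, 0.10, 0.11, 0.16, 0.22, 0.24, 0.26, 0.27, 0.30, 0.20))),  # crops
    5: dict(zip(("B2", "B3", "B4", "B5", "B6", "B7", "B8", "B8A", "B11", "B12"),
                (0.09, 0.11, 0.13, 0.16, 0.19, 0.21, 0.22, 0.23, 0.32, 0.26))),  # shrub & scrub
    6: dict(zip(("B2", "B3", "B4", "B5", "B6", "B7", "B8", "B8A", "B11", "B12"),
                (0.14, 0.15, 0.16, 0.17, 0.18, 0.19, 0.20, 0.20, 0.22, 0.21))),  # built
    7: dict(zip(("B2", "B3", "B4", "B5", "B6", "B7", "B8", "B8A", "B11", "B12"),
                (0.16, 0.20, 0.24, 0.28, 0.31, 0.33, 0.35, 0.36, 0.45, 0.40))),  # bare
    8: dict(zip(("B2", "B3", "B4", "B5", "B6", "B7", "B8", "B8A", "B11", "B12"),
                (0.85, 0.82, 0.78, 0.75, 0.72, 0.70, 0.68, 0.66, 0.15, 0.10))),  # snow & ice
}
_AUX_BANDS = ("B1", "B9", "B10")  # coastal aerosol, water vapour, cirrus


@dataclass
class SpectralLibrary:
    """Per-class reflectance model plus cloud / shadow / building signatures."""

    means: dict[int, dict[str, float]] = field(default_factory=lambda: {
        c: dict(m) for c, m in _BASE_MEANS.items()})
    noise_scale: float = 0.012
    cloud_boost: float = 0.55
    cloud_cirrus: float = 0.03
    shadow_factor: float = 0.35
    building_boost: float = 0.45

    def __post_init__(self) -> None:
        for c, bands in self.means.items():
            if any(v < 0 for v in bands.values()):
                raise ConfigError(f"negative mean reflectance for class {c}")
        if self.noise_scale < 0 or self.cloud_boost <= 0:
            raise ConfigError("noise_scale must be >= 0 and cloud_boost > 0")
        if not (0.0 < self.shadow_factor < 1.0):
            raise ConfigError("shadow_factor must be in (0, 1)")

    def mean(self, class_id: int, band: str) -> float:
        if class_id not in self.means:
            raise ConfigError(f"class {class_id} missing from spectral library")
        if band in self.means[class_id]:
            return self.means[class_id][band]
        # Aux bands (B1/B9/B10) carry low, class-correlated signal.
        base = self.means[class_id]
        if band == "B1":
            return 0.8 * base["B2"]
        if band == "B9":
            return 0.3 * base["B8A"]
        if band == "B10":
            return 0.002  # cirrus band is near-dark for clear ground
        raise ConfigError(f"unknown band {band}")


@dataclass
class AnnotatorProfile:
    """Behavioural model of one annotator.

    ``confusion_kernel`` is a K x K row-stochastic matrix applied patch-wise:
    a patch whose true class is c is labeled k with probability kernel[c, k].
    ``coverage_fraction`` is the minimum labeled fraction of the tile.
    """

    annotator_id: str
    expertise: str = "expert"
    confusion_kernel: np.ndarray | None = None
    coverage_fraction: float = 0.7
    skip_probability: float = 0.1

    def __post_init__(self) -> None:
        if self.expertise not in ("expert", "non_expert"):
            raise ConfigError("expertise must be 'expert' or 'non_expert'")
        if self.confusion_kernel is None:
            self.confusion_kernel = np.eye(N_CLASSES)
        self.confusion_kernel = np.asarray(self.confusion_kernel, dtype=float)
        if self.confusion_kernel.shape[0] != self.confusion_kernel.shape[1]:
            raise ConfigError("confusion_kernel must be square")
        if not np.allclose(self.confusion_kernel.sum(axis=1), 1.0):
            raise ConfigError("confusion_kernel rows must sum to 1")
        if not (0.0 < self.coverage_fraction <= 1.0):
            raise ConfigError("coverage_fraction must be in (0, 1]")


def uniform_error_kernel(error_rate: float, k: int = N_CLASSES) -> np.ndarray:
    """Row-stochastic kernel with 1-e on the diagonal, e spread uniformly off it."""
    kern = np.full((k, k), error_rate / (k - 1))
    np.fill_diagonal(kern, 1.0 - error_rate)
    return kern


@dataclass
class SyntheticScenePackage:
    scene: Scene
    truth_labels: RasterGrid
    truth_contamination: RasterGrid
    annotations: list[AnnotationSet]
    cloud_mask: np.ndarray | None = None
    shadow_mask: np.ndarray | None = None
    building_mask: np.ndarray | None = None


# ---------------------------------------------------------------------------
# Truth generation

def generate_truth(config: WorldConfig) -> RasterGrid:
    """Generate a patchy categorical label world honouring the MMU.

    Labels are drawn on a coarse grid of mmu-sized blocks (so every connected
    patch has edge >= mmu_pixels by construction) by taking the per-cell argmax
    of smoothed Gaussian score fields, with per-class biases iteratively tuned
    toward ``class_mixture``, then block-replicated to 10 m pixels.
    """
    rng = np.random.default_rng(config.seed)
    mix = np.asarray(config.class_mixture, dtype=float)
    active = np.where(mix > 0)[0]
    n = config.tile_pixels
    mmu = config.mmu_pixels
    coarse = max(2, n // mmu)

    sigma = max(config.blob_scale / mmu / 2.0, 1.0)
    fields = np.stack([
        ndimage.gaussian_filter(rng.standard_normal((coarse, coarse)), sigma, mode="wrap")
        for _ in active
    ])
    fields /= fields.std(axis=(1, 2), keepdims=True) + 1e-12

    # Tune per-class biases so realized fractions approach the target mixture.
    bias = np.log(mix[active] + 1e-6)
    for _ in range(80):
        labels_c = np.argmax(fields + bias[:, None, None], axis=0)
        frac = np.bincount(labels_c.ravel(), minlength=active.size) / labels_c.size
        bias += 1.5 * (mix[active] - frac)
    labels_c = np.argmax(fields + bias[:, None, None], axis=0)
    labels_coarse = active[labels_c]

    labels = np.repeat(np.repeat(labels_coarse, mmu, axis=0), mmu, axis=1)
    # Pad to exactly tile_pixels if mmu does not divide it.
    labels = np.pad(labels, ((0, max(0, n - labels.shape[0])),
                             (0, max(0, n - labels.shape[1]))), mode="edge")[:n, :n]
    return RasterGrid(labels.astype(np.int16), 10.0,
                      categories=frozenset(range(N_CLASSES)))


# ---------------------------------------------------------------------------
# Rendering

def render_scene(truth: RasterGrid, library: SpectralLibrary | None = None,
                 seed: int = 0, *, solar_azimuth_deg: float = 135.0,
                 timestamp: str = "2019-07-01T10:30:00Z",
                 tile_id: str = "SYN_TILE") -> Scene:
    """Render a truth grid to a 13-band Scene with a clear (s2c = 0) sky.

    The 10 m field is generated per band from class means plus Gaussian noise
    (clipped at 0); 20 m and 60 m bands are block means of that field, which
    is what a coarser detector integrating the same radiance would record.
    """
    library = library or SpectralLibrary()
    rng = np.random.default_rng(seed)
    labels = truth.values
    if labels.shape[0] % 6 or labels.shape[1] % 6:
        raise ConfigError(
            "tile edge must be divisible by 6 so the 60 m bands align with the 10 m grid")
    present = np.unique(labels)
    for c in present:
        library.mean(int(c), "B2")  # raises if a class is missing

    n = labels.shape[0]
    bands: dict[str, RasterGrid] = {}
    for name in ALL_BANDS:
        mean_lut = np.array([library.mean(c, name) for c in range(N_CLASSES)])
        field10 = mean_lut[labels]
        if library.noise_scale > 0:
            field10 = field10 + rng.normal(0.0, library.noise_scale, size=field10.shape)
        field10 = np.clip(field10, 0.0, None)
        ps = BAND_RESOLUTION[name]
        if ps == 10.0:
            values = field10
        else:
            values = block_mean(field10, int(ps // 10))
        bands[name] = RasterGrid(values.astype(np.float32), ps)
    s2c = RasterGrid(np.zeros((n, n), dtype=np.float32), 10.0)
    return Scene(bands=bands, s2c=s2c, solar_azimuth_deg=solar_azimuth_deg,
                 cloudy_pixel_percentage=0.0, timestamp=timestamp, tile_id=tile_id)


def _ellipse_mask(shape: tuple[int, int], center: tuple[float, float],
                  axes: tuple[float, float], angle: float) -> np.ndarray:
    rr, cc = np.mgrid[0:shape[0], 0:shape[1]]
    dr, dc = rr - center[0], cc - center[1]
    ca, sa = math.cos(angle), math.sin(angle)
    u = dr * ca + dc * sa
    v = -dr * sa + dc * ca
    return (u / axes[0]) ** 2 + (v / axes[1]) ** 2 <= 1.0


def inject_clouds_shadows(scene: Scene, truth: RasterGrid, cloud_fraction: float,
                          solar_azimuth_deg: float | None = None, seed: int = 0, *,
                          shadow_displacement_m: float = 1000.0,
                          add_building: bool = False,
                          library: SpectralLibrary | None = None,
                          place_shadows: bool = True) -> SyntheticScenePackage:
    """Place elliptical clouds (with CDI-active band-ratio texture), anti-solar
    shadows, and optionally a bright CDI-neutral "building" target.

    Over clouds the B7/B8A ratio field receives strong local texture while the
    B8/B8A ratio stays comparatively smooth, giving the two near-infrared
    ratios the distinct local variances that the Cloud Displacement Index
    keys on; the building gets high cloud probability but spatially uniform
    ratios, so the parallax test must clear it.
    """
    if not (0.0 <= cloud_fraction < 1.0):
        raise ConfigError("cloud_fraction must be in [0, 1)")
    if cloud_fraction == 0.0 and place_shadows and not add_building:
        if solar_azimuth_deg is None:
            solar_azimuth_deg = scene.solar_azimuth_deg
        # no clouds: nothing to do, but keep the contract explicit
    library = library or SpectralLibrary()
    rng = np.random.default_rng(seed)
    az = scene.solar_azimuth_deg if solar_azimuth_deg is None else solar_azimuth_deg

    n = truth.values.shape[0]
    cloud10 = np.zeros((n, n), dtype=bool)
    if cloud_fraction > 0:
        target = cloud_fraction * n * n
        attempts = 0
        while cloud10.sum() < target and attempts < 200:
            a = rng.uniform(0.05, 0.14) * n
            b = rng.uniform(0.5, 0.9) * a
            center = (rng.uniform(0.15, 0.85) * n, rng.uniform(0.15, 0.85) * n)
            cloud10 |= _ellipse_mask((n, n), center, (a, b), rng.uniform(0, math.pi))
            attempts += 1

    shadow10 = np.zeros((n, n), dtype=bool)
    if place_shadows and cloud10.any():
        theta = math.radians((az + 180.0) % 360.0)
        d_pix = shadow_displacement_m / 10.0
        dc = d_pix * math.sin(theta)          # east displacement in columns
        dr = -d_pix * math.cos(theta)         # north displacement = -rows
        rr, cc = np.nonzero(cloud10)
        r2 = np.round(rr + dr).astype(int)
        c2 = np.round(cc + dc).astype(int)
        keep = (r2 >= 0) & (r2 < n) & (c2 >= 0) & (c2 < n)
        shadow10[r2[keep], c2[keep]] = True
        shadow10 &= ~cloud10

    building10 = np.zeros((n, n), dtype=bool)
    if add_building:
        size = max(6, n // 40)
        r0 = int(rng.uniform(0.1, 0.8) * n)
        c0 = int(rng.uniform(0.1, 0.8) * n)
        for _ in range(50):
            if not (cloud10[r0:r0 + size, c0:c0 + size].any()
                    or shadow10[r0:r0 + size, c0:c0 + size].any()):
                break
            r0 = int(rng.uniform(0.1, 0.8) * n)
            c0 = int(rng.uniform(0.1, 0.8) * n)
        building10[r0:r0 + size, c0:c0 + size] = True

    bands = {name: grid.copy() for name, grid in scene.bands.items()}
    s2c = scene.s2c.values.copy().astype(np.float32)

    # Smooth texture field used to give the B8/B8A ratio variance over clouds.
    texture = ndimage.gaussian_filter(rng.standard_normal((n, n)), 1.5)
    texture /= texture.std() + 1e-12

    for name, grid in bands.items():
        ps = grid.pixel_size
        f = int(ps // 10)
        cl = cloud10 if f == 1 else block_mean(cloud10.astype(float), f) > 0.5
        sh = shadow10 if f == 1 else block_mean(shadow10.astype(float), f) > 0.5
        bl = building10 if f == 1 else block_mean(building10.astype(float), f) > 0.5
        v = grid.values.astype(np.float32)
        boost = library.cloud_cirrus if name == "B10" else library.cloud_boost
        v[cl] = v[cl] + boost
        if name == "B7":
            # parallax texture: strong multiplicative ripple on B7 over clouds
            tex = texture if f == 1 else block_mean(texture, f)
            v[cl] = v[cl] * (1.0 + 0.35 * tex[cl])
        v[sh] = v[sh] * library.shadow_factor
        if name != "B10":
            v[bl] = v[bl] + library.building_boost   # uniform boost: CDI-neutral
        grid.values = np.clip(v, 0.0, None)

    s2c[cloud10] = np.clip(rng.uniform(0.85, 1.0, size=int(cloud10.sum())), 0, 1)
    s2c[building10] = 0.9   # the commission error the parallax step must fix
    s2c = np.clip(s2c, 0.0, 1.0)

    contamination = cloud10 | shadow10
    out_scene = Scene(
        bands=bands,
        s2c=RasterGrid(s2c, 10.0),
        solar_azimuth_deg=az % 360.0,
        cloudy_pixel_percentage=100.0 * cloud10.mean(),
        timestamp=scene.timestamp,
        tile_id=scene.tile_id,
    )
    return SyntheticScenePackage(
        scene=out_scene,
        truth_labels=truth,
        truth_contamination=RasterGrid(contamination, 10.0),
        annotations=[],
        cloud_mask=cloud10,
        shadow_mask=shadow10,
        building_mask=building10,
    )


# ---------------------------------------------------------------------------
# Annotators

def _patch_components(labels: np.ndarray) -> tuple[np.ndarray, int]:
    """Connected components of constant-label patches (4-connectivity)."""
    comp = np.zeros_like(labels, dtype=np.int32)
    next_id = 0
    for c in np.unique(labels):
        lab, k = ndimage.label(labels == c)
        comp[lab > 0] = lab[lab > 0] + next_id
        next_id += k
    return comp, next_id


def _patch_polygon(comp: np.ndarray, patch_id: int, pixel_size: float,
                   origin: tuple[float, float]) -> MultiPolygon:
    rows, cols = np.nonzero(comp == patch_id)
    x0, y0 = origin
    cells = [box(x0 + c * pixel_size, y0 - (r + 1) * pixel_size,
                 x0 + (c + 1) * pixel_size, y0 - r * pixel_size)
             for r, c in zip(rows, cols)]
    geom = unary_union(cells)
    return geom


def simulate_annotators(truth: RasterGrid, profiles: list[AnnotatorProfile],
                        seed: int = 0, mmu_pixels: int = 5) -> list[AnnotationSet]:
    """Produce one polygon AnnotationSet per profile.

    Patches are the connected constant-label regions of the truth grid (which
    the generator builds from mmu-sized blocks).  Each annotator may skip
    patches with ``skip_probability`` — but never below ``coverage_fraction``
    of total area — and mislabels whole patches according to its confusion
    kernel, mimicking polygon-level disagreement.
    """
    if not profiles:
        raise ConfigError("at least one annotator profile required")
    coarse = truth.values[::mmu_pixels, ::mmu_pixels]
    comp_c, n_comp = _patch_components(coarse)
    comp = np.repeat(np.repeat(comp_c, mmu_pixels, axis=0), mmu_pixels, axis=1)
    comp = comp[:truth.values.shape[0], :truth.values.shape[1]]

    patch_ids = np.arange(1, n_comp + 1)
    areas = np.bincount(comp.ravel(), minlength=n_comp + 1)[1:]
    total = areas.sum()
    patch_class = ndimage.labeled_comprehension(
        coarse, comp_c, patch_ids, lambda v: v[0], np.int16, 0)

    out: list[AnnotationSet] = []
    for i, prof in enumerate(profiles):
        rng = np.random.default_rng(np.random.SeedSequence([seed, i]))
        order = rng.permutation(n_comp)
        kept = np.ones(n_comp, dtype=bool)
        covered = float(total)
        for j in order:
            if rng.random() < prof.skip_probability:
                if (covered - areas[j]) / total >= prof.coverage_fraction:
                    kept[j] = False
                    covered -= areas[j]
        k = prof.confusion_kernel.shape[0]
        assigned = np.array([
            rng.choice(k, p=prof.confusion_kernel[patch_class[j]])
            for j in range(n_comp)
        ])
        polygons = []
        for draw_order, j in enumerate(np.nonzero(kept)[0]):
            geom = _patch_polygon(comp, int(patch_ids[j]), truth.pixel_size, truth.origin)
            polygons.append(AnnotationPolygon(
                geometry=geom, class_id=int(assigned[j]), draw_order=draw_order))
        out.append(AnnotationSet(
            polygons=polygons, annotator_id=prof.annotator_id,
            expertise=prof.expertise, tile_id="SYN_TILE"))
    return out


def make_package(config: WorldConfig, *, cloud_fraction: float = 0.1,
                 add_building: bool = False,
                 profiles: list[AnnotatorProfile] | None = None,
                 library: SpectralLibrary | None = None,
                 solar_azimuth_deg: float = 135.0) -> SyntheticScenePackage:
    """Convenience: truth -> rendered scene -> clouds/shadows -> annotations."""
    ss = np.random.SeedSequence(config.seed)
    s_render, s_cloud, s_annot = [int(s.generate_state(1)[0] % (2**31)) for s in ss.spawn(3)]
    truth = generate_truth(config)
    scene = render_scene(truth, library, seed=s_render, solar_azimuth_deg=solar_azimuth_deg)
    pkg = inject_clouds_shadows(scene, truth, cloud_fraction,
                                solar_azimuth_deg, seed=s_cloud,
                                add_building=add_building, library=library)
    if profiles:
        pkg.annotations = simulate_annotators(truth, profiles, seed=s_annot,
                                              mmu_pixels=config.mmu_pixels)
    return pkg
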