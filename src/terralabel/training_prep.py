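"""Annotation handling and training-example preparation.

Polygon annotations are rasterized by pixel-center containment, one-hot
targets are smoothed according to annotator confidence, per-pixel weights
compensate class imbalance / emphasise high-frequency structure / attenuate
polygon interiors, and examples are augmented by right-angle rotation plus
per-band contrast (power) transforms.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import shapely
from scipy import ndimage
from shapely.geometry import mapping as shapely_mapping
from shapely.geometry import shape as shapely_shape
from shapely.geometry.base import BaseGeometry

from .io_core import N_ANNOTATION_CLASSES, RasterGrid

UNLABELED = -1  #: sentinel for pixels in no polygon


class AnnotationError(ValueError):
    pass


@dataclass
class AnnotationPolygon:
    geometry: BaseGeometry
    class_id: int
    draw_order: int = 0

    def __post_init__(self) -> None:
        if not (0 <= self.class_id < N_ANNOTATION_CLASSES):
            raise AnnotationError(
                f"class_id {self.class_id} outside the {N_ANNOTATION_CLASSES}-class taxonomy")


@dataclass
class AnnotationSet:
    """One annotator's polygons for one tile (class 9 = cloud)."""

    polygons: list[AnnotationPolygon]
    annotator_id: str
    expertise: str
    tile_id: str

    def __post_init__(self) -> None:
        if self.expertise not in ("expert", "non_expert"):
            raise AnnotationError("expertise must be 'expert' or 'non_expert'")


@dataclass
class SmoothingConfig:
    """Confidence-weighted label smoothing: experts get less smoothing."""

    eps_expert: float = 0.2
    eps_nonexpert: float = 0.3
    n_classes: int = N_ANNOTATION_CLASSES

    def __post_init__(self) -> None:
        for eps in (self.eps_expert, self.eps_nonexpert):
            if not (0.0 <= eps < 1.0):
                raise AnnotationError("smoothing epsilon must be in [0, 1)")
        if self.n_classes < 2:
            raise AnnotationError("need at least 2 classes")

    def eps(self, expertise: str) -> float:
        return self.eps_expert if expertise == "expert" else self.eps_nonexpert


@dataclass
class WeightConfig:
    beta_high_freq: float = 4.0   # gain on gradient magnitude
    d_edge: float = 2.0           # pixels: "near a label boundary"
    w_interior: float = 0.5       # attenuation deep inside polygons


@dataclass
class TrainingExample:
    """Inputs, smoothed targets, weights and masks for one tile."""

    inputs: np.ndarray        # (9, H, W) normalized reflectance in (0, 1)
    targets: np.ndarray       # (K, H, W) per-pixel distribution where labeled
    class_weight: np.ndarray  # (H, W) classification weight (balance x edge)
    synth_weight: np.ndarray  # (H, W) synthesis (high-frequency) weight
    labeled: np.ndarray       # (H, W) bool
    clear: np.ndarray         # (H, W) bool, False under cloud/shadow mask

    def __post_init__(self) -> None:
        h, w = self.inputs.shape[1:]
        for name in ("targets", "class_weight", "synth_weight", "labeled", "clear"):
            arr = getattr(self, name)
            if arr.shape[-2:] != (h, w):
                raise AnnotationError(f"{name} shape mismatch")
        if np.any(self.class_weight < 0) or np.any(self.synth_weight < 0):
            raise AnnotationError("weights must be non-negative")
        sums = self.targets.sum(axis=0)[self.labeled]
        if sums.size and not np.allclose(sums, 1.0, atol=1e-5):
            raise AnnotationError("targets must sum to 1 on labeled pixels")


# ---------------------------------------------------------------------------

def rasterize_annotations(annotations: AnnotationSet, grid: RasterGrid) -> RasterGrid:
    """Label each pixel by the polygon containing its center; overlaps resolved
    by highest draw_order; uncovered pixels get the UNLABELED sentinel."""
    nr, nc = grid.shape
    out = np.full((nr, nc), UNLABELED, dtype=np.int16)
    x0, y0 = grid.origin
    ps = grid.pixel_size
    xs = x0 + (np.arange(nc) + 0.5) * ps
    ys = y0 - (np.arange(nr) + 0.5) * ps

    for idx, poly in enumerate(sorted(annotations.polygons, key=lambda p: p.draw_order)):
        geom = poly.geometry
        if geom.is_empty:
            continue
        if not geom.is_valid:
            raise AnnotationError(f"invalid geometry at polygon index {idx}")
        minx, miny, maxx, maxy = geom.bounds
        c_lo = max(0, int(np.floor((minx - x0) / ps - 0.5)))
        c_hi = min(nc, int(np.ceil((maxx - x0) / ps + 0.5)))
        r_lo = max(0, int(np.floor((y0 - maxy) / ps - 0.5)))
        r_hi = min(nr, int(np.ceil((y0 - miny) / ps + 0.5)))
        if c_lo >= c_hi or r_lo >= r_hi:
            continue
        xx, yy = np.meshgrid(xs[c_lo:c_hi], ys[r_lo:r_hi])
        inside = shapely.contains_xy(geom, xx.ravel(), yy.ravel()).reshape(xx.shape)
        window = out[r_lo:r_hi, c_lo:c_hi]
        window[inside] = poly.class_id
    return RasterGrid(out, ps, grid.origin,
                      categories=frozenset(range(-1, N_ANNOTATION_CLASSES)))


def smooth_labels(labels: RasterGrid | np.ndarray, expertise: str,
                  config: SmoothingConfig | None = None) -> tuple[np.ndarray, np.ndarray]:
    """Smooth one-hot labels toward the uniform distribution.

    For a labeled pixel of class c: target(k) = (1 - eps) * [k == c] + eps / K.
    Returns ``(targets, labeled)`` where targets is (K, H, W) and rows for
    unlabeled pixels are all zero.
    """
    config = config or SmoothingConfig()
    lab = labels.values if isinstance(labels, RasterGrid) else np.asarray(labels)
    eps = config.eps(expertise)
    k = config.n_classes
    labeled = lab != UNLABELED
    targets = np.zeros((k,) + lab.shape, dtype=np.float32)
    base = eps / k
    for c in range(k):
        targets[c][labeled] = base + (1.0 - eps) * (lab[labeled] == c)
    return targets, labeled


def class_balance_weights(corpus_class_counts: np.ndarray) -> np.ndarray:
    """w(c) = T / (C * n_c) over classes with n_c > 0 (0 for absent classes).

    Preserves total weighted mass: sum_c n_c * w(c) = T.
    """
    counts = np.asarray(corpus_class_counts, dtype=float)
    total = counts.sum()
    n_present = int((counts > 0).sum())
    w = np.zeros_like(counts)
    if n_present:
        nz = counts > 0
        w[nz] = total / (n_present * counts[nz])
    return w


def high_frequency_weight(inputs: np.ndarray, beta: float = 4.0) -> np.ndarray:
    """1 + beta * mean-over-bands gradient magnitude of the input stack."""
    gy, gx = np.gradient(inputs, axis=(1, 2))
    mag = np.sqrt(gx ** 2 + gy ** 2).mean(axis=0)
    return 1.0 + beta * mag


def edge_attenuation_weight(labels: np.ndarray, d_edge: float = 2.0,
                            w_interior: float = 0.5) -> np.ndarray:
    """1.0 within d_edge pixels of a label boundary, w_interior deeper inside.

    A boundary pixel is one whose label differs from a 4-neighbour (transitions
    to unlabeled count).  Unlabeled pixels get weight 0.
    """
    lab = np.asarray(labels)
    boundary = np.zeros(lab.shape, dtype=bool)
    boundary[:-1, :] |= lab[:-1, :] != lab[1:, :]
    boundary[1:, :] |= lab[1:, :] != lab[:-1, :]
    boundary[:, :-1] |= lab[:, :-1] != lab[:, 1:]
    boundary[:, 1:] |= lab[:, 1:] != lab[:, :-1]
    # outer image edge counts as a boundary too
    boundary[0, :] = boundary[-1, :] = boundary[:, 0] = boundary[:, -1] = True
    dist = ndimage.distance_transform_edt(~boundary)
    w = np.where(dist > d_edge, w_interior, 1.0)
    w[lab == UNLABELED] = 0.0
    return w


def compute_weights(labels: RasterGrid | np.ndarray, inputs: np.ndarray,
                    corpus_class_counts: np.ndarray,
                    config: WeightConfig | None = None,
                    ) -> dict[str, np.ndarray]:
    """Per-pixel weight grids: class_balance, high_freq, edge, plus the
    combined classification weight (class_balance x edge)."""
    config = config or WeightConfig()
    lab = labels.values if isinstance(labels, RasterGrid) else np.asarray(labels)
    w_class = class_balance_weights(corpus_class_counts)
    labeled = lab != UNLABELED
    if not labeled.any():
        import warnings
        warnings.warn("no labeled pixels: classification weights are all zero")
    balance = np.zeros(lab.shape, dtype=float)
    balance[labeled] = w_class[lab[labeled]]
    high_freq = high_frequency_weight(inputs, config.beta_high_freq)
    edge = edge_attenuation_weight(lab, config.d_edge, config.w_interior)
    return {
        "class_balance": balance,
        "high_freq": high_freq,
        "edge": edge,
        "classification": balance * edge,
    }


# ---------------------------------------------------------------------------
# Augmentation

def augment(example: TrainingExample, copies: int = 4, seed: int = 0,
            gamma_range: tuple[float, float] = (0.8, 1.25)) -> list[TrainingExample]:
    """Produce ``copies`` augmented variants of an example.

    Each copy applies one rotation from {0, 90, 180, 270} degrees (the same to
    every per-pixel field) and an independent per-band contrast x -> x**gamma
    with gamma uniform in ``gamma_range``; power transforms are monotone and
    closed on (0, 1).
    """
    if copies < 1:
        raise AnnotationError("copies must be >= 1")
    rng = np.random.default_rng(seed)
    out = []
    for _ in range(copies):
        k = int(rng.integers(0, 4))
        gammas = rng.uniform(*gamma_range, size=example.inputs.shape[0])
        rot = lambda a: np.rot90(a, k, axes=(-2, -1)).copy()
        inputs = rot(example.inputs) ** gammas[:, None, None]
        out.append(TrainingExample(
            inputs=inputs.astype(example.inputs.dtype),
            targets=rot(example.targets),
            class_weight=rot(example.class_weight),
            synth_weight=rot(example.synth_weight),
            labeled=rot(example.labeled),
            clear=rot(example.clear),
        ))
    return out


# ---------------------------------------------------------------------------
# Example assembly and archive I/O

def prepare_example(scene, annotations: AnnotationSet, stats,
                    corpus_class_counts: np.ndarray,
                    final_mask=None,
                    weight_config: WeightConfig | None = None,
                    smoothing: SmoothingConfig | None = None) -> TrainingExample:
    """Assemble one TrainingExample from a scene, one annotator's polygons,
    fitted normalization stats, and (optionally) a cloud/shadow mask."""
    from .inference import expand_mask_to_10m, prepare_model_inputs

    inputs = prepare_model_inputs(scene, stats)
    grid = scene.bands["B2"]
    labels = rasterize_annotations(annotations, grid)
    targets, labeled = smooth_labels(labels, annotations.expertise, smoothing)
    weights = compute_weights(labels, inputs, corpus_class_counts, weight_config)
    if final_mask is None:
        clear = np.ones(inputs.shape[1:], dtype=bool)
    else:
        clear = ~expand_mask_to_10m(final_mask, inputs.shape[1:])
    return TrainingExample(inputs=inputs, targets=targets,
                           class_weight=weights["classification"],
                           synth_weight=weights["high_freq"],
                           labeled=labeled, clear=clear)


_EXAMPLE_FIELDS = ("inputs", "targets", "class_weight", "synth_weight",
                   "labeled", "clear")


def save_examples(path: Path | str, examples: list[TrainingExample]) -> None:
    """Store examples as one compressed array archive plus a JSON manifest."""
    path = Path(path)
    arrays = {"n_examples": np.array(len(examples))}
    for i, ex in enumerate(examples):
        for name in _EXAMPLE_FIELDS:
            arrays[f"{name}_{i}"] = getattr(ex, name)
    np.savez_compressed(path, **arrays)
    manifest = {
        "n_examples": len(examples),
        "fields": list(_EXAMPLE_FIELDS),
        "shapes": [list(ex.inputs.shape) for ex in examples],
    }
    path.with_suffix(".manifest.json").write_text(json.dumps(manifest, indent=1))


def load_examples(path: Path | str) -> list[TrainingExample]:
    blob = np.load(Path(path))
    n = int(blob["n_examples"])
    return [TrainingExample(**{name: blob[f"{name}_{i}"] for name in _EXAMPLE_FIELDS})
            for i in range(n)]


# ---------------------------------------------------------------------------
# GeoJSON I/O

def annotations_to_geojson(annotations: AnnotationSet) -> dict:
    features = []
    for poly in annotations.polygons:
        features.append({
            "type": "Feature",
            "geometry": shapely_mapping(poly.geometry),
            "properties": {
                "class_id": poly.class_id,
                "annotator_id": annotations.annotator_id,
                "expertise": annotations.expertise,
                "draw_order": poly.draw_order,
            },
        })
    return {"type": "FeatureCollection",
            "properties": {"tile_id": annotations.tile_id},
            "features": features}


def annotations_from_geojson(doc: dict) -> AnnotationSet:
    feats = doc.get("features", [])
    if not feats:
        return AnnotationSet([], "unknown", "expert",
                             doc.get("properties", {}).get("tile_id", "unknown"))
    props0 = feats[0]["properties"]
    polygons = [AnnotationPolygon(
        geometry=shapely_shape(f["geometry"]),
        class_id=int(f["properties"]["class_id"]),
        draw_order=int(f["properties"].get("draw_order", i)),
    ) for i, f in enumerate(feats)]
    return AnnotationSet(
        polygons=polygons,
        annotator_id=str(props0.get("annotator_id", "unknown")),
        expertise=str(props0.get("expertise", "expert")),
        tile_id=str(doc.get("properties", {}).get("tile_id", "unknown")),
    )


def write_annotations(path: Path | str, annotations: AnnotationSet) -> None:
    Path(path).write_text(json.dumps(annotations_to_geojson(annotations)))


def read_annotations(path: Path | str) -> AnnotationSet:
    return annotations_from_geojson(json.loads(Path(path).read_text()))
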