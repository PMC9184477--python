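"""Per-scene probabilistic inference: the probability + label product.

A scene's 9 model bands (B2-B4, B5-B7, B8, B11, B12 — B1, B8A, B9 and B10
are dropped) are bilinearly upsampled to 10 m, normalized with the fitted
global stats, and pushed through the labeling model.  The product carries one
probability band per class (summing to 1 at every valid pixel), a Top-1 label
band (ties broken toward the lowest class index), and a nodata mask obtained
by expanding the 100 m cloud/shadow mask to 10 m by nearest replication.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import tifffile

from .io_core import CLASS_NAMES, MODEL_BANDS, N_CLASSES, Scene, \
    resample_bilinear, resample_nearest
from .masking import FinalMask
from .model import ALGORITHM_VERSION, FCN, predict_probs
from .normalization import NormStats, normalize


class InferenceError(RuntimeError):
    pass


@dataclass
class CollectionFilter:
    max_cloudy_pixel_percentage: float = 35.0

    def __post_init__(self) -> None:
        if not (0.0 <= self.max_cloudy_pixel_percentage <= 100.0):
            raise InferenceError("max_cloudy_pixel_percentage outside [0, 100]")


@dataclass
class ProbabilityImage:
    """Nine class-probability grids, the Top-1 label grid, and metadata."""

    probabilities: np.ndarray   # (9, H, W) float, rows ordered as CLASS_NAMES
    label: np.ndarray           # (H, W) uint8 in [0, 8]
    nodata: np.ndarray          # (H, W) bool, True where masked
    pixel_size: float
    origin: tuple[float, float]
    metadata: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.validate()

    def validate(self) -> None:
        if self.probabilities.shape[0] != N_CLASSES:
            raise InferenceError("expected 9 probability bands")
        valid = ~self.nodata
        if valid.any():
            sums = self.probabilities[:, valid].sum(axis=0)
            if not np.allclose(sums, 1.0, atol=1e-6):
                raise InferenceError("probabilities do not sum to 1 at valid pixels")
            argmax = self.probabilities.argmax(axis=0)
            if not np.array_equal(self.label[valid], argmax[valid]):
                raise InferenceError("label band is not the argmax of the probabilities")
        if self.label.max(initial=0) > 8:
            raise InferenceError("label values must lie in [0, 8]")

    @property
    def valid(self) -> np.ndarray:
        return ~self.nodata


def prepare_model_inputs(scene: Scene, stats: NormStats) -> np.ndarray:
    """(9, H, W) normalized stack at 10 m, bands in fixed MODEL_BANDS order.

    Raw reflectance is bilinearly upsampled to 10 m first; normalization is
    applied afterwards (pointwise, so the order only matters for the 20 m
    bands' interpolated values).
    """
    stack = []
    for name in MODEL_BANDS:
        if name not in scene.bands:
            raise InferenceError(f"scene is missing band {name}")
        grid = resample_bilinear(scene.bands[name], 10.0)
        stack.append(normalize(grid, name, stats).values)
    return np.stack(stack).astype(np.float32)


def expand_mask_to_10m(mask: FinalMask, shape: tuple[int, int]) -> np.ndarray:
    """Expand the 100 m combined mask to 10 m by nearest replication (each
    100 m cell masks its full block)."""
    grid = resample_nearest(mask.combined_final, 10.0)
    out = grid.values
    if out.shape != shape:
        raise InferenceError(f"mask shape {out.shape} does not match scene {shape}")
    return np.asarray(out, dtype=bool)


def predict_image(scene: Scene, labeling: FCN, stats: NormStats,
                  mask: FinalMask) -> ProbabilityImage:
    """Run the labeling model on a scene and package the masked product."""
    inputs = prepare_model_inputs(scene, stats)
    probs = predict_probs(labeling, inputs).astype(np.float64)
    probs /= probs.sum(axis=0, keepdims=True)
    nodata = expand_mask_to_10m(mask, inputs.shape[1:])
    label = probs.argmax(axis=0).astype(np.uint8)   # np.argmax: lowest index wins ties
    probs[:, nodata] = 0.0
    label[nodata] = 0
    ref = scene.bands["B2"]
    metadata = {
        "system:index": scene.tile_id,
        "system:time_start": scene.timestamp,
        "dynamicworld_algorithm_version": ALGORITHM_VERSION,
        "qa_algorithm_version": mask.qa_algorithm_version,
    }
    return ProbabilityImage(probabilities=probs, label=label, nodata=nodata,
                            pixel_size=10.0, origin=ref.origin, metadata=metadata)


def filter_collection(scenes: list[Scene],
                      collection_filter: CollectionFilter | None = None) -> list[Scene]:
    """Keep scenes strictly below the cloudy-pixel-percentage threshold,
    preserving input order; scenes without the metadata are skipped."""
    collection_filter = collection_filter or CollectionFilter()
    out = []
    for scene in scenes:
        cpp = getattr(scene, "cloudy_pixel_percentage", None)
        if cpp is None:
            import warnings
            warnings.warn(f"scene {getattr(scene, 'tile_id', '?')} lacks cloudiness metadata; skipped")
            continue
        if cpp < collection_filter.max_cloudy_pixel_percentage:
            out.append(scene)
    return out


# ---------------------------------------------------------------------------
# Product I/O: 10-band TIFF (water..snow_and_ice, label) + JSON sidecar.

def write_product(path: Path | str, image: ProbabilityImage) -> None:
    image.validate()
    path = Path(path)
    stack = np.concatenate([
        image.probabilities.astype(np.float32),
        image.label[None].astype(np.float32),
    ])
    tifffile.imwrite(path, stack, tile=(256, 256))
    tifffile.imwrite(path.with_name(path.stem + "_nodata.tif"),
                     image.nodata.astype(np.uint8), tile=(256, 256))
    sidecar = dict(image.metadata)
    sidecar.update({
        "bands": list(CLASS_NAMES) + ["label"],
        "pixel_size": image.pixel_size,
        "origin": list(image.origin),
    })
    path.with_suffix(".json").write_text(json.dumps(sidecar, indent=1))


def read_product(path: Path | str) -> ProbabilityImage:
    path = Path(path)
    stack = tifffile.imread(path)
    nodata = tifffile.imread(path.with_name(path.stem + "_nodata.tif")).astype(bool)
    meta = json.loads(path.with_suffix(".json").read_text())
    probs = stack[:N_CLASSES].astype(np.float64)
    valid = ~nodata
    probs[:, valid] /= probs[:, valid].sum(axis=0)
    return ProbabilityImage(
        probabilities=probs,
        label=stack[N_CLASSES].astype(np.uint8),
        nodata=nodata,
        pixel_size=float(meta["pixel_size"]),
        origin=tuple(meta["origin"]),
        metadata={k: meta[k] for k in ("system:index", "system:time_start",
                                       "dynamicworld_algorithm_version",
                                       "qa_algorithm_version") if k in meta},
    )
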