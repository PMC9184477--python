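"""Temporal composites and per-pixel time series over product collections.

Two composite flavours: the mode composite tallies Top-1 labels per pixel
over a half-open time window (most frequent valid label wins, ties broken
toward the lowest class index), and the mean-probability composite averages
the class distributions (which stays on the simplex) and takes the argmax of
the mean.  Pixels with zero valid observations come out as nodata.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .inference import ProbabilityImage
from .io_core import N_CLASSES


class AggregationError(ValueError):
    pass


def _time_key(value) -> float:
    """Timestamps compare as floats when numeric, else lexicographically
    (ISO-8601 strings order correctly)."""
    return value


@dataclass
class ImageCollection:
    images: list[ProbabilityImage]

    def __post_init__(self) -> None:
        self.images = sorted(self.images,
                             key=lambda im: _time_key(im.metadata.get("system:time_start")))
        if self.images:
            shape = self.images[0].label.shape
            for im in self.images:
                if im.label.shape != shape or im.pixel_size != self.images[0].pixel_size:
                    raise AggregationError("collection images are not aligned")

    def window(self, start, end) -> list[ProbabilityImage]:
        """Images with start <= system:time_start < end."""
        return [im for im in self.images
                if start <= im.metadata.get("system:time_start") < end]


def mode_composite(collection: ImageCollection, start, end) -> tuple[np.ndarray, np.ndarray]:
    """Per-pixel most frequent valid Top-1 label over [start, end).

    Returns ``(labels, nodata)``; pixels never observed are nodata.
    """
    images = collection.window(start, end)
    if not collection.images:
        raise AggregationError("empty collection")
    shape = collection.images[0].label.shape
    counts = np.zeros((N_CLASSES,) + shape, dtype=np.int32)
    for im in images:
        valid = im.valid
        for c in range(N_CLASSES):
            counts[c][valid & (im.label == c)] += 1
    total = counts.sum(axis=0)
    labels = counts.argmax(axis=0).astype(np.uint8)   # ties -> lowest index
    nodata = total == 0
    labels[nodata] = 0
    return labels, nodata


def mean_probability_composite(collection: ImageCollection, start, end
                               ) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Per-pixel arithmetic mean of class probabilities over [start, end).

    Returns ``(mean_probs, top1, nodata)``; the mean of simplex points stays
    on the simplex, and top1 is its argmax (lowest index on ties).
    """
    images = collection.window(start, end)
    if not collection.images:
        raise AggregationError("empty collection")
    shape = collection.images[0].label.shape
    acc = np.zeros((N_CLASSES,) + shape, dtype=np.float64)
    n = np.zeros(shape, dtype=np.int32)
    for im in images:
        valid = im.valid
        acc[:, valid] += im.probabilities[:, valid]
        n[valid] += 1
    nodata = n == 0
    mean = np.divide(acc, n, out=np.zeros_like(acc), where=n > 0)
    top1 = mean.argmax(axis=0).astype(np.uint8)
    top1[nodata] = 0
    return mean, top1, nodata


def time_series_to_csv(series, path) -> None:
    """Write a pixel time series as CSV: time, one column per class
    probability, and the Top-1 label."""
    from pathlib import Path

    from .io_core import CLASS_NAMES
    lines = ["time," + ",".join(CLASS_NAMES) + ",label"]
    for t, probs, label in series:
        lines.append(f"{t}," + ",".join(f"{p:.6f}" for p in probs) + f",{label}")
    Path(path).write_text("\n".join(lines) + "\n")


def pixel_time_series(collection: ImageCollection, location: tuple[float, float]
                      ) -> list[tuple[object, np.ndarray, int]]:
    """Time-ordered (time, 9-vector, label) entries at a map location,
    omitting observations where the pixel is masked."""
    if not collection.images:
        return []
    ref = collection.images[0]
    x, y = location
    x0, y0 = ref.origin
    col = int(np.floor((x - x0) / ref.pixel_size))
    row = int(np.floor((y0 - y) / ref.pixel_size))
    nr, nc = ref.label.shape
    if not (0 <= row < nr and 0 <= col < nc):
        raise AggregationError(f"location {location} outside the collection extent")
    out = []
    for im in collection.images:
        if im.nodata[row, col]:
            continue
        out.append((im.metadata.get("system:time_start"),
                    im.probabilities[:, row, col].copy(),
                    int(im.label[row, col])))
    return out
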