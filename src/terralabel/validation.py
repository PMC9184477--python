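"""Multi-annotator consensus voting, confusion matrices, and agreement.

Three expert annotations per tile are fused per pixel under one of four
voting schemes; the fused reference is compared with a candidate labeling
(another annotator or a model product) via a confusion matrix whose rows are
the candidate and columns the reference, carrying precision (user's
accuracy) on rows and recall (producer's accuracy) on columns.  Class
merging supports crosswalks to coarser external taxonomies.
"""

from __future__ import annotations

from dataclasses import dataclass
from enum import Enum

import numpy as np

from .io_core import (N_ANNOTATION_CLASSES, RasterGrid, resample_nearest)

ABSENT = -1  #: sentinel for "no opinion" / unlabeled
INVALID = -2  #: sentinel for "no consensus under the scheme"


class ValidationError(ValueError):
    pass


class VotingScheme(str, Enum):
    """The four schemes for fusing three expert opinions at a pixel.

    * ``three_expert_strict`` — all three had an opinion and all agreed.
    * ``expert_consensus`` — every expert who had an opinion agreed (three
      agreeing, or two agreeing with one abstention, or a single opinion).
    * ``expert_majority`` — at least two agreed on a class, or exactly one
      had an opinion.
    * ``expert_simple_majority`` — at least two had an opinion and at least
      two agreed on a class.
    """

    three_expert_strict = "three_expert_strict"
    expert_consensus = "expert_consensus"
    expert_majority = "expert_majority"
    expert_simple_majority = "expert_simple_majority"


def vote_pixel(labels: tuple[int | None, int | None, int | None],
               scheme: VotingScheme) -> int:
    """Fuse three optional expert labels; returns the class or INVALID."""
    a, b, c = (ABSENT if v is None else int(v) for v in labels)
    arr = np.array([[a], [b], [c]])
    return int(consensus_votes(arr, scheme)[0])


def consensus_votes(labels: np.ndarray, scheme: VotingScheme) -> np.ndarray:
    """Vectorized voting over (3, N) label arrays with ABSENT = -1."""
    scheme = VotingScheme(scheme)
    a, b, c = labels[0], labels[1], labels[2]
    pa, pb, pc = a != ABSENT, b != ABSENT, c != ABSENT
    n_present = pa.astype(int) + pb.astype(int) + pc.astype(int)

    ab = pa & pb & (a == b)
    ac = pa & pc & (a == c)
    bc = pb & pc & (b == c)
    pair_label = np.where(ab | ac, a, np.where(bc, b, ABSENT))
    n_agree_pairs = ab | ac | bc            # at least two present agree
    all_three = pa & pb & pc & (a == b) & (b == c)

    single = np.where(pa, a, np.where(pb, b, c))  # label of the lone opinion

    out = np.full(a.shape, INVALID, dtype=np.int16)
    if scheme is VotingScheme.three_expert_strict:
        out[all_three] = a[all_three]
    elif scheme is VotingScheme.expert_consensus:
        # all present agree, at least one present
        two_agree_one_absent = (n_present == 2) & n_agree_pairs
        mask3 = all_three
        mask1 = n_present == 1
        out[mask3] = a[mask3]
        out[two_agree_one_absent] = pair_label[two_agree_one_absent]
        out[mask1] = single[mask1]
    elif scheme is VotingScheme.expert_majority:
        out[n_agree_pairs] = pair_label[n_agree_pairs]
        mask1 = n_present == 1
        out[mask1] = single[mask1]
    elif scheme is VotingScheme.expert_simple_majority:
        mask = (n_present >= 2) & n_agree_pairs
        out[mask] = pair_label[mask]
    return out


def consensus_grid(expert_rasters: list[RasterGrid | np.ndarray],
                   scheme: VotingScheme) -> np.ndarray:
    """Per-pixel voting over three aligned expert label grids (ABSENT = -1
    marks unlabeled pixels); returns a grid with INVALID where no consensus."""
    if len(expert_rasters) != 3:
        raise ValidationError("exactly three expert rasters required")
    arrs = [r.values if isinstance(r, RasterGrid) else np.asarray(r)
            for r in expert_rasters]
    shape = arrs[0].shape
    if any(a.shape != shape for a in arrs):
        raise ValidationError("expert rasters are misaligned")
    stacked = np.stack([a.ravel() for a in arrs])
    return consensus_votes(stacked, scheme).reshape(shape)


# ---------------------------------------------------------------------------

@dataclass
class ConfusionMatrix:
    """counts[candidate_class, reference_class] over jointly valid pixels."""

    counts: np.ndarray
    class_names: tuple[str, ...] | None = None

    def __post_init__(self) -> None:
        self.counts = np.asarray(self.counts)
        if self.counts.ndim != 2 or self.counts.shape[0] != self.counts.shape[1]:
            raise ValidationError("confusion matrix must be square")
        if np.any(self.counts < 0):
            raise ValidationError("confusion counts must be non-negative")

    @property
    def n_valid(self) -> int:
        return int(self.counts.sum())


@dataclass
class AgreementReport:
    overall: float
    precision: np.ndarray   # user's accuracy, per candidate row (nan if empty)
    recall: np.ndarray      # producer's accuracy, per reference column
    n_valid: int


def agreement_report(matrix: ConfusionMatrix) -> AgreementReport:
    counts = matrix.counts.astype(float)
    n = counts.sum()
    diag = np.diag(counts)
    row = counts.sum(axis=1)
    col = counts.sum(axis=0)
    with np.errstate(invalid="ignore", divide="ignore"):
        precision = np.where(row > 0, diag / row, np.nan)
        recall = np.where(col > 0, diag / col, np.nan)
    overall = float(diag.sum() / n) if n > 0 else float("nan")
    return AgreementReport(overall=overall, precision=precision, recall=recall,
                           n_valid=int(n))


def confusion(reference: RasterGrid | np.ndarray, candidate: RasterGrid | np.ndarray,
              n_classes: int = N_ANNOTATION_CLASSES,
              class_names: tuple[str, ...] | None = None) -> ConfusionMatrix:
    """Tally candidate vs reference over pixels valid in both grids (negative
    sentinel values mark invalid/absent pixels)."""
    ref = reference.values if isinstance(reference, RasterGrid) else np.asarray(reference)
    cand = candidate.values if isinstance(candidate, RasterGrid) else np.asarray(candidate)
    if ref.shape != cand.shape:
        raise ValidationError("reference and candidate grids are misaligned")
    valid = (ref >= 0) & (cand >= 0)
    if not valid.any():
        import warnings
        warnings.warn("zero jointly valid pixels; metrics are undefined")
        return ConfusionMatrix(np.zeros((n_classes, n_classes), dtype=np.int64),
                               class_names)
    idx = cand[valid].astype(np.int64) * n_classes + ref[valid].astype(np.int64)
    counts = np.bincount(idx, minlength=n_classes * n_classes)
    return ConfusionMatrix(counts.reshape(n_classes, n_classes), class_names)


def merge_classes_grid(grid: RasterGrid | np.ndarray, mapping: dict[int, int]
                       ) -> np.ndarray:
    """Relabel a grid under an old-class -> new-class mapping (total on the
    occurring classes; negative sentinels pass through)."""
    arr = grid.values if isinstance(grid, RasterGrid) else np.asarray(grid)
    out = arr.copy()
    present = np.unique(arr[arr >= 0])
    missing = [int(c) for c in present if int(c) not in mapping]
    if missing:
        raise ValidationError(f"mapping is missing classes {missing}")
    for old, new in mapping.items():
        out[arr == old] = new
    return out


def merge_classes_matrix(matrix: ConfusionMatrix, mapping: dict[int, int]
                         ) -> ConfusionMatrix:
    """Aggregate a confusion matrix under a class mapping; total preserved."""
    k_old = matrix.counts.shape[0]
    occurring = [c for c in range(k_old)
                 if matrix.counts[c].any() or matrix.counts[:, c].any()]
    missing = [c for c in occurring if c not in mapping]
    if missing:
        raise ValidationError(f"mapping is missing classes {missing}")
    full = {c: mapping.get(c, c) for c in range(k_old)}
    k_new = max(full.values()) + 1
    proj = np.zeros((k_old, k_new), dtype=matrix.counts.dtype)
    for old, new in full.items():
        proj[old, new] = 1
    return ConfusionMatrix(proj.T @ matrix.counts @ proj)


def build_validation_manifest(n_tiles: int = 409, n_experts: int = 3,
                              n_nonexperts: int = 1) -> list[tuple[str, str]]:
    """Enumerate the (tile, annotator-role) pairs of a validation campaign in
    which every held-out tile is labeled by ``n_experts`` experts and
    ``n_nonexperts`` non-experts (409 x 4 = 1,636 tile annotations at the
    defaults)."""
    manifest = []
    for i in range(n_tiles):
        tile = f"tile_{i:04d}"
        for e in range(n_experts):
            manifest.append((tile, f"expert_{e}"))
        for v in range(n_nonexperts):
            manifest.append((tile, f"non_expert_{v}"))
    return manifest


def compare_external(reference: RasterGrid, external: RasterGrid,
                     crosswalk: dict[int, int],
                     n_classes: int = N_ANNOTATION_CLASSES) -> AgreementReport:
    """Compare a 10 m reference labeling with a coarser external product:
    nearest-neighbour upsample to 10 m, crosswalk remap, then confusion."""
    up = resample_nearest(external, reference.pixel_size)
    if up.shape != reference.shape:
        raise ValidationError("external grid extent does not match the reference")
    remapped = merge_classes_grid(up, crosswalk)
    return agreement_report(confusion(reference, remapped, n_classes))
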