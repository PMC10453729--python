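"""Confusion-matrix substrate for binary segmentation evaluation.

Every metric in this package is a pure function of the four confusion
cells counted over a pixel/voxel grid: TP (foreground predicted
foreground), FP (background predicted foreground), FN (foreground
predicted background) and TN (background predicted background).  The
actual-positive count is P = TP + FN and the actual-negative count is
N = TN + FP; a *weak label* is a ground truth with P = 0 (no region of
interest present), the case this package exists to score sensibly.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np


class MaskShapeError(ValueError):
    """Raised when a mask pair cannot be compared (shape mismatch, empty grid)."""


@dataclass(frozen=True)
class BinaryMask:
    """An n-dimensional boolean foreground mask.

    ``data`` is coerced to a read-only boolean array; binarization of
    integer label images happens at load time (see :mod:`mism.mask_io`),
    never here.  A mask must contain at least one element — a
    zero-element grid has no pixels to classify and every metric on it
    would be 0/0.
    """

    data: np.ndarray

    def __post_init__(self) -> None:
        arr = np.asarray(self.data)
        if arr.dtype != np.bool_:
            if not np.isin(arr, (0, 1)).all():
                raise ValueError(
                    "BinaryMask requires boolean data; binarize label images "
                    "with a loading rule first"
                )
            arr = arr.astype(bool)
        if arr.size < 1:
            raise MaskShapeError("mask must contain at least one element")
        arr = arr.copy()
        arr.setflags(write=False)
        object.__setattr__(self, "data", arr)

    @property
    def shape(self) -> tuple[int, ...]:
        return self.data.shape

    @property
    def n_foreground(self) -> int:
        return int(np.count_nonzero(self.data))

    @property
    def size(self) -> int:
        return int(self.data.size)

    def complement(self) -> "BinaryMask":
        return BinaryMask(~self.data)

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, BinaryMask):
            return NotImplemented
        return self.shape == other.shape and bool(np.array_equal(self.data, other.data))

    def __hash__(self) -> int:  # frozen dataclass contract
        return hash((self.shape, self.data.tobytes()))


@dataclass(frozen=True)
class ConfusionCounts:
    """The four confusion cells for one ground-truth/prediction pair.

    Invariants enforced here: all cells non-negative, at least one
    positive (the grid is nonempty).  ``p`` and ``n`` are the derived
    actual-positive and actual-negative counts; ``p == 0`` identifies
    the weak-label case and forces ``tp == fn == 0``.
    """

    tp: int
    fp: int
    tn: int
    fn: int

    def __post_init__(self) -> None:
        for name in ("tp", "fp", "tn", "fn"):
            value = getattr(self, name)
            if value != int(value) or value < 0:
                raise ValueError(f"confusion cell {name}={value!r} must be a non-negative integer")
            object.__setattr__(self, name, int(value))
        if self.total == 0:
            raise ValueError("all confusion cells are zero: the image has no pixels")

    @property
    def p(self) -> int:
        """Actual positives: TP + FN."""
        return self.tp + self.fn

    @property
    def n(self) -> int:
        """Actual negatives: TN + FP."""
        return self.tn + self.fp

    @property
    def total(self) -> int:
        return self.tp + self.fp + self.tn + self.fn

    @property
    def is_weak_label(self) -> bool:
        return self.p == 0


def counts_from_cells(tp: int, fp: int, tn: int, fn: int) -> ConfusionCounts:
    """Build validated :class:`ConfusionCounts` directly from the four cells.

    Lets worked examples stated as counts be evaluated without
    constructing masks.  Negative cells and the all-zero vector (an
    empty image) are rejected.
    """
    return ConfusionCounts(tp=tp, fp=fp, tn=tn, fn=fn)


def compute_confusion(truth: BinaryMask, pred: BinaryMask) -> ConfusionCounts:
    """Count TP/FP/TN/FN between a ground-truth and a predicted mask.

    Both masks must share a shape; the counts always sum to the number
    of grid elements.  3-D volumes are handled identically to 2-D
    images — the cells are flat element counts with no anisotropy
    weighting, so orientation metadata is irrelevant here.
    """
    if truth.shape != pred.shape:
        raise MaskShapeError(
            f"mask shapes differ: truth {truth.shape} vs prediction {pred.shape}"
        )
    t = truth.data
    q = pred.data
    tp = int(np.count_nonzero(t & q))
    fp = int(np.count_nonzero(~t & q))
    fn = int(np.count_nonzero(t & ~q))
    tn = int(np.count_nonzero(~t & ~q))
    return ConfusionCounts(tp=tp, fp=fp, tn=tn, fn=fn)
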