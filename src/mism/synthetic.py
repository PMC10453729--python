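"""Synthetic mask pairs emulating tumor/no-tumor evaluation scenarios.

Ground truths are filled disks (balls in 3-D) standing in for annotated
lesions, or all-background masks standing in for control images with no
region of interest (weak labels).  Predictions are derived from the
truth by simple perturbation operators — morphological dilation and
erosion, translation, spurious blobs at seeded random locations,
inversion, and the two degenerate predictions (all-empty, all-
foreground) — chosen to span the qualitative range from perfect overlap
to complete failure on both normal and weak-label images.

Rasterization rule: a pixel is foreground iff its center lies within
Euclidean distance ``radius`` of the lesion center.  Everything is
deterministic given the spec (including its seed).
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from typing import Iterator

import numpy as np
from scipy import ndimage

from .confusion import BinaryMask

PERTURBATIONS = (
    "none",
    "dilate",
    "erode",
    "shift",
    "spurious_blob",
    "invert",
    "empty_prediction",
    "full_false_positive",
)


@dataclass(frozen=True)
class Lesion:
    """A disk/ball blob: center coordinates and radius in pixels."""

    center: tuple[int, ...]
    radius: int


@dataclass(frozen=True)
class ScenarioSpec:
    """One evaluation scenario: a ground truth and how to corrupt it.

    ``lesion is None`` marks a weak-label scenario (P = 0 in the
    truth).  ``magnitude`` is the perturbation size in pixels —
    iterations for dilate/erode, offset for shift, blob radius for
    spurious_blob; ignored by the parameter-free perturbations.
    """

    name: str
    image_shape: tuple[int, ...] = (64, 64)
    lesion: Lesion | None = None
    perturbation: str = "none"
    magnitude: int = 0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.perturbation not in PERTURBATIONS:
            raise ValueError(
                f"unknown perturbation {self.perturbation!r}; "
                f"choose from {', '.join(PERTURBATIONS)}"
            )
        if self.magnitude < 0:
            raise ValueError("perturbation magnitude must be >= 0")
        if any(s < 1 for s in self.image_shape):
            raise ValueError(f"invalid image shape {self.image_shape}")


def _ball(shape: tuple[int, ...], center: tuple[int, ...], radius: int) -> np.ndarray:
    grids = np.ogrid[tuple(slice(0, s) for s in shape)]
    dist2 = sum((g - c) ** 2 for g, c in zip(grids, center))
    return dist2 <= radius * radius


def make_truth(spec: ScenarioSpec) -> BinaryMask:
    """Render the ground truth: a filled disk/ball, or all-background.

    A lesion must fit entirely inside the image; a radius-0 lesion is a
    single foreground pixel.
    """
    if spec.lesion is None:
        return BinaryMask(np.zeros(spec.image_shape, dtype=bool))
    center, radius = spec.lesion.center, spec.lesion.radius
    if len(center) != len(spec.image_shape):
        raise ValueError(
            f"lesion center {center} does not match image dimensionality "
            f"{len(spec.image_shape)}"
        )
    for c, s in zip(center, spec.image_shape):
        if c - radius < 0 or c + radius > s - 1:
            raise ValueError(
                f"lesion (center={center}, radius={radius}) overflows image {spec.image_shape}"
            )
    return BinaryMask(_ball(spec.image_shape, center, radius))


def _shift_no_wrap(data: np.ndarray, offset: int) -> np.ndarray:
    """Translate along axis 0; pixels leaving the image are dropped."""
    out = np.zeros_like(data)
    if offset == 0:
        return data.copy()
    if offset >= data.shape[0]:
        return out
    out[offset:] = data[:-offset]
    return out


def _place_spurious_blob(truth: np.ndarray, radius: int, rng: np.random.Generator) -> np.ndarray:
    shape = truth.shape
    for s in shape:
        if 2 * radius + 1 > s:
            raise ValueError(f"spurious blob of radius {radius} does not fit in image {shape}")
    # Prefer a location whose blob is disjoint from the true foreground so
    # the perturbation adds pure false positives; fall back after 100 draws.
    blob = np.zeros_like(truth)
    for _ in range(100):
        center = tuple(int(rng.integers(radius, s - radius)) for s in shape)
        blob = _ball(shape, center, radius)
        if not (blob & truth).any():
            break
    return truth | blob


def make_prediction(truth: BinaryMask, spec: ScenarioSpec) -> BinaryMask:
    """Derive the predicted mask from the truth per the scenario's perturbation."""
    data = truth.data
    kind = spec.perturbation
    if kind == "none":
        out = data.copy()
    elif kind == "dilate":
        out = ndimage.binary_dilation(data, iterations=max(spec.magnitude, 1)) \
            if spec.magnitude > 0 else data.copy()
    elif kind == "erode":
        out = ndimage.binary_erosion(data, iterations=spec.magnitude) \
            if spec.magnitude > 0 else data.copy()
    elif kind == "shift":
        out = _shift_no_wrap(data, spec.magnitude)
    elif kind == "spurious_blob":
        rng = np.random.default_rng(spec.seed)
        out = _place_spurious_blob(data, spec.magnitude, rng)
    elif kind == "invert":
        out = ~data
    elif kind == "empty_prediction":
        out = np.zeros_like(data)
    elif kind == "full_false_positive":
        out = np.ones_like(data)
    else:  # pragma: no cover - guarded by ScenarioSpec validation
        raise ValueError(f"unknown perturbation {kind!r}")
    return BinaryMask(out)


def default_scenarios(seed: int = 42, image_shape: tuple[int, ...] = (64, 64)) -> list[ScenarioSpec]:
    """The standard scenario family: normal cases (P > 0) and weak-label edge cases."""
    center = tuple(s // 2 for s in image_shape)
    lesion = Lesion(center=center, radius=10)
    base = dict(image_shape=image_shape, lesion=lesion)
    return [
        ScenarioSpec(name="perfect", perturbation="none", seed=seed, **base),
        ScenarioSpec(name="under-segmentation", perturbation="erode", magnitude=3,
                     seed=seed + 1, **base),
        ScenarioSpec(name="over-segmentation", perturbation="dilate", magnitude=3,
                     seed=seed + 2, **base),
        ScenarioSpec(name="shifted", perturbation="shift", magnitude=8,
                     seed=seed + 3, **base),
        ScenarioSpec(name="inverted", perturbation="invert", seed=seed + 4, **base),
        ScenarioSpec(name="missed-lesion", perturbation="empty_prediction",
                     seed=seed + 5, **base),
        ScenarioSpec(name="weak-label-perfect", image_shape=image_shape, lesion=None,
                     perturbation="none", seed=seed + 6),
        ScenarioSpec(name="weak-label-small-fp", image_shape=image_shape, lesion=None,
                     perturbation="spurious_blob", magnitude=4, seed=seed + 7),
        ScenarioSpec(name="weak-label-large-fp", image_shape=image_shape, lesion=None,
                     perturbation="spurious_blob", magnitude=20, seed=seed + 8),
        ScenarioSpec(name="weak-label-all-fp", image_shape=image_shape, lesion=None,
                     perturbation="full_false_positive", seed=seed + 9),
    ]


def scenario_suite(
    seed: int = 42, image_shape: tuple[int, ...] = (64, 64)
) -> Iterator[tuple[str, BinaryMask, BinaryMask]]:
    """Yield (name, truth, prediction) for the deterministic default suite."""
    for spec in default_scenarios(seed=seed, image_shape=image_shape):
        truth = make_truth(spec)
        yield spec.name, truth, make_prediction(truth, spec)
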