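"""Segmentation metrics over confusion counts, with an explicit undefined state.

The central metric is MISm, a piecewise composition::

    MISm(alpha) = DSC                 if P > 0
                = wSpec(alpha)        if P = 0  (weak label)

where DSC = 2TP/(2TP+FP+FN) and wSpec(alpha) = alpha*TN / ((1-alpha)*FP
+ alpha*TN).  DSC is undefined exactly when TP = FP = FN = 0 (a
completely true-negative prediction) and specificity is undefined
exactly when TN = FP = 0; MISm is defined for every nonempty image
because the P > 0 branch has denominator >= 2P > 0 and the P = 0 branch
has fp + tn = N = total > 0.

Undefined values are a first-class result state (``MetricResult.value
is None``), never an exception and never silently zero: collapsing an
undefined DSC to zero is precisely the weak-label scoring artifact the
composite metric is designed to avoid.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Callable

from .confusion import BinaryMask, ConfusionCounts, compute_confusion

#: Serialized spelling of the undefined state in reports and tables.
UNDEFINED_LABEL = "undefined"

#: Community-default weighting coefficient for wSpec / MISm.
DEFAULT_ALPHA = 0.1


@dataclass(frozen=True)
class MetricConfig:
    """Evaluation parameters.

    ``alpha`` weights TN against FP in the weighted specificity.  It
    must lie strictly inside (0, 1): alpha = 0 makes wSpec 0/0 whenever
    FP = 0, and alpha = 1 pins wSpec at 1 whenever TN > 0, destroying
    the scoring gradient in either case.  The default 0.1 down-weights
    the (typically dominant) true-negative count so that false
    positives on weak labels are penalized meaningfully.
    """

    alpha: float = DEFAULT_ALPHA
    tolerance: float = 5e-5

    def __post_init__(self) -> None:
        if not (0.0 < self.alpha < 1.0):
            raise ValueError(
                f"alpha={self.alpha} is outside the open interval (0, 1); "
                "the endpoints degenerate the weighted specificity"
            )


@dataclass(frozen=True)
class MetricResult:
    """One metric value for one mask pair.

    ``value`` is a float in [0, 1] or ``None`` when the metric's
    denominator vanishes for these counts.  ``alpha_used`` is set only
    for the alpha-parameterized metrics (wSpec, MISm).
    """

    name: str
    value: float | None
    counts: ConfusionCounts
    alpha_used: float | None = None

    @property
    def defined(self) -> bool:
        return self.value is not None

    def __str__(self) -> str:
        shown = UNDEFINED_LABEL if self.value is None else f"{self.value:.6f}"
        return f"{self.name}={shown}"


def dsc(c: ConfusionCounts) -> MetricResult:
    """Dice similarity coefficient (F1): 2TP/(2TP+FP+FN).

    Undefined iff TP = FP = FN = 0, i.e. the ground truth is a weak
    label and the prediction is perfectly empty.
    """
    denom = 2 * c.tp + c.fp + c.fn
    value = None if denom == 0 else 2 * c.tp / denom
    return MetricResult("DSC", value, c)


def fpr(c: ConfusionCounts) -> MetricResult:
    """False positive rate (fall-out): FP/(FP+TN); undefined when N = 0."""
    value = None if c.n == 0 else c.fp / c.n
    return MetricResult("FPR", value, c)


def specificity(c: ConfusionCounts) -> MetricResult:
    """Specificity (true negative rate): TN/(FP+TN) = 1 - FPR.

    Undefined iff TN = FP = 0 (no actual negatives in the image).
    """
    value = None if c.n == 0 else c.tn / c.n
    return MetricResult("Spec", value, c)


def weighted_specificity(c: ConfusionCounts, cfg: MetricConfig | None = None) -> MetricResult:
    """Weighted specificity: alpha*TN / ((1-alpha)*FP + alpha*TN).

    alpha < 0.5 shifts weight from the dominant TN count onto FP so
    that false positives on class-imbalanced images cost score; at
    alpha = 0.5 the weights cancel and wSpec reduces to specificity.
    Undefined iff TN = FP = 0, exactly as specificity.
    """
    cfg = cfg or MetricConfig()
    a = cfg.alpha
    denom = (1.0 - a) * c.fp + a * c.tn
    value = None if denom == 0.0 else a * c.tn / denom
    return MetricResult("wSpec", value, c, alpha_used=a)


def mism(c: ConfusionCounts, cfg: MetricConfig | None = None) -> MetricResult:
    """The composite metric: DSC when P > 0, weighted specificity when P = 0.

    Total on every nonempty image — the two branches cover each
    other's definition gaps.  The P > 0 branch reuses :func:`dsc`'s
    arithmetic path bit-for-bit.
    """
    cfg = cfg or MetricConfig()
    if c.p > 0:
        value = dsc(c).value
    else:
        value = weighted_specificity(c, cfg).value
    assert value is not None  # totality: guaranteed by nonempty-image invariant
    return MetricResult("MISm", value, c, alpha_used=cfg.alpha)


def accuracy(c: ConfusionCounts) -> MetricResult:
    """Accuracy: (TP+TN)/total; always defined on a nonempty image."""
    return MetricResult("Acc", (c.tp + c.tn) / c.total, c)


def mcc(c: ConfusionCounts) -> float:
    """Matthews correlation coefficient in [-1, 1].

    Convention: when any marginal (TP+FP, TP+FN, TN+FP, TN+FN) is zero
    the denominator vanishes and MCC is taken as 0, the value for a
    prediction uncorrelated with the truth.
    """
    denom = (c.tp + c.fp) * (c.tp + c.fn) * (c.tn + c.fp) * (c.tn + c.fn)
    if denom == 0:
        return 0.0
    return (c.tp * c.tn - c.fp * c.fn) / math.sqrt(denom)


def nmcc(c: ConfusionCounts) -> MetricResult:
    """Normalized Matthews correlation coefficient: (MCC+1)/2 in [0, 1].

    1 is a perfect prediction, 0 an exactly inverted annotation, and
    0.5 a prediction uncorrelated with the truth — which, under the
    MCC := 0 convention, is also the value every weak-label prediction
    receives regardless of its false-positive load.
    """
    return MetricResult("nMCC", (mcc(c) + 1.0) / 2.0, c)


#: Registry of metric labels -> callables taking (counts, cfg).
METRIC_REGISTRY: dict[str, Callable[[ConfusionCounts, MetricConfig], MetricResult]] = {
    "DSC": lambda c, cfg: dsc(c),
    "Spec": lambda c, cfg: specificity(c),
    "wSpec": weighted_specificity,
    "FPR": lambda c, cfg: fpr(c),
    "Acc": lambda c, cfg: accuracy(c),
    "nMCC": lambda c, cfg: nmcc(c),
    "MISm": mism,
}

#: Lower-case aliases accepted on the command line.
METRIC_ALIASES = {name.lower(): name for name in METRIC_REGISTRY}


def resolve_metric_names(names: list[str] | None) -> list[str]:
    """Map user-supplied labels (case-insensitive) onto registry keys."""
    if not names:
        return list(METRIC_REGISTRY)
    resolved = []
    for name in names:
        key = METRIC_ALIASES.get(name.strip().lower())
        if key is None:
            raise ValueError(
                f"unknown metric {name!r}; choose from {', '.join(METRIC_REGISTRY)}"
            )
        resolved.append(key)
    return resolved


def evaluate_counts(
    c: ConfusionCounts,
    cfg: MetricConfig | None = None,
    metrics: list[str] | None = None,
) -> list[MetricResult]:
    """Evaluate a selection of metrics on one shared set of counts."""
    cfg = cfg or MetricConfig()
    return [METRIC_REGISTRY[name](c, cfg) for name in resolve_metric_names(metrics)]


def evaluate_all(
    truth: BinaryMask,
    pred: BinaryMask,
    cfg: MetricConfig | None = None,
    metrics: list[str] | None = None,
) -> list[MetricResult]:
    """Compute every requested metric for one mask pair from a single confusion matrix."""
    return evaluate_counts(compute_confusion(truth, pred), cfg, metrics)
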