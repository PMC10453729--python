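"""Dataset-level evaluation reports: per-image metric values plus aggregates."""

from __future__ import annotations

from dataclasses import dataclass, field

from .confusion import ConfusionCounts
from .metrics import METRIC_REGISTRY, MetricConfig, MetricResult


@dataclass(frozen=True)
class MetricAggregate:
    """Aggregate of one metric over a dataset.

    ``value`` is the macro mean over images where the metric is
    defined (or the pooled-count micro value); undefined per-image
    values are excluded from the mean and counted separately — imputing
    them as zero would reintroduce the weak-label artifact of scoring
    correct empty predictions as failures.
    """

    metric: str
    value: float | None
    n_defined: int
    n_undefined: int


@dataclass
class EvaluationReport:
    """Per-image and aggregated metric values for a dataset of mask pairs."""

    per_image: list[tuple[str, list[MetricResult]]]
    aggregates: dict[str, MetricAggregate]
    alpha: float
    aggregate_mode: str = "macro"

    @property
    def n_images(self) -> int:
        return len(self.per_image)

    @property
    def metric_names(self) -> list[str]:
        if not self.per_image:
            return []
        return [r.name for r in self.per_image[0][1]]


def build_report(
    per_image: list[tuple[str, list[MetricResult]]],
    cfg: MetricConfig,
    aggregate: str = "macro",
) -> EvaluationReport:
    """Assemble a report from per-image results.

    ``aggregate`` is "macro" (mean of per-image values, over images
    where the metric is defined) or "micro" (pool the confusion counts
    of all images, then evaluate each metric once on the pooled
    counts).  Macro is the default: pooling lets a few large-lesion
    images swamp weak-label failures, which is exactly the effect a
    weak-label-aware evaluation should expose, not hide.
    """
    if not per_image:
        raise ValueError("cannot build a report from zero images")
    if aggregate not in ("macro", "micro"):
        raise ValueError(f"unknown aggregation mode {aggregate!r}")
    names = [r.name for r in per_image[0][1]]
    for image_id, results in per_image:
        if [r.name for r in results] != names:
            raise ValueError(f"image {image_id!r} has a different metric set")

    aggregates: dict[str, MetricAggregate] = {}
    for j, name in enumerate(names):
        values = [results[j].value for _, results in per_image]
        defined = [v for v in values if v is not None]
        n_undef = len(values) - len(defined)
        if aggregate == "macro":
            agg_value = sum(defined) / len(defined) if defined else None
        else:
            pooled = ConfusionCounts(
                tp=sum(results[j].counts.tp for _, results in per_image),
                fp=sum(results[j].counts.fp for _, results in per_image),
                tn=sum(results[j].counts.tn for _, results in per_image),
                fn=sum(results[j].counts.fn for _, results in per_image),
            )
            agg_value = METRIC_REGISTRY[name](pooled, cfg).value
        aggregates[name] = MetricAggregate(name, agg_value, len(defined), n_undef)
    return EvaluationReport(
        per_image=per_image, aggregates=aggregates, alpha=cfg.alpha,
        aggregate_mode=aggregate,
    )
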