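"""Scoring-gradient sweep for the weak-label edge case.

Holds the total pixel count N fixed with P = 0 and sweeps the
false-positive load from fp = 0 to fp = N, evaluating each metric at
every grid point.  This exposes how each metric grades a weak-label
prediction as its error grows: MISm(alpha) falls smoothly from 1 to 0
(faster for smaller alpha), accuracy falls linearly, DSC is pinned at 0
for any fp > 0 (and undefined at fp = 0), and nMCC sits at 0.5
throughout under the MCC := 0 convention.

In closed form, with r = fp/N the MISm curve is
``alpha*(1-r) / ((1-alpha)*r + alpha*(1-r))`` — the independent oracle
used in the tests.
"""

from __future__ import annotations

import csv
import logging
import math
from dataclasses import dataclass, field
from pathlib import Path

from .confusion import ConfusionCounts
from .metrics import UNDEFINED_LABEL, METRIC_REGISTRY, MetricConfig

logger = logging.getLogger(__name__)

#: Default total pixel count for the sweep (a 200x300 image's worth).
DEFAULT_N_PIXELS = 60_000

#: Default fan of weighting coefficients; 0.1 is the proposed community default.
DEFAULT_ALPHAS = (0.05, 0.1, 0.25, 0.5, 0.75)

#: Comparator metrics shown next to the MISm(alpha) curves.
DEFAULT_COMPARATORS = ("DSC", "Acc", "nMCC")


def mism_label(alpha: float) -> str:
    return f"MISm(α={alpha:g})"


@dataclass
class ScoreTable:
    """Metric scores across a grid of FP/N ratios (P = 0 throughout).

    ``ratios`` is the requested grid; ``realized_ratios`` the grid
    actually achieved after rounding fp to an integer count.  ``scores``
    maps metric labels (including the ``MISm(α=x)`` variants) to value
    lists aligned with the grid; ``None`` marks an undefined value.
    """

    ratios: list[float]
    n_pixels: int
    scores: dict[str, list[float | None]]
    realized_ratios: list[float] = field(default_factory=list)

    def __post_init__(self) -> None:
        for label, column in self.scores.items():
            if len(column) != len(self.ratios):
                raise ValueError(
                    f"column {label!r} has {len(column)} values for {len(self.ratios)} ratios"
                )


def sweep(
    n_pixels: int = DEFAULT_N_PIXELS,
    ratios: list[float] | None = None,
    alphas: list[float] | None = None,
    metrics: list[str] | None = None,
) -> ScoreTable:
    """Evaluate metrics over the weak-label grid (tp = fn = 0, fp = round(r*N)).

    Rounding is half-up so that integer counts are exact; the realized
    ratio fp/N is recorded alongside the requested one.
    """
    if n_pixels < 1:
        raise ValueError("n_pixels must be >= 1")
    if ratios is None:
        ratios = [i / 100 for i in range(101)]
    if alphas is None:
        alphas = list(DEFAULT_ALPHAS)
    if metrics is None:
        metrics = list(DEFAULT_COMPARATORS)
    for r in ratios:
        if not (0.0 <= r <= 1.0):
            raise ValueError(f"ratio {r} outside [0, 1]")
    configs = [MetricConfig(alpha=a) for a in alphas]  # validates alphas
    for name in metrics:
        if name not in METRIC_REGISTRY:
            raise ValueError(f"unknown metric {name!r}")

    labels = [mism_label(a) for a in alphas] + list(metrics)
    columns: dict[str, list[float | None]] = {label: [] for label in labels}
    realized = []
    for r in ratios:
        fp = math.floor(r * n_pixels + 0.5)  # half-up
        counts = ConfusionCounts(tp=0, fp=fp, tn=n_pixels - fp, fn=0)
        realized.append(fp / n_pixels)
        for cfg in configs:
            columns[mism_label(cfg.alpha)].append(
                METRIC_REGISTRY["MISm"](counts, cfg).value
            )
        for name in metrics:
            columns[name].append(METRIC_REGISTRY[name](counts, configs[0]).value)
    return ScoreTable(ratios=list(ratios), n_pixels=n_pixels, scores=columns,
                      realized_ratios=realized)


def write_sweep_csv(table: ScoreTable, path: str | Path) -> Path:
    """Serialize a ScoreTable as CSV; undefined cells spelled "undefined"."""
    path = Path(path)
    with path.open("w", newline="", encoding="utf-8") as fh:
        writer = csv.writer(fh)
        labels = list(table.scores)
        writer.writerow(["ratio", "realized_ratio", *labels])
        realized = table.realized_ratios or table.ratios
        for i, (r, rr) in enumerate(zip(table.ratios, realized)):
            row = [f"{r:.6f}", f"{rr:.6f}"]
            for label in labels:
                v = table.scores[label][i]
                row.append(UNDEFINED_LABEL if v is None else f"{v:.6f}")
            writer.writerow(row)
    return path


def render_sweep(table: ScoreTable, out_path: str | Path) -> Path:
    """Line plot of score vs FP/N ratio, one series per metric label.

    Undefined points are omitted; a series that is undefined everywhere
    is dropped with a warning.  The output format follows the file
    extension (PNG or SVG).
    """
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    if not table.ratios:
        raise ValueError("cannot render an empty score table")
    out_path = Path(out_path)
    fig, ax = plt.subplots(figsize=(7, 4.5))
    x_axis = table.realized_ratios or table.ratios
    for label, column in table.scores.items():
        xs = [x for x, v in zip(x_axis, column) if v is not None]
        ys = [v for v in column if v is not None]
        if not ys:
            logger.warning("series %r is undefined at every grid point; omitted", label)
            continue
        ax.plot(xs, ys, marker="" if len(ys) > 1 else "o", label=label)
    ax.set_xlabel("false positives / actual negatives (FP/N)")
    ax.set_ylabel("score")
    ax.set_title("Metric scoring gradient on weak labels (P = 0)")
    ax.set_ylim(-0.02, 1.02)
    ax.legend(fontsize=8)
    fig.tight_layout()
    fig.savefig(out_path)
    plt.close(fig)
    return out_path
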