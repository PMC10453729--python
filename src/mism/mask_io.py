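"""Reading and writing segmentation masks (PNG, NIfTI) and evaluation reports.

PNG covers 2-D slices; NIfTI-1 (.nii / .nii.gz) covers 2-D and 3-D
volumes.  Pixel data are binarized at load time: by default any nonzero
value is foreground, or a single label value can be selected
(``label:K``).  Metric computation ignores NIfTI orientation metadata —
confusion counts are orientation-invariant — but the affine is carried
through on write.
"""

from __future__ import annotations

import csv
import json
from dataclasses import dataclass
from pathlib import Path

import imageio.v3 as iio
import nibabel as nib
import numpy as np

from .confusion import BinaryMask
from .metrics import UNDEFINED_LABEL
from .report import EvaluationReport

PNG_SUFFIXES = {".png"}
NIFTI_SUFFIXES = {".nii", ".nii.gz"}


class MaskIOError(ValueError):
    """Raised when a mask file cannot be read or written as requested."""


def _format_of(path: Path) -> str:
    name = path.name.lower()
    if name.endswith(".nii.gz") or name.endswith(".nii"):
        return "nifti"
    if name.endswith(".png"):
        return "png"
    raise MaskIOError(f"{path}: unsupported mask format (expected .png, .nii or .nii.gz)")


@dataclass(frozen=True)
class MaskFileRecord:
    """A mask file on disk plus its binarization rule.

    ``binarization_rule`` is "nonzero" (default) or "label:K" to select
    a single integer label as foreground.
    """

    path: Path
    binarization_rule: str = "nonzero"

    @property
    def format(self) -> str:
        return _format_of(Path(self.path))


def binarize(arr: np.ndarray, rule: str = "nonzero") -> np.ndarray:
    """Apply a binarization rule to raw pixel data."""
    if rule == "nonzero":
        return arr != 0
    if rule.startswith("label:"):
        try:
            label = int(rule.split(":", 1)[1])
        except ValueError as exc:
            raise MaskIOError(f"bad binarization rule {rule!r}") from exc
        return arr == label
    raise MaskIOError(f"bad binarization rule {rule!r} (use 'nonzero' or 'label:K')")


def load_mask(record: MaskFileRecord | str | Path, rule: str | None = None) -> BinaryMask:
    """Load a mask file and binarize it.

    Accepts a :class:`MaskFileRecord` or a bare path (with an optional
    ``rule`` override).  RGB(A) PNGs are accepted only when all color
    channels are identical.
    """
    if not isinstance(record, MaskFileRecord):
        record = MaskFileRecord(path=Path(record), binarization_rule=rule or "nonzero")
    path = Path(record.path)
    fmt = record.format
    if not path.exists():
        raise MaskIOError(f"{path}: file not found")
    try:
        if fmt == "png":
            arr = np.asarray(iio.imread(path))
        else:
            arr = np.asanyarray(nib.load(str(path)).dataobj)
    except MaskIOError:
        raise
    except Exception as exc:
        raise MaskIOError(f"{path}: cannot be parsed as {fmt}: {exc}") from exc
    if fmt == "png" and arr.ndim == 3:
        rgb = arr[..., :3]
        if not (rgb == rgb[..., :1]).all():
            raise MaskIOError(f"{path}: RGB image with non-identical channels is not a mask")
        arr = rgb[..., 0]
    return BinaryMask(binarize(arr, record.binarization_rule))


def save_mask(mask: BinaryMask, path: str | Path) -> Path:
    """Write a mask to PNG (2-D only) or NIfTI; round-trips exactly via load_mask."""
    path = Path(path)
    fmt = _format_of(path)
    if fmt == "png":
        if mask.data.ndim != 2:
            raise MaskIOError(f"{path}: PNG can only hold 2-D masks, got shape {mask.shape}")
        iio.imwrite(path, (mask.data.astype(np.uint8) * 255))
    else:
        img = nib.Nifti1Image(mask.data.astype(np.uint8), affine=np.eye(4))
        nib.save(img, str(path))
    return path


def _fmt(value: float | None) -> str:
    return UNDEFINED_LABEL if value is None else f"{value:.6f}"


def write_report(report: EvaluationReport, path: str | Path) -> Path:
    """Serialize an evaluation report as CSV or JSON (by extension).

    CSV layout: one detail row per (image, metric), then one aggregate
    row per metric carrying the mean over defined values and the
    defined/undefined counts.  Floats use 6 decimals; undefined values
    are the literal string "undefined".
    """
    path = Path(path)
    if report.n_images == 0:
        raise ValueError("refusing to write an empty report")
    if path.suffix.lower() == ".json":
        payload = {
            "alpha": report.alpha,
            "aggregate_mode": report.aggregate_mode,
            "n_images": report.n_images,
            "per_image": {
                image_id: {r.name: _fmt(r.value) for r in results}
                for image_id, results in report.per_image
            },
            "aggregates": {
                name: {
                    "value": _fmt(agg.value),
                    "n_defined": agg.n_defined,
                    "n_undefined": agg.n_undefined,
                }
                for name, agg in report.aggregates.items()
            },
        }
        path.write_text(json.dumps(payload, indent=2, ensure_ascii=False) + "\n",
                        encoding="utf-8")
        return path
    with path.open("w", newline="", encoding="utf-8") as fh:
        writer = csv.writer(fh)
        writer.writerow(["image", "metric", "value", "n_defined", "n_undefined"])
        for image_id, results in report.per_image:
            for r in results:
                writer.writerow([image_id, r.name, _fmt(r.value), "", ""])
        for name, agg in report.aggregates.items():
            writer.writerow([
                f"aggregate({report.aggregate_mode})", name, _fmt(agg.value),
                agg.n_defined, agg.n_undefined,
            ])
    return path


def export_scenario_suite(out_dir: str | Path, seed: int = 42,
                          image_shape: tuple[int, ...] = (64, 64)) -> Path:
    """Write the synthetic scenario suite as ``<name>/truth.png`` + ``<name>/pred.png``."""
    from .synthetic import scenario_suite

    out_dir = Path(out_dir)
    truth_dir = out_dir / "truth"
    pred_dir = out_dir / "pred"
    truth_dir.mkdir(parents=True, exist_ok=True)
    pred_dir.mkdir(parents=True, exist_ok=True)
    for name, truth, pred in scenario_suite(seed=seed, image_shape=image_shape):
        save_mask(truth, truth_dir / f"{name}.png")
        save_mask(pred, pred_dir / f"{name}.png")
    return out_dir
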