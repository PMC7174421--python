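"""File I/O: TIFF stacks, 16-bit label masks, ROI JSON, manifest YAML.

All stacks are written as float32 TIFF (lossless round-trip), masks as
uint16 TIFF. ROI documents follow the schema::

    {"rois": [{"role": "filopodium|cut_line|kymograph_line",
               "owner": int | null,
               "vertices": [[x, y], ...]}, ...]}
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import tifffile
import yaml

from .model import Calibration, ImageStack, LabelMask, Polyline, ValidationError


def read_stack(path, calibration: Calibration, channel_name: str = "") -> ImageStack:
    """Read a 1+ frame TIFF into a float :class:`ImageStack`.

    Frames keep file order; intensities are cast to float with no
    rescaling; the calibration is attached unchanged.
    """
    try:
        arr = tifffile.imread(str(path))
    except (FileNotFoundError, IsADirectoryError):
        raise
    except Exception as exc:  # corrupt / non-TIFF
        raise ValidationError(f"cannot read TIFF {path}: {exc}") from exc
    arr = np.asarray(arr)
    if arr.ndim not in (2, 3):
        raise ValidationError(
            f"{path}: expected 1+ single-channel frames, got shape {arr.shape}")
    return ImageStack(arr.astype(np.float64), calibration, channel_name)


def write_stack(stack: ImageStack, path) -> Path:
    """Write a stack as float32 TIFF, lossless for float32 data."""
    path = Path(path)
    tifffile.imwrite(str(path), stack.data.astype(np.float32),
                     photometric="minisblack")
    return path


def read_mask(path, clone_labels=()) -> LabelMask:
    arr = tifffile.imread(str(path))
    return LabelMask(np.asarray(arr), frozenset(int(c) for c in clone_labels))


def write_mask(mask: LabelMask, path) -> Path:
    path = Path(path)
    if mask.labels.max(initial=0) > np.iinfo(np.uint16).max:
        raise ValidationError("labels exceed 16-bit range")
    tifffile.imwrite(str(path), mask.labels.astype(np.uint16))
    return path


def read_rois(path) -> list[Polyline]:
    """Read an ROI JSON document into a list of :class:`Polyline`."""
    with open(path) as fh:
        doc = json.load(fh)
    if not isinstance(doc, dict) or "rois" not in doc:
        raise ValidationError(f"{path}: missing top-level 'rois' key")
    return [Polyline.from_dict(d) for d in doc["rois"]]


def write_rois(polylines, path) -> Path:
    path = Path(path)
    with open(path, "w") as fh:
        json.dump({"rois": [p.to_dict() for p in polylines]}, fh, indent=1)
    return path


def read_yaml(path) -> dict:
    with open(path) as fh:
        return yaml.safe_load(fh)


def write_yaml(obj: dict, path) -> Path:
    path = Path(path)
    with open(path, "w") as fh:
        yaml.safe_dump(obj, fh, sort_keys=True)
    return path
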