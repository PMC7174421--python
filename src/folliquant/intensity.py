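"""Intensity quantification: background subtraction, photobleaching
correction, per-cell means, central/lateral partitioning and
clone-relative intensity.

The central/lateral partition splits each cell along the tissue AP axis
into a medio-basal band (the middle half of the AP extent) and two
lateral quarter-bands abutting the anterior and posterior junctional
membranes. Ratios are computed on mean-per-pixel intensity so that
region-area differences cancel.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
from scipy import ndimage, stats

from .model import (Calibration, ImageStack, LabelMask, ValidationError,
                    axis_unit_vectors)


@dataclass
class RegionPartition:
    """Central / lateral pixel masks of one cell (they tile the cell)."""

    label: int
    central_mask: np.ndarray
    lateral_mask: np.ndarray

    def __post_init__(self) -> None:
        if (self.central_mask & self.lateral_mask).any():
            raise ValidationError("central and lateral masks overlap")


@dataclass
class BleachFit:
    """Exponential photobleaching fit of the whole-field mean."""

    tau: float            # seconds; inf when no decay was detected
    amplitude: float
    corrected: bool       # False = fell back to no correction


def subtract_background(stack: ImageStack, bg_mask: np.ndarray) -> ImageStack:
    """Subtract the per-frame scalar mean of the background region.

    ``bg_mask`` is a boolean image (True = area without sample), e.g.
    ``mask.labels == 0``. Negative results are clamped to zero.
    """
    bg = np.asarray(bg_mask, dtype=bool)
    if bg.shape != stack.shape[1:]:
        raise ValidationError("background mask shape mismatch")
    if not bg.any():
        raise ValidationError("empty background region")
    offs = stack.data[:, bg].mean(axis=1)
    out = np.clip(stack.data - offs[:, None, None], 0, None)
    return stack.with_data(out)


def correct_bleaching(stack: ImageStack, min_frames: int = 5
                      ) -> tuple[ImageStack, BleachFit]:
    """Divide out an exponential fit ``A exp(-t/tau)`` of the whole-field
    mean intensity (least squares on log intensity).

    A non-decaying or non-finite fit falls back to no correction with
    ``corrected=False``. The field-level fit is robust to individual
    oscillating cells.
    """
    if stack.n_frames < min_frames:
        raise ValidationError(f"bleach correction needs >= {min_frames} frames")
    t = stack.times
    mean_t = stack.data.mean(axis=(1, 2))
    if (mean_t <= 0).any():
        return stack, BleachFit(math.inf, float(mean_t.mean()), False)
    res = stats.linregress(t, np.log(mean_t))
    slope, intercept = res.slope, res.intercept
    if not np.isfinite(slope) or slope >= 0:
        return stack, BleachFit(math.inf, float(np.exp(intercept)), False)
    tau = -1.0 / slope
    corr = stack.data / np.exp(-t / tau)[:, None, None]
    return stack.with_data(corr), BleachFit(float(tau), float(np.exp(intercept)), True)


def _ap_coordinate(ys: np.ndarray, xs: np.ndarray, calibration: Calibration
                   ) -> np.ndarray:
    ap, _ = axis_unit_vectors(calibration)
    return xs * ap[0] + ys * ap[1]


def partition_cell(mask: LabelMask, label: int, calibration: Calibration
                   ) -> RegionPartition:
    """Split one cell into its central AP band and the two lateral bands.

    Pixels whose AP coordinate (tissue frame) lies between the 25th and
    75th percentile of the cell's AP extent form the central region; the
    remainder is lateral. The two masks tile the cell exactly.
    """
    cell = mask.cell_mask(label)
    if not cell.any():
        raise ValidationError(f"label {label} absent from mask")
    ys, xs = np.nonzero(cell)
    p = _ap_coordinate(ys, xs, calibration)
    lo_ext, hi_ext = p.min(), p.max()
    if hi_ext - lo_ext < 3:
        raise ValidationError(f"cell {label} smaller than 4 px along AP")
    lo = lo_ext + 0.25 * (hi_ext - lo_ext)
    hi = lo_ext + 0.75 * (hi_ext - lo_ext)
    central_sel = (p >= lo) & (p < hi)
    central = np.zeros_like(cell)
    lateral = np.zeros_like(cell)
    central[ys[central_sel], xs[central_sel]] = True
    lateral[ys[~central_sel], xs[~central_sel]] = True
    return RegionPartition(int(label), central, lateral)


def central_lateral_ratio(stack: ImageStack, partition: RegionPartition
                          ) -> np.ndarray:
    """Per-frame ratio of central to lateral mean pixel intensity.

    Input should be background-subtracted. A zero lateral mean yields NaN
    (undefined) for that frame.
    """
    c = stack.data[:, partition.central_mask].mean(axis=1)
    l = stack.data[:, partition.lateral_mask].mean(axis=1)
    with np.errstate(divide="ignore", invalid="ignore"):
        r = np.where(l > 0, c / np.where(l > 0, l, 1.0), np.nan)
    return r


def cell_mean_intensity(stack: ImageStack, mask: LabelMask) -> dict[int, np.ndarray]:
    """Mean intensity per cell per frame (average of all pixels in the
    cell area)."""
    labels = mask.present_labels()
    out = {}
    traces = np.stack([
        ndimage.mean(frame, labels=mask.labels, index=labels)
        for frame in stack.data])
    for k, l in enumerate(labels):
        out[int(l)] = traces[:, k]
    return out


def clone_relative_intensity(stack: ImageStack, mask: LabelMask
                             ) -> dict[int, np.ndarray]:
    """Each clone cell's mean intensity divided by the mean over all
    non-clone (wild-type) cells in the same frame."""
    if not mask.clone_labels:
        raise ValidationError("mask has no clone labels")
    means = cell_mean_intensity(stack, mask)
    wt = [v for l, v in means.items() if l not in mask.clone_labels]
    if not wt:
        raise ValidationError("no wild-type cells to normalise against")
    wt_mean = np.mean(wt, axis=0)
    return {l: means[l] / wt_mean for l in sorted(mask.clone_labels)}
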