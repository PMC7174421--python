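"""Calibrated image / mask / ROI data model shared by every analysis stage.

Conventions (fixed package-wide):

* coordinates are 0-based and pixel-centered, ``x`` is the column index
  (rightward) and ``y`` the row index (downward);
* angles are measured from the image x-axis toward the y-axis, in radians;
* the anterior-posterior (AP) tissue axis lies at ``Calibration.axis_frame``
  in image coordinates and the dorsal-ventral (DV) axis at ``axis_frame +
  pi/2``; measurements are reported in the tissue frame after subtracting
  ``axis_frame``;
* intensities are handled as floats throughout and never rescaled on load,
  so that ratio statistics remain scale-faithful.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Iterable, Sequence

import networkx as nx
import numpy as np
import pandas as pd


class ValidationError(ValueError):
    """Raised when an input object violates a model invariant."""


class GeometryError(ValueError):
    """Raised when a geometric input (ROI, cut line, mask) is unusable."""


@dataclass(frozen=True)
class Calibration:
    """Physical calibration of an image stack.

    Parameters
    ----------
    pixel_size : float
        Length of one pixel side, in micrometres per pixel.
    frame_interval : float
        Time between consecutive frames, in seconds.
    axis_frame : float
        Angle of the tissue AP axis in image coordinates (radians,
        0 = image x-axis). Normalised to ``[0, pi)``.
    """

    pixel_size: float
    frame_interval: float = 1.0
    axis_frame: float = 0.0

    def __post_init__(self) -> None:
        if not (self.pixel_size > 0 and math.isfinite(self.pixel_size)):
            raise ValidationError("pixel_size must be positive and finite")
        if not (self.frame_interval > 0 and math.isfinite(self.frame_interval)):
            raise ValidationError("frame_interval must be positive and finite")
        object.__setattr__(self, "axis_frame", float(self.axis_frame) % math.pi)

    def to_dict(self) -> dict:
        return {
            "pixel_size": float(self.pixel_size),
            "frame_interval": float(self.frame_interval),
            "axis_frame": float(self.axis_frame),
        }

    @classmethod
    def from_dict(cls, d: dict) -> "Calibration":
        return cls(**{k: float(v) for k, v in d.items()})


@dataclass
class ImageStack:
    """A T x Y x X stack of nonnegative float intensities with calibration."""

    data: np.ndarray
    calibration: Calibration
    channel_name: str = ""

    def __post_init__(self) -> None:
        arr = np.asarray(self.data, dtype=float)
        if arr.ndim == 2:
            arr = arr[None]
        if arr.ndim != 3:
            raise ValidationError(f"stack must be TxYxX, got ndim={arr.ndim}")
        if arr.shape[0] < 1 or arr.shape[1] < 1 or arr.shape[2] < 1:
            raise ValidationError(f"empty stack of shape {arr.shape}")
        if not np.isfinite(arr).all():
            raise ValidationError("stack contains non-finite intensities")
        if (arr < 0).any():
            raise ValidationError("stack contains negative intensities")
        self.data = arr

    @property
    def n_frames(self) -> int:
        return self.data.shape[0]

    @property
    def shape(self) -> tuple:
        return self.data.shape

    def frame(self, t: int = 0) -> np.ndarray:
        return self.data[t]

    @property
    def times(self) -> np.ndarray:
        """Acquisition time of each frame in seconds (frame 0 at t=0)."""
        return np.arange(self.n_frames) * self.calibration.frame_interval

    def with_data(self, data: np.ndarray) -> "ImageStack":
        return ImageStack(data, self.calibration, self.channel_name)


@dataclass
class LabelMask:
    """Per-cell segmentation: 0 = background, k>0 = cell ``k``.

    ``clone_labels`` marks the cells carrying a genetic perturbation
    (e.g. Cdc42DN clones); it must be a subset of the labels present.
    """

    labels: np.ndarray
    clone_labels: frozenset = frozenset()

    def __post_init__(self) -> None:
        arr = np.asarray(self.labels)
        if arr.ndim != 2:
            raise ValidationError("label mask must be 2-D")
        if not np.issubdtype(arr.dtype, np.integer):
            if not np.all(arr == np.round(arr)):
                raise ValidationError("labels must be integers")
            arr = arr.astype(np.int32)
        if arr.min() < 0:
            raise ValidationError("labels must be nonnegative")
        self.labels = arr
        present = set(self.present_labels().tolist())
        clones = frozenset(int(c) for c in self.clone_labels)
        if not clones <= present:
            raise ValidationError(
                f"clone labels {sorted(clones - present)} absent from mask"
            )
        self.clone_labels = clones

    def present_labels(self) -> np.ndarray:
        lab = np.unique(self.labels)
        return lab[lab > 0]

    def cell_mask(self, label: int) -> np.ndarray:
        return self.labels == label

    @property
    def shape(self) -> tuple:
        return self.labels.shape


@dataclass
class Polyline:
    """An ordered open polyline in pixel coordinates ``[(x, y), ...]``.

    Roles: ``filopodium`` (traced protrusion), ``cut_line`` (laser ablation
    line) or ``kymograph_line`` (sampling line).
    """

    vertices: np.ndarray
    role: str = "filopodium"
    owner_label: int | None = None

    ROLES = ("filopodium", "cut_line", "kymograph_line")

    def __post_init__(self) -> None:
        v = np.asarray(self.vertices, dtype=float)
        if v.ndim != 2 or v.shape[1] != 2 or v.shape[0] < 2:
            raise ValidationError("polyline needs >=2 (x, y) vertices")
        if np.any(np.all(np.diff(v, axis=0) == 0, axis=1)):
            raise ValidationError("consecutive polyline vertices must differ")
        if self.role not in self.ROLES:
            raise ValidationError(f"unknown ROI role {self.role!r}")
        self.vertices = v

    def length_px(self) -> float:
        """Geodesic (along-path) length in pixels."""
        return float(np.sum(np.hypot(*np.diff(self.vertices, axis=0).T)))

    def length_um(self, calibration: Calibration) -> float:
        return self.length_px() * calibration.pixel_size

    def chord(self) -> np.ndarray:
        """End-to-end vector (dx, dy) in pixels."""
        return self.vertices[-1] - self.vertices[0]

    def to_dict(self) -> dict:
        return {
            "role": self.role,
            "owner": None if self.owner_label is None else int(self.owner_label),
            "vertices": [[float(x), float(y)] for x, y in self.vertices],
        }

    @classmethod
    def from_dict(cls, d: dict) -> "Polyline":
        return cls(
            vertices=d["vertices"],
            role=d.get("role", "filopodium"),
            owner_label=d.get("owner"),
        )


class ResultTable:
    """A tabular result whose numeric columns carry unit strings.

    Thin wrapper over :class:`pandas.DataFrame`; CSV serialisation writes a
    ``units`` row directly beneath the header.
    """

    def __init__(self, df: pd.DataFrame, units: dict[str, str]):
        missing = [c for c in df.columns if c not in units]
        if missing:
            raise ValidationError(f"columns without units: {missing}")
        self.df = df.reset_index(drop=True)
        self.units = dict(units)

    def to_csv(self, path) -> None:
        header = pd.DataFrame([[self.units[c] for c in self.df.columns]],
                              columns=self.df.columns)
        pd.concat([header, self.df.astype(object)]).to_csv(path, index=False)

    @classmethod
    def from_csv(cls, path) -> "ResultTable":
        raw = pd.read_csv(path, dtype=object)
        units = {c: raw.iloc[0][c] for c in raw.columns}
        df = raw.iloc[1:].reset_index(drop=True)
        for c in df.columns:
            try:
                df[c] = pd.to_numeric(df[c])
            except (ValueError, TypeError):
                pass
        return cls(df, units)

    def __len__(self) -> int:
        return len(self.df)


# ---------------------------------------------------------------------------
# Cell adjacency


def build_adjacency(mask: LabelMask, boundary_gap: int = 1) -> nx.Graph:
    """Cell-neighbour graph of a label mask.

    Two cells are adjacent when a pixel of one is 8-connected to a pixel of
    the other. With ``boundary_gap = 1`` (default) cells separated by a
    one-pixel background ridge -- the usual situation for watershed-style
    masks derived from a membrane channel -- are additionally linked: any
    background pixel whose 8-neighbourhood contains both labels bridges
    them. ``boundary_gap = 0`` restricts to direct contact.

    Background (0) is never a node; an all-background mask yields an empty
    graph.
    """
    lab = mask.labels
    g = nx.Graph()
    g.add_nodes_from(int(v) for v in mask.present_labels())

    h, w = lab.shape
    shifts = [(0, 1), (1, 0), (1, 1), (1, -1)]  # unique 8-conn directions
    for dy, dx in shifts:
        a = lab[max(0, -dy): h - max(0, dy), max(0, -dx): w - max(0, dx)]
        b = lab[max(0, dy): h - max(0, -dy), max(0, dx): w - max(0, -dx)]
        sel = (a > 0) & (b > 0) & (a != b)
        if sel.any():
            pairs = np.unique(
                np.stack([np.minimum(a[sel], b[sel]),
                          np.maximum(a[sel], b[sel])], axis=1), axis=0)
            g.add_edges_from((int(p), int(q)) for p, q in pairs)

    if boundary_gap >= 1:
        bg = np.argwhere(lab == 0)
        h, w = lab.shape
        for (y, x) in bg:
            y0, y1 = max(0, y - 1), min(h, y + 2)
            x0, x1 = max(0, x - 1), min(w, x + 2)
            near = np.unique(lab[y0:y1, x0:x1])
            near = near[near > 0]
            for i in range(len(near)):
                for j in range(i + 1, len(near)):
                    g.add_edge(int(near[i]), int(near[j]))
    return g


def adjacency_bruteforce(mask: LabelMask, boundary_gap: int = 1) -> nx.Graph:
    """O(pixels^2) oracle for :func:`build_adjacency` (small masks only)."""
    lab = mask.labels
    if lab.size > 64 * 64:
        raise ValueError("brute-force oracle is restricted to small masks")
    g = nx.Graph()
    g.add_nodes_from(int(v) for v in mask.present_labels())
    pix = np.argwhere(lab != 0)
    for i in range(len(pix)):
        for j in range(i + 1, len(pix)):
            a = int(lab[tuple(pix[i])])
            b = int(lab[tuple(pix[j])])
            if a == b:
                continue
            d = np.abs(pix[i] - pix[j]).max()
            if d <= 1:
                g.add_edge(a, b)
    if boundary_gap >= 1:
        bg = np.argwhere(lab == 0)
        for p in bg:
            near = set()
            for q in pix:
                if np.abs(p - q).max() <= 1:
                    near.add(int(lab[tuple(q)]))
            for a in near:
                for b in near:
                    if a < b:
                        g.add_edge(a, b)
    return g


def axis_unit_vectors(calibration: Calibration) -> tuple[np.ndarray, np.ndarray]:
    """Unit vectors (x, y components) of the AP and DV axes in image coords."""
    a = calibration.axis_frame
    ap = np.array([math.cos(a), math.sin(a)])
    dv = np.array([-math.sin(a), math.cos(a)])
    return ap, dv


def to_tissue_angle(theta_image: float | np.ndarray,
                    calibration: Calibration,
                    axial: bool = True) -> np.ndarray:
    """Convert an image-frame angle to the tissue frame.

    Axial angles (orientations, headless) are folded to ``[0, pi)``;
    directional angles to ``[0, 2*pi)``.
    """
    period = math.pi if axial else 2 * math.pi
    return np.mod(np.asarray(theta_image) - calibration.axis_frame, period)
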