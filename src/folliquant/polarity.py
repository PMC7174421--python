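"""Per-cell stress-fiber directors and the pairwise nematic order
parameter.

A cell's *director* is the axial (headless) mean orientation of its
fiber texture, estimated from the structure tensor of the image. The
planar-polarity statistic over a group of cells is

    S = 2 (<cos^2(theta_ij)> - 1/2)

where ``theta_ij`` is the axial angle between the directors of cells
``i`` and ``j`` and the average runs over all unique unordered cell
pairs in the group; S = 1 for perfectly aligned directors, 0 for random
orientations, -1 for an orthogonal pair.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage

from .geometry import classify_cells
from .model import (Calibration, ImageStack, LabelMask, ValidationError,
                    to_tissue_angle)

CATEGORIES = ("clone", "neighbor_wt", "far_wt", "unclassified")


@dataclass
class CellDirector:
    label: int
    theta: float | None          # tissue frame, [0, pi); None = undefined
    coherence: float
    category: str = "unclassified"


@dataclass
class DirectorSet:
    directors: list[CellDirector] = field(default_factory=list)

    def angles(self, category: str | None = None) -> np.ndarray:
        return np.array([d.theta for d in self.directors
                         if d.theta is not None
                         and (category is None or d.category == category)])

    def __iter__(self):
        return iter(self.directors)

    def __len__(self):
        return len(self.directors)


@dataclass
class OrderParameterResult:
    S: float
    n_pairs: int
    n_cells: int
    category: str = "all"


def orientation_field(image: np.ndarray,
                      sigma_grad: float = 1.0,
                      sigma_tensor: float = 4.0
                      ) -> tuple[np.ndarray, np.ndarray]:
    """Per-pixel dominant local orientation (axial, [0, pi)) and
    coherence in [0, 1] from the smoothed gradient-outer-product
    (structure) tensor.

    ``sigma_grad`` smooths the image before differentiation;
    ``sigma_tensor`` smooths the tensor components (the local averaging
    scale). The returned orientation is the fiber direction, i.e. the
    eigenvector of the *smaller* structure-tensor eigenvalue.
    """
    if sigma_grad <= 0 or sigma_tensor <= 0:
        raise ValidationError("smoothing scales must be positive")
    img = np.asarray(image, dtype=float)
    # Gaussian-derivative gradients: central differences carry a
    # grid-anisotropy bias of a few degrees for oblique orientations
    gx = ndimage.gaussian_filter(img, sigma_grad, order=(0, 1))
    gy = ndimage.gaussian_filter(img, sigma_grad, order=(1, 0))
    jxx = ndimage.gaussian_filter(gx * gx, sigma_tensor)
    jxy = ndimage.gaussian_filter(gx * gy, sigma_tensor)
    jyy = ndimage.gaussian_filter(gy * gy, sigma_tensor)
    # gradient (normal) orientation; fiber orientation is orthogonal
    phi = 0.5 * np.arctan2(2 * jxy, jxx - jyy)
    theta = np.mod(phi + math.pi / 2.0, math.pi)
    tr = jxx + jyy
    det_disc = np.sqrt((jxx - jyy) ** 2 + 4 * jxy ** 2)
    with np.errstate(invalid="ignore", divide="ignore"):
        coherence = np.where(tr > 0, det_disc / np.where(tr > 0, tr, 1.0), 0.0)
    return theta, np.clip(coherence, 0.0, 1.0)


def cell_director(theta: np.ndarray, coherence: np.ndarray,
                  mask: LabelMask, label: int,
                  calibration: Calibration,
                  coherence_floor: float = 0.2,
                  min_pixels: int = 50) -> CellDirector:
    """Coherence-weighted axial circular mean orientation of one cell,
    reported in the tissue frame.

    Cells with fewer than ``min_pixels`` coherent pixels, or with a
    vanishing axial resultant (e.g. two orthogonal populations of equal
    weight), get ``theta=None``.
    """
    sel = mask.cell_mask(label) & (coherence >= coherence_floor)
    if sel.sum() < min_pixels:
        return CellDirector(int(label), None, 0.0)
    w = coherence[sel]
    z = np.sum(w * np.exp(2j * theta[sel]))
    resultant = abs(z) / w.sum()
    if resultant < 1e-3:
        return CellDirector(int(label), None, float(resultant))
    th_img = float(np.angle(z) / 2.0 % math.pi)
    th = float(to_tissue_angle(th_img, calibration, axial=True))
    return CellDirector(int(label), th, float(resultant))


def extract_directors(stack: ImageStack, mask: LabelMask,
                      sigma_grad: float = 1.0, sigma_tensor: float = 4.0,
                      frame: int = 0,
                      exclude_border: bool = True,
                      **kwargs) -> DirectorSet:
    """Directors for every cell of a mask from one image frame.

    Cells touching the image border are excluded by default: their
    truncated fiber fields bias the orientation estimate.
    """
    theta, coh = orientation_field(stack.frame(frame), sigma_grad, sigma_tensor)
    h, w = mask.shape
    border = np.zeros((h, w), dtype=bool)
    border[0, :] = border[-1, :] = True
    border[:, 0] = border[:, -1] = True
    out = DirectorSet()
    for label in mask.present_labels():
        if exclude_border and (mask.cell_mask(label) & border).any():
            continue
        out.directors.append(
            cell_director(theta, coh, mask, int(label), stack.calibration,
                          **kwargs))
    return out


def pairwise_angles(angles: np.ndarray) -> np.ndarray:
    """Axial angle between every unique unordered pair, folded to
    [0, pi/2]."""
    a = np.asarray(angles, dtype=float)
    i, j = np.triu_indices(len(a), k=1)
    d = np.abs(a[i] - a[j]) % math.pi
    return np.minimum(d, math.pi - d)


def order_parameter(angles, category: str = "all") -> OrderParameterResult:
    """S = 2(<cos^2 theta_ij> - 1/2) over all unique cell pairs.

    Computed via the axial resultant: the pair average of cos(2 theta_ij)
    equals ``(|sum exp(2i theta)|^2 - n) / (n (n - 1))``.
    """
    a = np.asarray([x for x in np.atleast_1d(angles) if x is not None],
                   dtype=float)
    n = len(a)
    if n < 2:
        raise ValidationError("order parameter needs >= 2 directors")
    z = np.exp(2j * a).sum()
    s = (abs(z) ** 2 - n) / (n * (n - 1))
    return OrderParameterResult(float(s), n * (n - 1) // 2, n, category)


def order_parameter_bruteforce(angles) -> float:
    """Explicit double loop over pairs (oracle for small n)."""
    a = [x for x in np.atleast_1d(angles) if x is not None]
    tot, cnt = 0.0, 0
    for i in range(len(a)):
        for j in range(i + 1, len(a)):
            d = abs(a[i] - a[j]) % math.pi
            d = min(d, math.pi - d)
            tot += math.cos(d) ** 2
            cnt += 1
    if cnt == 0:
        raise ValidationError("order parameter needs >= 2 directors")
    return 2.0 * (tot / cnt - 0.5)


def categorize_directors(directors: DirectorSet, adjacency,
                         clone_labels) -> DirectorSet:
    """Assign clone / neighbor_wt / far_wt categories in place."""
    cat = classify_cells(adjacency, clone_labels)
    for d in directors:
        d.category = cat.get(d.label, "unclassified")
    return directors


def order_parameter_by_category(directors: DirectorSet, adjacency,
                                clone_labels) -> dict[str, OrderParameterResult]:
    """S computed separately for clone, neighbor-WT and far-WT cells;
    categories with fewer than two measurable directors are omitted."""
    categorize_directors(directors, adjacency, clone_labels)
    out: dict[str, OrderParameterResult] = {}
    for cat in ("clone", "neighbor_wt", "far_wt"):
        a = directors.angles(cat)
        if len(a) >= 2:
            out[cat] = order_parameter(a, cat)
    return out
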