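"""Tissue-level geometry: mosaic cell classification and egg-chamber
elongation.

Mosaic tissues are scored in three categories -- perturbed clone cells,
wild-type cells adjacent to a clone (``neighbor_wt``) and wild-type
cells not adjacent to any clone (``far_wt``) -- which is how
non-cell-autonomous effects are detected. Tissue elongation is the
AP-to-DV length ratio of the egg-chamber silhouette.
"""

from __future__ import annotations

import math
import warnings

import networkx as nx
import numpy as np
from scipy import ndimage

from .model import Calibration, GeometryError, ValidationError, axis_unit_vectors


def classify_cells(adjacency: nx.Graph, clone_labels) -> dict[int, str]:
    """Classify every cell of an adjacency graph.

    ``clone`` = in ``clone_labels``; ``neighbor_wt`` = non-clone with at
    least one clone neighbour; ``far_wt`` = every other cell. Clone
    labels absent from the graph are ignored with a warning. The result
    partitions the node set exactly.
    """
    clones = {int(c) for c in clone_labels}
    missing = clones - set(adjacency.nodes)
    if missing:
        warnings.warn(f"clone labels absent from graph: {sorted(missing)}",
                      stacklevel=2)
        clones -= missing
    out: dict[int, str] = {}
    for node in adjacency.nodes:
        if node in clones:
            out[node] = "clone"
        elif any(nb in clones for nb in adjacency.neighbors(node)):
            out[node] = "neighbor_wt"
        else:
            out[node] = "far_wt"
    return out


def ap_dv_ratio(tissue_mask: np.ndarray, calibration: Calibration,
                method: str = "extent") -> float:
    """AP-to-DV length ratio of a single connected silhouette.

    ``method='extent'`` (default) measures caliper lengths: the extent of
    the mask pixels along the rotated AP and DV axes, matching a length
    measurement on a micrograph. ``method='ellipse'`` instead uses the
    major/minor axis lengths of the inertia-equivalent ellipse; it is
    useful when the silhouette boundary is ragged. The ratio is
    dimensionless and invariant to translation and pixel size.
    """
    m = np.asarray(tissue_mask).astype(bool)
    if not m.any():
        raise GeometryError("empty tissue mask")
    n_comp = ndimage.label(m)[1]
    if n_comp != 1:
        raise GeometryError(f"tissue mask must be one connected region "
                            f"(found {n_comp})")
    ys, xs = np.nonzero(m)
    ap, dv = axis_unit_vectors(calibration)
    p_ap = xs * ap[0] + ys * ap[1]
    p_dv = xs * dv[0] + ys * dv[1]
    if method == "extent":
        len_ap = p_ap.max() - p_ap.min() + 1
        len_dv = p_dv.max() - p_dv.min() + 1
    elif method == "ellipse":
        # 4-sigma axis lengths of the inertia-equivalent ellipse,
        # projected on the tissue axes (exact for a solid ellipse)
        cov = np.cov(np.stack([p_ap, p_dv]))
        len_ap = 4.0 * math.sqrt(cov[0, 0])
        len_dv = 4.0 * math.sqrt(cov[1, 1])
    else:
        raise ValidationError("method must be 'extent' or 'ellipse'")
    if len_dv == 0:
        raise GeometryError("degenerate mask: zero DV extent")
    return float(len_ap / len_dv)
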