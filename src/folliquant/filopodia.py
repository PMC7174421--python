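"""Filopodia metrics: lengths with the >= 0.5 um inclusion rule,
per-cell averages and dorso-ventral directionality.

The primary input is traced polylines (manual tracing of protrusions);
:func:`extract_protrusions` is a clearly flagged best-effort image-based
tracer, validated only on synthetic scenes. When ground-truth polylines
are supplied, all metrics depend on geometry only, never on images.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import networkx as nx
import numpy as np
import pandas as pd
from scipy import ndimage
from skimage.morphology import skeletonize

from .model import (Calibration, ImageStack, LabelMask, Polyline,
                    ResultTable, ValidationError, axis_unit_vectors,
                    to_tissue_angle)

#: shortest filopodium retained, in micrometres ("all filopodia not
#: < 0.5 um were measured")
MIN_LENGTH_UM = 0.5


@dataclass
class FilopodiumRecord:
    owner_label: int | None
    length_um: float
    orientation: float        # tissue frame, [0, 2 pi), end-to-end chord
    side: str                 # 'dorsal' | 'ventral' | 'axial'
    crosses_boundary: bool = False


def measure_filopodia(polylines, calibration: Calibration,
                      mask: LabelMask | None = None,
                      min_length_um: float = MIN_LENGTH_UM
                      ) -> list[FilopodiumRecord]:
    """Geodesic lengths and chord orientations of traced filopodia.

    Polylines with ``role='filopodium'`` and geodesic length >=
    ``min_length_um`` are measured; shorter traces are excluded *before*
    any per-cell averaging. Orientation is the angle of the end-to-end
    chord in the tissue frame; ``side`` is set by the sign of its DV
    component (exactly AP-aligned chords are flagged ``axial`` and kept
    out of the dorsal/ventral counts).
    """
    out: list[FilopodiumRecord] = []
    for p in polylines:
        if p.role != "filopodium":
            continue
        length = p.length_um(calibration)
        if length < min_length_um:
            continue
        dx, dy = p.chord()
        theta = float(to_tissue_angle(math.atan2(dy, dx), calibration,
                                      axial=False))
        dv_comp = math.sin(theta)
        if abs(dv_comp) < 1e-12:
            side = "axial"
        else:
            side = "dorsal" if dv_comp > 0 else "ventral"
        crosses = False
        if mask is not None:
            x0, y0 = p.vertices[0]
            x1, y1 = p.vertices[-1]
            h, w = mask.shape
            l0 = mask.labels[min(int(round(y0)), h - 1), min(int(round(x0)), w - 1)]
            l1 = mask.labels[min(int(round(y1)), h - 1), min(int(round(x1)), w - 1)]
            crosses = l0 != l1
        out.append(FilopodiumRecord(p.owner_label, float(length), theta,
                                    side, crosses))
    return out


def per_cell_average_length(records) -> ResultTable:
    """Mean filopodium length per owner cell.

    Owners present in the records but with no retained filopodia are
    reported as 0 with ``n_filopodia = 0`` (flagged rather than dropped).
    """
    rows = []
    by_owner: dict = {}
    for r in records:
        by_owner.setdefault(r.owner_label, []).append(r.length_um)
    for owner in sorted(by_owner, key=lambda o: (o is None, o)):
        lens = by_owner[owner]
        rows.append({"label": owner,
                     "n_filopodia": len(lens),
                     "mean_length": float(np.mean(lens)) if lens else 0.0})
    df = pd.DataFrame(rows, columns=["label", "n_filopodia", "mean_length"])
    return ResultTable(df, {"label": "cell id", "n_filopodia": "count",
                            "mean_length": "um"})


def directionality_stats(records) -> dict:
    """Dorsal/ventral filopodia partition and bidirectionality index.

    ``index = 1 - |n_dorsal - n_ventral| / (n_dorsal + n_ventral)``:
    1 for an equal split (fully bidirectional), 0 when every filopodium
    points the same way. Exactly AP-aligned records are excluded from
    the side counts and reported separately.
    """
    recs = list(records)
    if not recs:
        raise ValidationError("directionality needs >= 1 filopodium")
    n_d = sum(1 for r in recs if r.side == "dorsal")
    n_v = sum(1 for r in recs if r.side == "ventral")
    n_ax = sum(1 for r in recs if r.side == "axial")
    tot = n_d + n_v
    index = math.nan if tot == 0 else 1.0 - abs(n_d - n_v) / tot
    return {"n_dorsal": n_d, "n_ventral": n_v, "n_axial": n_ax,
            "fraction_dorsal": n_d / tot if tot else math.nan,
            "fraction_ventral": n_v / tot if tot else math.nan,
            "bidirectionality_index": index}


# ---------------------------------------------------------------------------
# best-effort image-based tracing (synthetic validation only)


def _skeleton_paths(skel: np.ndarray) -> list[np.ndarray]:
    """Longest endpoint-to-endpoint path of each skeleton component."""
    g = nx.Graph()
    pts = np.argwhere(skel)
    pset = {tuple(p) for p in pts}
    for (y, x) in pts:
        for dy in (-1, 0, 1):
            for dx in (-1, 0, 1):
                if dy == dx == 0:
                    continue
                q = (y + dy, x + dx)
                if q in pset:
                    g.add_edge((y, x), q,
                               weight=math.hypot(dy, dx))
    g.add_nodes_from(map(tuple, pts))
    paths = []
    for comp in nx.connected_components(g):
        sub = g.subgraph(comp)
        ends = [n for n in sub if sub.degree(n) <= 1]
        if len(ends) < 2:
            continue
        best = None
        for i in range(len(ends)):
            lengths = nx.single_source_dijkstra_path_length(sub, ends[i])
            far = max((n for n in ends[i + 1:] if n in lengths),
                      key=lambda n: lengths[n], default=None)
            if far is not None and (best is None or lengths[far] > best[0]):
                best = (lengths[far], ends[i], far)
        if best is None:
            continue
        path = nx.dijkstra_path(sub, best[1], best[2])
        paths.append(np.array([(x, y) for (y, x) in path], dtype=float))
    return paths


def extract_protrusions(mask: LabelMask, membrane_stack: ImageStack,
                        threshold_rel: float = 0.5, frame: int = 0,
                        min_length_um: float = MIN_LENGTH_UM,
                        threshold_abs: float | None = None
                        ) -> list[Polyline]:
    """Best-effort filopodia tracing from a membrane/protrusion channel.

    Pixels above the threshold (``threshold_rel`` times the frame
    maximum, or the absolute intensity ``threshold_abs`` when given) are
    skeletonised; each skeleton component is traced end-to-end and
    returned as a polyline, with the owner set to the majority cell
    label along the trace. Intended for synthetic validation; traced
    (manual) polylines are the reference input for measurement.
    """
    import warnings
    img = membrane_stack.frame(frame)
    thr = threshold_abs if threshold_abs is not None else threshold_rel * img.max()
    binary = img >= thr
    skel = skeletonize(binary)
    if not skel.any():
        warnings.warn("empty skeleton: no protrusions detected", stacklevel=2)
        return []
    px = membrane_stack.calibration.pixel_size
    out = []
    for path in _skeleton_paths(skel):
        if len(path) < 2:
            continue
        poly = Polyline(path, role="filopodium")
        if poly.length_um(membrane_stack.calibration) < min_length_um:
            continue
        xs = np.clip(np.round(path[:, 0]).astype(int), 0, mask.shape[1] - 1)
        ys = np.clip(np.round(path[:, 1]).astype(int), 0, mask.shape[0] - 1)
        labels = mask.labels[ys, xs]
        labels = labels[labels > 0]
        owner = int(np.bincount(labels).argmax()) if len(labels) else None
        poly.owner_label = owner
        out.append(poly)
    return out
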