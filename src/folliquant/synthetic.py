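"""Ground-truthed synthetic scenes of the follicle-cell basal surface.

Every generator is a pure function of its :class:`GroundTruthManifest`
(seed included): identical manifests give identical outputs. Scenes emulate

* ``fiber`` -- a DV-elongated cell lattice with ~9 um AP spacing, per-cell
  stress-fiber textures of controllable angular dispersion, a controllable
  central/lateral intensity allocation, and bright interfacial filopodia;
* ``oscillation`` -- per-cell sinusoidal myosin intensity with random phase
  and photobleaching decay;
* ``ablation`` -- a pre-cut / 2-s-post-cut frame pair related by an imposed
  exponentially decaying recoil displacement field around the cut line;
* ``rotation`` -- Gaussian nuclear blobs translating coherently along DV.

Fibers are rendered as anti-aliased line segments whose intensity is
speckled along their length (actomyosin puncta); without this longitudinal
texture, displacement along the fiber axis would be unconstrained for any
correlation-based flow estimator.

Generators render with the AP axis along image x (``axis_frame = 0``);
rotated-frame behaviour is exercised by rotating generated scenes.
"""

from __future__ import annotations

import dataclasses
import math
import warnings
from dataclasses import dataclass, field
from importlib import resources

import numpy as np
import yaml
from numpy.random import default_rng
from scipy import ndimage
from skimage.draw import line_aa

from .model import Calibration, GeometryError, ImageStack, LabelMask, Polyline, ValidationError

SCENE_KINDS = ("fiber", "oscillation", "ablation", "rotation")


@dataclass
class GroundTruthManifest:
    """Full parameter record of a synthetic scene; the oracle for
    parameter-recovery tests.

    Lengths in micrometres, times in seconds, angles in radians (tissue
    frame), speeds in the units stated per field.
    """

    seed: int = 0
    scene_kind: str = "fiber"
    calibration: Calibration = field(
        default_factory=lambda: Calibration(0.2, 2.0, 0.0))
    # --- lattice geometry
    n_cells_ap: int = 6
    n_cells_dv: int = 4
    cell_len_ap: float = 9.0
    cell_len_dv: float = 10.0
    dv_stagger: float = 0.5   # brickwork offset of DV cell rows, fraction of cell_len_dv
    dv_jitter: float = 0.25   # row-height jitter within a column, fraction of cell_len_dv
    # --- fiber texture
    director_mean: float = math.pi / 2  # DV in the tissue frame
    director_kappa: float = 8.0
    central_fraction: float = 0.7
    fiber_density: float = 1.2          # fibers per um of AP extent
    fiber_amp: float = 100.0
    fiber_speckle: float = 0.5
    puncta_contrast: float = 0.35
    # --- filopodia
    filopodia_per_cell: int = 4
    filopodia_len: float = 1.5          # mean length, um
    filopodia_amp: float = 80.0
    filopodia_spec: list | None = None  # explicit [[owner, angle_rad, length_um], ...]
    # --- clones
    clone_labels: list = field(default_factory=list)
    clone_intensity_scale: float = 1.0
    clone_kappa: float | None = None    # fiber dispersion inside clones
    # --- oscillation
    osc_period: float = 360.0
    osc_amplitude: float = 0.3
    osc_baseline: float = 100.0
    bleach_tau: float | None = 1000.0   # None = no photobleaching
    duration: float = 1800.0
    # --- ablation recoil
    recoil_vmax: float = 0.22           # um/s
    recoil_lambda: float = 40.0         # decay length, um
    cut_axis: str = "ap"
    cut_length: float = 6.0
    cut_halfwidth: float = 0.5          # zeroed ablated band half-width, um
    cut_line: list | None = None        # explicit [[x, y], ...] px
    cut_gaps: list | None = None        # segmented cuts: [[s0, s1], ...] um along line
    # --- noise and nuclei
    noise_sigma: float = 0.05           # relative to mean foreground intensity
    nuclei_speed: float = 0.5           # um/min along DV
    nuclei_sigma: float = 1.5           # blob radius, um
    # --- filled in by the generators (ground truth outputs)
    true_directors: dict | None = None
    true_filopodia: list | None = None
    true_phases: dict | None = None
    nuclei_start: list | None = None

    def __post_init__(self) -> None:
        if isinstance(self.calibration, dict):
            self.calibration = Calibration.from_dict(self.calibration)
        if self.scene_kind not in SCENE_KINDS:
            raise ValidationError(f"unknown scene kind {self.scene_kind!r}")
        for name in ("cell_len_ap", "cell_len_dv", "fiber_amp", "osc_period",
                     "osc_baseline", "duration", "recoil_lambda", "cut_length",
                     "nuclei_sigma"):
            if not getattr(self, name) > 0:
                raise ValidationError(f"{name} must be > 0")
        if self.director_kappa < 0:
            raise ValidationError("director_kappa must be >= 0")
        if not 0 < self.central_fraction < 1:
            raise ValidationError("central_fraction must be in (0, 1)")
        if self.recoil_vmax < 0 or self.noise_sigma < 0:
            raise ValidationError("recoil_vmax and noise_sigma must be >= 0")

    # -- serialisation -----------------------------------------------------
    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        d["calibration"] = self.calibration.to_dict()
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "GroundTruthManifest":
        known = {f.name for f in dataclasses.fields(cls)}
        extra = set(d) - known
        if extra:
            raise ValidationError(f"unknown manifest keys: {sorted(extra)}")
        return cls(**d)

    def to_yaml(self, path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(self.to_dict(), fh, sort_keys=True)

    @classmethod
    def from_yaml(cls, path) -> "GroundTruthManifest":
        with open(path) as fh:
            return cls.from_dict(yaml.safe_load(fh))

    def replace(self, **kw) -> "GroundTruthManifest":
        return dataclasses.replace(self, **kw)

    # -- derived geometry --------------------------------------------------
    @property
    def cell_px(self) -> tuple[int, int]:
        """(AP, DV) cell size in pixels."""
        px = self.calibration.pixel_size
        return round(self.cell_len_ap / px), round(self.cell_len_dv / px)

    @property
    def image_shape(self) -> tuple[int, int]:
        lap, ldv = self.cell_px
        return self.n_cells_dv * ldv, self.n_cells_ap * lap


def default_manifest(kind: str, **overrides) -> GroundTruthManifest:
    """A manifest with the study-condition defaults for one scene kind."""
    kw: dict = {"scene_kind": kind}
    if kind == "fiber":
        kw["calibration"] = Calibration(0.2, 1.0, 0.0)
    elif kind == "oscillation":
        kw["calibration"] = Calibration(0.2, 30.0, 0.0)
    elif kind == "ablation":
        kw["calibration"] = Calibration(0.2, 2.0, 0.0)
    elif kind == "rotation":
        kw.update(calibration=Calibration(0.2, 30.0, 0.0), duration=600.0)
    kw.update(overrides)
    return GroundTruthManifest(**kw)


# ---------------------------------------------------------------------------
# lattice + fiber rendering


def _lattice_mask(manifest: GroundTruthManifest) -> LabelMask:
    """Brickwork cell lattice: exact ``cell_len_ap`` columns along AP;
    DV row boundaries staggered and jittered independently per column
    (follicular epithelia are staggered, not gridded -- a perfectly
    regular lattice would imprint an artificial DV periodicity that the
    real tissue does not show)."""
    rng = default_rng([manifest.seed, 1715])
    lap, ldv = manifest.cell_px
    h, w = manifest.image_shape
    labels = np.zeros((h, w), dtype=np.int32)
    interior = np.arange(1, manifest.n_cells_dv) * ldv
    for j in range(manifest.n_cells_ap):
        if manifest.dv_stagger > 0 and manifest.n_cells_dv > 1:
            off = rng.uniform(-manifest.dv_stagger, manifest.dv_stagger) * ldv
            edges = interior + off + rng.uniform(
                -manifest.dv_jitter, manifest.dv_jitter, len(interior)) * ldv
            edges = np.round(edges).astype(int)
            edges = np.clip(edges, 4, h - 4)
            for i in range(1, len(edges)):   # keep every cell >= 4 px tall
                edges[i] = max(edges[i], edges[i - 1] + 4)
        else:
            edges = interior
        rows = np.searchsorted(edges, np.arange(h), side="right")
        labels[:, j * lap:(j + 1) * lap] = (
            rows[:, None] * manifest.n_cells_ap + j + 1)
    return LabelMask(labels, frozenset(int(c) for c in manifest.clone_labels))


def _cell_boxes(mask: LabelMask) -> dict[int, tuple[int, int, int, int]]:
    """(x0, y0, x1, y1) half-open bounding box per label (cells are
    rectangles by construction)."""
    out = {}
    for label, sl in zip(range(1, mask.labels.max() + 1),
                         ndimage.find_objects(mask.labels)):
        if sl is not None:
            out[label] = (sl[1].start, sl[0].start, sl[1].stop, sl[0].stop)
    return out


def _clip_line_to_rect(x0, y0, dx, dy, rx0, ry0, rx1, ry1):
    """Intersect the infinite line through (x0, y0) with the rectangle
    [rx0, rx1] x [ry0, ry1] (Liang-Barsky); returns endpoints or None."""
    t0, t1 = -1e9, 1e9
    for p, q in ((-dx, x0 - rx0), (dx, rx1 - x0), (-dy, y0 - ry0), (dy, ry1 - y0)):
        if abs(p) < 1e-12:
            if q < 0:
                return None
            continue
        r = q / p
        if p < 0:
            t0 = max(t0, r)
        else:
            t1 = min(t1, r)
    if t0 >= t1:
        return None
    return (x0 + t0 * dx, y0 + t0 * dy, x0 + t1 * dx, y0 + t1 * dy)


def _sample_axial(rng, mean, kappa, size):
    """Axial (orientation) angles about ``mean`` with concentration
    ``kappa``; kappa=0 is uniform on [0, pi)."""
    if kappa <= 0:
        delta = rng.uniform(-math.pi, math.pi, size)
    else:
        delta = rng.vonmises(0.0, kappa, size)
    return np.mod(mean + delta / 2.0, math.pi)


def _axial_mean(angles):
    z = np.exp(2j * np.asarray(angles)).mean()
    return float(np.angle(z) / 2.0 % math.pi)


def _draw_polyline(canvas, vertices, amp, rng=None, speckle=0.0,
                   bounds=None):
    """Accumulate an anti-aliased polyline onto ``canvas``."""
    h, w = canvas.shape
    for (xa, ya), (xb, yb) in zip(vertices[:-1], vertices[1:]):
        rr, cc, val = line_aa(int(round(ya)), int(round(xa)),
                              int(round(yb)), int(round(xb)))
        keep = (rr >= 0) & (rr < h) & (cc >= 0) & (cc < w)
        if bounds is not None:
            ry0, rx0, ry1, rx1 = bounds
            keep &= (rr >= ry0) & (rr < ry1) & (cc >= rx0) & (cc < rx1)
        rr, cc, val = rr[keep], cc[keep], val[keep]
        if len(rr) == 0:
            continue
        val = val * amp
        if speckle > 0 and rng is not None:
            mod = ndimage.gaussian_filter1d(
                rng.standard_normal(len(val)), 2.0, mode="nearest")
            val = val * np.clip(1.0 + speckle * mod, 0.05, None)
        np.add.at(canvas, (rr, cc), val)


def _render_fiber_frame(manifest: GroundTruthManifest, rng):
    """Noise-free fiber frame + mask + filopodia + per-cell directors."""
    if manifest.calibration.axis_frame != 0.0:
        raise ValidationError("generators render with AP along x (axis_frame=0)")
    px = manifest.calibration.pixel_size
    lap, ldv = manifest.cell_px
    if lap < 3 or ldv < 3:
        raise ValidationError(
            f"cell smaller than 3 px ({lap}x{ldv}); increase resolution")
    mask = _lattice_mask(manifest)
    h, w = mask.shape
    canvas = np.zeros((h, w))
    clone_set = set(int(c) for c in manifest.clone_labels)

    directors: dict[int, float] = {}
    n_fib = max(2, round(manifest.fiber_density * manifest.cell_len_ap))
    boxes = _cell_boxes(mask)
    for label in sorted(boxes):
        x0, y0, x1, y1 = boxes[label]
        kappa = manifest.director_kappa
        if label in clone_set and manifest.clone_kappa is not None:
            kappa = manifest.clone_kappa
        angles = _sample_axial(rng, manifest.director_mean, kappa, n_fib)
        directors[label] = _axial_mean(angles)
        xs = rng.uniform(x0 + 0.5, x1 - 0.5, n_fib)
        yc = (y0 + y1) / 2.0
        cell_canvas = np.zeros_like(canvas)
        for xf, th in zip(xs, angles):
            seg = _clip_line_to_rect(xf, yc, math.cos(th), math.sin(th),
                                     x0, y0, x1, y1)
            if seg is None:
                continue
            amp = manifest.fiber_amp * rng.uniform(0.7, 1.3)
            _draw_polyline(cell_canvas, [(seg[0], seg[1]), (seg[2], seg[3])],
                           amp, rng, manifest.fiber_speckle,
                           bounds=(y0, x0, y1, x1))
        # allocate central_fraction of this cell's fiber intensity to the
        # middle AP band (extent quartiles), the rest to the lateral
        # bands; the band convention matches the analysis partition
        # (quartiles of the pixel-coordinate extent x0 .. x1-1)
        lo = x0 + 0.25 * (x1 - 1 - x0)
        hi = x0 + 0.75 * (x1 - 1 - x0)
        cols = np.arange(w)
        central_cols = (cols >= lo) & (cols < hi)
        cell_rows = slice(y0, y1)
        sub = cell_canvas[cell_rows]
        s_c = sub[:, central_cols].sum()
        s_l = sub[:, ~central_cols].sum()
        tot = s_c + s_l
        f = manifest.central_fraction
        if s_c > 0 and s_l > 0:
            sub[:, central_cols] *= f * tot / s_c
            sub[:, ~central_cols] *= (1 - f) * tot / s_l
        if label in clone_set:
            sub *= manifest.clone_intensity_scale
        canvas[cell_rows] += cell_canvas[cell_rows]

    if manifest.puncta_contrast > 0:
        # punctate actomyosin texture along the fibers: without intensity
        # variation along a fiber, motion parallel to the fiber axis would
        # be unobservable to any correlation-based flow estimator
        fieldtex = ndimage.gaussian_filter(rng.standard_normal(canvas.shape), 1.2)
        fieldtex /= fieldtex.std()
        canvas *= np.clip(1.0 + manifest.puncta_contrast * fieldtex, 0.2, None)

    filopodia = _make_filopodia(manifest, mask, rng)
    for p in filopodia:
        amp = manifest.filopodia_amp * rng.uniform(0.8, 1.2)
        if p.owner_label in clone_set:
            amp *= manifest.clone_intensity_scale
        _draw_polyline(canvas, p.vertices, amp)

    canvas = ndimage.gaussian_filter(canvas, 0.7)
    return canvas, mask, filopodia, directors


def _make_filopodia(manifest: GroundTruthManifest, mask: LabelMask, rng):
    """Ground-truth filopodia polylines crossing DV cell boundaries."""
    px = manifest.calibration.pixel_size
    lap, ldv = manifest.cell_px
    h, w = mask.shape
    out: list[Polyline] = []
    if manifest.filopodia_spec is not None:
        for owner, angle, length in manifest.filopodia_spec:
            ys, xs = np.nonzero(mask.labels == int(owner))
            if len(ys) == 0:
                raise ValidationError(f"filopodia_spec owner {owner} absent")
            bx, by = xs.mean(), ys.mean()
            L = length / px
            out.append(Polyline(
                [[bx, by], [bx + L * math.cos(angle), by + L * math.sin(angle)]],
                role="filopodium", owner_label=int(owner)))
        return out
    boxes = _cell_boxes(mask)
    for label in sorted(boxes):
        x0, y0, x1, y1 = boxes[label]
        lap = x1 - x0
        n_k = int(rng.poisson(manifest.filopodia_per_cell)) \
            if manifest.filopodia_per_cell > 0 else 0
        for k in range(n_k):
            # filopodia radiate from the medial fiber network across a DV
            # cell boundary; the base offset from the boundary is jittered
            # so interdigitating protrusions overlap the boundary zone
            # smoothly rather than forming a periodic comb along DV (no
            # DV periodicity is seen in the real tissue)
            bx = rng.uniform(x0 + 0.3 * lap, x0 + 0.7 * lap)
            side = 1 if (k % 2 == 0) else -1
            length = float(np.clip(
                rng.lognormal(math.log(manifest.filopodia_len), 0.25),
                0.6, 3.0)) / px
            inset = rng.uniform(0.2, 0.8) * length
            by = (y1 - inset) if side > 0 else (y0 + inset)
            ang = side * math.pi / 2 + rng.uniform(-0.45, 0.45)
            ex = np.clip(bx + length * math.cos(ang), 1, w - 2)
            ey = np.clip(by + length * math.sin(ang), 1, h - 2)
            if math.hypot(ex - bx, ey - by) < 1:
                continue
            out.append(Polyline([[bx, by], [ex, ey]],
                                role="filopodium", owner_label=label))
    return out


def _add_noise(frame, rng, sigma_rel, foreground_mean):
    if sigma_rel <= 0:
        return np.clip(frame, 0, None)
    noisy = frame + rng.normal(0.0, sigma_rel * foreground_mean, frame.shape)
    return np.clip(noisy, 0, None)


# ---------------------------------------------------------------------------
# public generators


def generate_fiber_scene(manifest: GroundTruthManifest):
    """Single-frame fiber scene.

    Returns ``(stack, mask, filopodia, resolved_manifest)``; the resolved
    manifest records the realised per-cell directors and filopodia.
    """
    if manifest.scene_kind != "fiber":
        raise ValidationError("manifest.scene_kind must be 'fiber'")
    rng = default_rng(manifest.seed)
    canvas, mask, filopodia, directors = _render_fiber_frame(manifest, rng)
    fg = canvas[mask.labels > 0].mean()
    frame = _add_noise(canvas, rng, manifest.noise_sigma, fg)
    resolved = manifest.replace(
        true_directors=directors,
        true_filopodia=[p.to_dict() for p in filopodia])
    stack = ImageStack(frame[None], manifest.calibration, "fiber")
    return stack, mask, filopodia, resolved


def resolve_cut_segments(manifest: GroundTruthManifest) -> list[Polyline]:
    """Cut-line geometry in pixels: one polyline per dissected segment
    (several when ``cut_gaps`` specifies a segmented ablation)."""
    px = manifest.calibration.pixel_size
    h, w = manifest.image_shape
    if manifest.cut_line is not None:
        base = np.asarray(manifest.cut_line, dtype=float)
    else:
        cx, cy = (w - 1) / 2.0, (h - 1) / 2.0
        half = manifest.cut_length / px / 2.0
        if manifest.cut_axis == "ap":
            base = np.array([[cx - half, cy], [cx + half, cy]])
        elif manifest.cut_axis == "dv":
            base = np.array([[cx, cy - half], [cx, cy + half]])
        else:
            raise ValidationError("cut_axis must be 'ap' or 'dv'")
    if (base[:, 0].min() < 0 or base[:, 1].min() < 0
            or base[:, 0].max() > w - 1 or base[:, 1].max() > h - 1):
        raise GeometryError("cut line extends outside the image")
    if manifest.cut_gaps:
        a, b = base[0], base[-1]
        total = float(np.hypot(*(b - a))) * px
        edges = [0.0]
        for s0, s1 in sorted(manifest.cut_gaps):
            edges += [float(s0), float(s1)]
        edges.append(total)
        segs = []
        for s0, s1 in zip(edges[0::2], edges[1::2]):
            if s1 - s0 < 2 * px:
                continue
            p0 = a + (b - a) * (s0 / total)
            p1 = a + (b - a) * (s1 / total)
            segs.append(Polyline([p0, p1], role="cut_line"))
        return segs
    return [Polyline(base, role="cut_line")]


def _distance_direction_field(shape, segments: list[Polyline]):
    """Per-pixel distance (px) to the nearest cut segment and the unit
    vector pointing away from it."""
    h, w = shape
    yy, xx = np.mgrid[0:h, 0:w].astype(float)
    best_d = np.full(shape, np.inf)
    vec_x = np.zeros(shape)
    vec_y = np.zeros(shape)
    for seg in segments:
        v = seg.vertices
        for a, b in zip(v[:-1], v[1:]):
            ab = b - a
            denom = float(ab @ ab)
            t = ((xx - a[0]) * ab[0] + (yy - a[1]) * ab[1]) / denom
            t = np.clip(t, 0.0, 1.0)
            px_ = a[0] + t * ab[0]
            py_ = a[1] + t * ab[1]
            dx = xx - px_
            dy = yy - py_
            d = np.hypot(dx, dy)
            closer = d < best_d
            best_d = np.where(closer, d, best_d)
            vec_x = np.where(closer, dx, vec_x)
            vec_y = np.where(closer, dy, vec_y)
    norm = np.maximum(best_d, 1e-9)
    return best_d, vec_x / norm, vec_y / norm


def generate_ablation_pair(manifest: GroundTruthManifest):
    """Pre-cut / post-cut frame pair with an imposed recoil field.

    The post frame is the pre frame warped by
    ``d(x) = recoil_vmax * dt * exp(-dist(x, cut)/recoil_lambda) * n_hat(x)``
    with ``n_hat`` pointing away from the cut on each side and
    ``dt = frame_interval``; intensity within ``cut_halfwidth`` of the cut is
    zeroed (ablated material). Returns ``(stack, mask, resolved_manifest)``.
    """
    if manifest.scene_kind != "ablation":
        raise ValidationError("manifest.scene_kind must be 'ablation'")
    rng = default_rng(manifest.seed)
    canvas, mask, _filo, directors = _render_fiber_frame(manifest, rng)
    px = manifest.calibration.pixel_size
    dt = manifest.calibration.frame_interval
    segments = resolve_cut_segments(manifest)
    dist_px, nx_, ny_ = _distance_direction_field(canvas.shape, segments)
    mag_px = (manifest.recoil_vmax * dt / px) * np.exp(-dist_px * px
                                                       / manifest.recoil_lambda)
    # inverse mapping (no holes); cubic spline interpolation, because
    # bilinear resampling under-shifts high-frequency texture at the
    # ~0.1 px displacements the weakest cuts impose
    h, w = canvas.shape
    yy, xx = np.mgrid[0:h, 0:w].astype(float)
    post = ndimage.map_coordinates(canvas,
                                   [yy - mag_px * ny_, xx - mag_px * nx_],
                                   order=3, mode="nearest")
    post = np.clip(post, 0, None)
    post[dist_px * px < manifest.cut_halfwidth] = 0.0
    fg = canvas[mask.labels > 0].mean()
    pre_n = _add_noise(canvas, rng, manifest.noise_sigma, fg)
    post_n = _add_noise(post, rng, manifest.noise_sigma, fg)
    resolved = manifest.replace(
        true_directors=directors,
        cut_line=[[float(x), float(y)]
                  for x, y in np.vstack([s.vertices for s in segments])]
        if manifest.cut_line is None else manifest.cut_line)
    stack = ImageStack(np.stack([pre_n, post_n]), manifest.calibration,
                       "ablation")
    return stack, mask, resolved


def generate_oscillation_movie(manifest: GroundTruthManifest):
    """Per-cell oscillating intensity movie.

    Cell ``c`` has mean intensity
    ``baseline * (1 + A sin(2 pi t / T + phi_c)) * exp(-t / bleach_tau)``
    plus pixel noise; phases are random per cell. Returns
    ``(stack, mask, resolved_manifest)``.
    """
    if manifest.scene_kind != "oscillation":
        raise ValidationError("manifest.scene_kind must be 'oscillation'")
    dt = manifest.calibration.frame_interval
    if manifest.osc_period < 2 * dt:
        raise ValidationError(
            f"osc_period {manifest.osc_period}s is aliased at frame interval {dt}s")
    rng = default_rng(manifest.seed)
    mask = _lattice_mask(manifest)
    labels = mask.present_labels()
    phases = {int(l): float(rng.uniform(0, 2 * math.pi)) for l in labels}
    scales = {int(l): (manifest.clone_intensity_scale
                       if int(l) in mask.clone_labels else 1.0)
              for l in labels}
    n_frames = max(2, round(manifest.duration / dt))
    times = np.arange(n_frames) * dt
    tau = manifest.bleach_tau
    decay = (np.ones_like(times) if tau is None or not math.isfinite(tau)
             else np.exp(-times / tau))
    lab_img = mask.labels
    value_img = np.zeros(lab_img.shape)
    for l in labels:
        value_img[lab_img == l] = scales[int(l)]
    frames = np.empty((n_frames,) + lab_img.shape)
    phase_img = np.zeros(lab_img.shape)
    for l in labels:
        phase_img[lab_img == l] = phases[int(l)]
    for i, t in enumerate(times):
        osc = 1.0 + manifest.osc_amplitude * np.sin(
            2 * math.pi * t / manifest.osc_period + phase_img)
        frame = manifest.osc_baseline * value_img * osc * decay[i]
        frames[i] = _add_noise(frame, rng, manifest.noise_sigma,
                               manifest.osc_baseline)
    resolved = manifest.replace(true_phases=phases)
    return (ImageStack(frames, manifest.calibration, "myosin"), mask, resolved)


def generate_rotation_movie(manifest: GroundTruthManifest):
    """Nuclear blobs on a lattice translating coherently along DV at
    ``nuclei_speed`` um/min. Returns ``(stack, resolved_manifest)``."""
    if manifest.scene_kind != "rotation":
        raise ValidationError("manifest.scene_kind must be 'rotation'")
    rng = default_rng(manifest.seed)
    cal = manifest.calibration
    px, dt = cal.pixel_size, cal.frame_interval
    lap, ldv = manifest.cell_px
    h, w = manifest.image_shape
    n_frames = max(3, round(manifest.duration / dt))
    step_px = manifest.nuclei_speed / 60.0 * dt / px   # along +DV (= +y)
    nn_px = min(lap, ldv)
    if step_px > nn_px / 2:
        warnings.warn("per-frame displacement exceeds half the "
                      "nearest-neighbour distance; tracking may fail",
                      stacklevel=2)
    centers = []
    for idv in range(manifest.n_cells_dv):
        for iap in range(manifest.n_cells_ap):
            centers.append([(iap + 0.5) * lap + rng.uniform(-1, 1),
                            (idv + 0.5) * ldv + rng.uniform(-1, 1)])
    centers = np.asarray(centers)
    sig = manifest.nuclei_sigma / px
    amp = 100.0
    frames = np.zeros((n_frames, h, w))
    yy, xx = np.mgrid[0:h, 0:w].astype(float)
    for i in range(n_frames):
        pos = centers + np.array([0.0, step_px * i])
        frame = np.zeros((h, w))
        for (cx, cy) in pos:
            if cy - 4 * sig > h:
                continue
            y0, y1 = int(max(0, cy - 4 * sig)), int(min(h, cy + 4 * sig + 1))
            x0, x1 = int(max(0, cx - 4 * sig)), int(min(w, cx + 4 * sig + 1))
            if y0 >= y1 or x0 >= x1:
                continue
            frame[y0:y1, x0:x1] += amp * np.exp(
                -((xx[y0:y1, x0:x1] - cx) ** 2 + (yy[y0:y1, x0:x1] - cy) ** 2)
                / (2 * sig ** 2))
        frames[i] = _add_noise(frame, rng, manifest.noise_sigma, amp / 4)
    resolved = manifest.replace(
        nuclei_start=[[float(x), float(y)] for x, y in centers])
    return ImageStack(frames, cal, "nuclei"), resolved


def generate_scene(manifest: GroundTruthManifest):
    """Dispatch on ``manifest.scene_kind``; returns a dict of outputs."""
    if manifest.scene_kind == "fiber":
        stack, mask, filo, res = generate_fiber_scene(manifest)
        return {"stack": stack, "mask": mask, "rois": filo, "manifest": res}
    if manifest.scene_kind == "oscillation":
        stack, mask, res = generate_oscillation_movie(manifest)
        return {"stack": stack, "mask": mask, "rois": [], "manifest": res}
    if manifest.scene_kind == "ablation":
        stack, mask, res = generate_ablation_pair(manifest)
        rois = resolve_cut_segments(manifest)
        return {"stack": stack, "mask": mask, "rois": rois, "manifest": res}
    stack, res = generate_rotation_movie(manifest)
    return {"stack": stack, "mask": None, "rois": [], "manifest": res}


# ---------------------------------------------------------------------------
# packaged fixtures


def list_fixtures() -> list[str]:
    base = resources.files(__package__) / "fixtures"
    return sorted(p.name[:-5] for p in base.iterdir() if p.name.endswith(".yaml"))


def load_fixture(name: str) -> GroundTruthManifest:
    """Load a packaged scene manifest, e.g. ``ablation_control_cell_APcut``."""
    base = resources.files(__package__) / "fixtures"
    path = base / f"{name}.yaml"
    if not path.is_file():
        raise FileNotFoundError(
            f"no fixture {name!r}; available: {list_fixtures()}")
    with path.open() as fh:
        return GroundTruthManifest.from_dict(yaml.safe_load(fh))
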