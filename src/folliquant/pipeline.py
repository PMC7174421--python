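"""Pipeline orchestration: run analysis stages from one YAML config with
reproducible seeding and a provenance summary.

A config names its inputs -- either a ``simulate`` block (scene kind +
manifest or packaged fixture) or paths to stack/mask/ROI files -- and
the stages to run. Missing inputs for any requested stage fail the
preflight check before any computation. Rerunning an identical config
with the same seed reproduces all outputs bit-for-bit for synthetic
runs; the summary embeds the config hash, seed, package version and the
SHA-256 of every text output.
"""

from __future__ import annotations

import hashlib
import json
import math
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .model import (Calibration, ImageStack, LabelMask, Polyline, ResultTable,
                    ValidationError, build_adjacency)
from . import filopodia as filo_mod
from . import geometry, intensity, io, oscillation, periodicity, polarity, recoil
from .synthetic import GroundTruthManifest, generate_scene, load_fixture

STAGES = ("quantify-intensity", "periodicity", "polarity", "filopodia",
          "oscillation", "track-rotation", "piv-recoil", "classify", "shape")


class PipelineError(ValueError):
    """Raised when a config cannot be run (preflight failure)."""


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    h.update(path.read_bytes())
    return h.hexdigest()


def _config_hash(config: dict) -> str:
    canon = json.dumps(config, sort_keys=True, default=str)
    return hashlib.sha256(canon.encode()).hexdigest()


def _load_inputs(config: dict, seed: int, out_dir: Path) -> dict:
    """Resolve the simulate block or explicit input paths."""
    ctx: dict = {"stack": None, "mask": None, "rois": [], "manifest": None}
    sim = config.get("simulate")
    inputs = config.get("inputs", {})
    if sim is not None:
        if "fixture" in sim:
            manifest = load_fixture(sim["fixture"])
        elif "manifest" in sim:
            manifest = GroundTruthManifest.from_dict(sim["manifest"])
        else:
            manifest = None
        if manifest is None:
            raise PipelineError("simulate block needs 'fixture' or 'manifest'")
        if "kind" in sim and sim["kind"] != manifest.scene_kind:
            raise PipelineError(
                f"simulate.kind={sim['kind']!r} does not match the manifest "
                f"scene_kind={manifest.scene_kind!r}")
        manifest = manifest.replace(seed=int(seed))
        scene = generate_scene(manifest)
        ctx.update(scene)
        io.write_stack(ctx["stack"], out_dir / "stack.tif")
        if ctx["mask"] is not None:
            io.write_mask(ctx["mask"], out_dir / "mask.tif")
        if ctx["rois"]:
            io.write_rois(ctx["rois"], out_dir / "rois.json")
        ctx["manifest"].to_yaml(out_dir / "manifest.yaml")
    else:
        cal_d = inputs.get("calibration")
        if cal_d is None and ("stack" in inputs):
            raise PipelineError("inputs.calibration required with inputs.stack")
        cal = Calibration.from_dict(cal_d) if cal_d else None
        if "stack" in inputs:
            ctx["stack"] = io.read_stack(inputs["stack"], cal)
        if "mask" in inputs:
            ctx["mask"] = io.read_mask(inputs["mask"],
                                       inputs.get("clone_labels", ()))
        if "rois" in inputs:
            ctx["rois"] = io.read_rois(inputs["rois"])
    return ctx


_REQUIREMENTS = {
    "quantify-intensity": ("stack", "mask"),
    "periodicity": ("stack",),
    "polarity": ("stack", "mask"),
    "filopodia": ("stack", "rois"),
    "oscillation": ("stack", "mask"),
    "track-rotation": ("stack",),
    "piv-recoil": ("stack", "cut_line"),
    "classify": ("mask",),
    "shape": ("mask",),
}


def _preflight(config: dict, stages: list[str]) -> None:
    sim = config.get("simulate")
    inputs = config.get("inputs", {})
    have = set()
    if sim is not None:
        kind = sim.get("kind")
        if kind is None and "fixture" in sim:
            kind = load_fixture(sim["fixture"]).scene_kind
        if kind is None and "manifest" in sim:
            kind = sim["manifest"].get("scene_kind", "fiber")
        have.add("stack")
        if kind != "rotation":
            have.add("mask")
        if kind in ("fiber",):
            have.add("rois")
        if kind == "ablation":
            have.update(("rois", "cut_line"))
    else:
        have.update(k for k in ("stack", "mask", "rois") if k in inputs)
        if "rois" in inputs:
            try:
                rois = io.read_rois(inputs["rois"])
                if any(p.role == "cut_line" for p in rois):
                    have.add("cut_line")
            except (OSError, ValidationError):
                pass
    gaps = []
    for st in stages:
        if st not in _REQUIREMENTS:
            gaps.append(f"unknown stage {st!r}")
            continue
        missing = [r for r in _REQUIREMENTS[st] if r not in have]
        if missing:
            gaps.append(f"stage {st!r} missing inputs: {missing}")
    if gaps:
        raise PipelineError("preflight failed: " + "; ".join(gaps))


def _run_stage(name: str, ctx: dict, out_dir: Path, options: dict) -> dict:
    stack: ImageStack = ctx["stack"]
    mask: LabelMask | None = ctx["mask"]
    summary: dict = {}
    if name == "quantify-intensity":
        work = stack
        bg = mask.labels == 0
        if bg.any():
            work = intensity.subtract_background(work, bg)
        rows = []
        means = intensity.cell_mean_intensity(work, mask)
        ratios = {}
        if mask.clone_labels and len(mask.clone_labels) < len(mask.present_labels()):
            ratios = intensity.clone_relative_intensity(work, mask)
        for label, tr in means.items():
            try:
                part = intensity.partition_cell(mask, label, work.calibration)
                cl = intensity.central_lateral_ratio(work, part)
            except ValidationError:
                cl = np.full(work.n_frames, np.nan)
            for t in range(work.n_frames):
                rows.append({
                    "frame": t, "label": label, "mean_int": tr[t],
                    "ratio_central_lateral": cl[t],
                    "ratio_clone_wt": (float(ratios[label][t])
                                       if label in ratios else np.nan)})
        tab = ResultTable(pd.DataFrame(rows),
                          {"frame": "index", "label": "cell id",
                           "mean_int": "a.u.",
                           "ratio_central_lateral": "dimensionless",
                           "ratio_clone_wt": "dimensionless"})
        tab.to_csv(out_dir / "intensity.csv")
        summary["n_cells"] = len(means)
    elif name == "periodicity":
        for axis in ("ap", "dv"):
            res = periodicity.analyze_stack(stack, axis)
            pd.DataFrame({"frequency": res.frequencies,
                          "power": res.power}).to_csv(
                out_dir / f"spectrum_{axis}.csv", index=False)
            summary[axis] = {
                "dominant_period_um": res.dominant_period_um,
                "peak_significance": res.peak_significance}
    elif name == "polarity":
        adj = build_adjacency(mask)
        dirs = polarity.extract_directors(stack, mask)
        polarity.categorize_directors(dirs, adj, mask.clone_labels)
        rows = [{"label": d.label,
                 "theta_deg": (math.degrees(d.theta)
                               if d.theta is not None else np.nan),
                 "coherence": d.coherence, "category": d.category}
                for d in dirs]
        ResultTable(pd.DataFrame(rows),
                    {"label": "cell id", "theta_deg": "deg",
                     "coherence": "dimensionless",
                     "category": "category"}).to_csv(out_dir / "directors.csv")
        angles = dirs.angles()
        if len(angles) >= 2:
            res = polarity.order_parameter(angles)
            summary["all"] = {"S": res.S, "n_pairs": res.n_pairs}
        for cat, r in polarity.order_parameter_by_category(
                dirs, adj, mask.clone_labels).items():
            summary[cat] = {"S": r.S, "n_pairs": r.n_pairs}
    elif name == "filopodia":
        recs = filo_mod.measure_filopodia(ctx["rois"], stack.calibration, mask)
        rows = [{"owner": r.owner_label, "length": r.length_um,
                 "orientation_deg": math.degrees(r.orientation),
                 "side": r.side} for r in recs]
        ResultTable(pd.DataFrame(rows, columns=["owner", "length",
                                                "orientation_deg", "side"]),
                    {"owner": "cell id", "length": "um",
                     "orientation_deg": "deg", "side": "category"}
                    ).to_csv(out_dir / "filopodia.csv")
        filo_mod.per_cell_average_length(recs).to_csv(
            out_dir / "filopodia_per_cell.csv")
        if recs:
            summary.update(filo_mod.directionality_stats(recs))
        summary["n_filopodia"] = len(recs)
    elif name == "oscillation":
        work, fit = (intensity.correct_bleaching(stack)
                     if stack.n_frames >= 5 else (stack, None))
        traces = oscillation.extract_traces(work, mask)
        rows = []
        for tr in traces:
            ac = oscillation.autocorr_period(tr)
            iv = oscillation.cycle_periods(tr)
            rows.append({"label": tr.label,
                         "autocorr_period_s": ac if ac is not None else np.nan,
                         "mean_peak_interval_s": (float(np.mean(iv))
                                                  if iv else np.nan),
                         "n_peaks": len(iv) + 1 if iv else 0})
        ResultTable(pd.DataFrame(rows),
                    {"label": "cell id", "autocorr_period_s": "s",
                     "mean_peak_interval_s": "s", "n_peaks": "count"}
                    ).to_csv(out_dir / "periods.csv")
        summary["distribution"] = oscillation.period_distribution(traces)
        if fit is not None:
            summary["bleach_tau_s"] = None if math.isinf(fit.tau) else fit.tau
    elif name == "track-rotation":
        tracks = oscillation.track_nuclei(stack)
        rows = [{"track": i, "n_frames": len(tr.positions),
                 "speed_um_min": tr.mean_speed_um_min(
                     stack.calibration.pixel_size,
                     stack.calibration.frame_interval),
                 "ambiguous": tr.terminated_ambiguous}
                for i, tr in enumerate(tracks)]
        ResultTable(pd.DataFrame(rows),
                    {"track": "index", "n_frames": "count",
                     "speed_um_min": "um/min", "ambiguous": "flag"}
                    ).to_csv(out_dir / "tracks.csv")
        summary["rotation_speed_um_min"] = oscillation.rotation_speed(
            tracks, stack.calibration)
    elif name == "piv-recoil":
        cuts = [p for p in ctx["rois"] if p.role == "cut_line"]
        res = recoil.measure_recoil(stack, cuts,
                                    **{k: v for k, v in options.items()
                                       if k in ("window", "overlap",
                                                "band_width_um")})
        summary = {"max_recoil_speed_um_s": res.max_recoil_speed,
                   "side_speeds_um_s": {str(k): v
                                        for k, v in res.side_speeds.items()},
                   "n_vectors": res.n_vectors}
    elif name == "classify":
        adj = build_adjacency(mask)
        cats = geometry.classify_cells(adj, mask.clone_labels)
        ResultTable(pd.DataFrame(
            [{"label": l, "category": c} for l, c in sorted(cats.items())]),
            {"label": "cell id", "category": "category"}
        ).to_csv(out_dir / "categories.csv")
        summary["counts"] = {c: sum(1 for v in cats.values() if v == c)
                             for c in set(cats.values())}
    elif name == "shape":
        summary["ap_dv_ratio"] = geometry.ap_dv_ratio(
            mask.labels > 0, stack.calibration if stack is not None
            else Calibration(1.0))
    else:
        raise PipelineError(f"unknown stage {name!r}")
    return summary


def run_pipeline(config: dict | str | Path, out_dir: str | Path,
                 seed: int | None = None) -> dict:
    """Run the configured stages; returns (and writes) the summary.

    ``seed`` overrides ``config['seed']``; it feeds the synthetic scene
    when a ``simulate`` block is present. Outputs are written only under
    ``out_dir`` (append-only per run directory); inputs are never
    mutated.
    """
    if not isinstance(config, dict):
        config = io.read_yaml(config)
    stages = list(config.get("stages", []))
    _preflight(config, stages)
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    if seed is None:
        seed = int(config.get("seed", 0))
    ctx = _load_inputs(config, seed, out_dir)
    summary: dict = {
        "scene_id": config.get("scene_id", "scene"),
        "seed": int(seed),
        "config_sha256": _config_hash(config),
        "version": __version__,
        "stages": {},
    }
    for st in stages:
        summary["stages"][st] = _run_stage(st, ctx, out_dir,
                                           config.get(st, {}) or {})
    outputs = {}
    for p in sorted(out_dir.iterdir()):
        if p.suffix in (".csv", ".json", ".yaml") and p.name != "summary.json":
            outputs[p.name] = _sha256(p)
    summary["outputs"] = outputs
    with open(out_dir / "summary.json", "w") as fh:
        json.dump(summary, fh, indent=1, sort_keys=True, default=float)
    return summary
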