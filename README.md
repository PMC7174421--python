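# folliquant

Quantification of basal-surface fluorescence microscopy of the *Drosophila*
follicular epithelium — the monolayer of follicle cells whose basal
actomyosin stress fibers drive egg-chamber elongation. The package bundles
the measurements this system is studied with, plus a ground-truthed
synthetic-scene generator so every stage can be validated end-to-end
without microscope data:

- **Fiber planar polarity** — per-cell directors from the image structure
  tensor and the nematic order parameter
  *S* = 2(⟨cos²θᵢⱼ⟩ − ½) over all unique cell pairs, optionally split into
  clone / neighbor-WT / far-WT categories of a mosaic tissue.
- **Spatial periodicity** — FFT and autocorrelation analysis of the
  mean-intensity profile along the AP or DV tissue axis (stress fibers
  repeat at the ~9 µm AP cell spacing; the DV profile is aperiodic).
- **Intensity quantification** — background subtraction, exponential
  photobleaching correction, per-cell means, the central/lateral
  (medio-basal vs junctional) intensity partition, and clone-relative
  intensity.
- **Myosin oscillations** — per-cell intensity traces, cycle periods by
  peak intervals and by autocorrelation, period histograms.
- **Filopodia metrics** — lengths of traced protrusions with the ≥ 0.5 µm
  inclusion rule, per-cell averages, dorso-ventral directionality, and a
  best-effort skeleton-based tracer for synthetic validation.
- **Laser-ablation recoil** — windowed cross-correlation PIV between the
  pre-cut and 2 s post-cut frames; the maximum recoil speed is the mean
  velocity component orthogonal to the cut line in a band flanking the
  cut, with DV/AP anisotropy ratios and kymographs.
- **Tissue geometry** — mosaic cell classification from the label-mask
  adjacency graph, nuclear-tracking rotation speed, and the AP/DV
  elongation ratio of the egg-chamber silhouette.

## Worked example

Generate a synthetic single-cell ablation scene whose ground truth is a
DV recoil of 0.22 µm/s, then measure it back:

```python
import folliquant as fq
from folliquant.synthetic import load_fixture, resolve_cut_segments

manifest = load_fixture("ablation_control_cell_APcut").replace(seed=0)
stack, mask, resolved = fq.generate_ablation_pair(manifest)
result = fq.measure_recoil(stack, resolve_cut_segments(manifest))
print(f"recoil {result.max_recoil_speed:.3f} um/s from {result.n_vectors} vectors")
```

prints

```
recoil 0.195 um/s from 6 vectors
```

— the imposed 0.22 µm/s recovered to within 11% (the residual is the
known decay of the displacement field across the measurement band; see
`docs/methods.md`). The same scene family drives the spatial-periodicity
stage:

```python
stack, *_ = fq.generate_fiber_scene(load_fixture("fiber_stage10"))
_, profile = fq.axis_profile(stack, "ap")
res = fq.dominant_period(profile, stack.calibration)
print(f"AP period {res.dominant_period_um:.2f} um "
      f"(significance {res.peak_significance:.0f})")
```

```
AP period 9.07 um (significance 88)
```

while the DV profile of the same scene reports no significant period.

The same stages are scriptable from the shell:

```sh
folliquant simulate --fixture fiber_stage10 --seed 0 --out-dir scene/
folliquant periodicity --stack scene/stack.tif --pixel-size 0.2 --out-dir out/
folliquant run --config pipeline.yaml --out-dir run/   # multi-stage YAML config
```

## Layout

```
src/folliquant/
  model.py        calibrated stacks, label masks, polylines, adjacency
  io.py           TIFF / ROI-JSON / YAML input-output
  synthetic.py    ground-truthed scene generators + packaged fixtures/
  intensity.py    background, bleaching, central/lateral, clone ratios
  periodicity.py  axis profiles, FFT and autocorrelation periods
  polarity.py     structure-tensor directors, order parameter S
  filopodia.py    length/directionality metrics, skeleton tracer
  oscillation.py  traces, cycle periods, nuclear tracking
  recoil.py       PIV, vector filtering, recoil speed, kymographs
  geometry.py     clone classification, AP/DV elongation ratio
  pipeline.py     YAML-configured multi-stage runs with provenance
  cli.py          `folliquant` command-line interface
```
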