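# Methods

This note documents the measurement models, the synthetic-scene
generator that provides their ground truth, the numerical choices that
matter, and the limits of what the synthetic validation shows.

## Conventions

Coordinates are 0-based and pixel-centered; `x` is the column index,
`y` the row index. Angles are measured from the image x-axis toward the
y-axis. A `Calibration` carries the pixel size (µm/px), frame interval
(s) and `axis_frame`, the angle of the anterior–posterior (AP) tissue
axis in image coordinates; the dorsal–ventral (DV) axis is `axis_frame
+ π/2`. All reported angles are tissue-frame (image angle minus
`axis_frame`); orientations (fiber directors) are axial, i.e. defined
modulo π. Intensities are floats and are never rescaled on load, so
that every ratio statistic is invariant under global intensity scaling.

## Fiber polarity and the order parameter

Per-pixel orientation comes from the structure tensor: Gaussian-derivative
gradients at scale `sigma_grad` (default 1 px), tensor components smoothed
at `sigma_tensor` (default 4 px). Gaussian derivatives matter here —
central-difference gradients carry a grid-anisotropy bias of 2–3° for
oblique orientations, larger than the accuracy we validate. The fiber
orientation is the minor eigenvector (orthogonal to the dominant
gradient); coherence is `(λ₁−λ₂)/(λ₁+λ₂)`.

A cell's director is the coherence-weighted axial circular mean
`½·arg Σ c·e^{2iθ}` over its pixels, requiring at least 50 pixels with
coherence ≥ 0.2; cells touching the image border are excluded by
default because truncated fiber fields bias the estimate. Two equally
weighted orthogonal populations have zero axial resultant and the
director is flagged undefined rather than invented.

The planar-polarity statistic over a cell group is

    S = 2 (⟨cos² θᵢⱼ⟩ − ½) = ⟨cos 2θᵢⱼ⟩,

θᵢⱼ the axial angle between directors of cells *i* and *j* (folded to
[0, π/2] — directors are headless, so the formula is otherwise
ill-defined), averaged over all unique unordered pairs. It is computed
via the axial resultant, `S = (|Σ e^{2iθ}|² − n) / (n(n−1))`, which the
test suite checks against an explicit pair loop for n ≤ 50. S is 1 for
identical directors, −1 for an orthogonal pair, 0 in expectation for
uniform orientations. For mosaic tissues S is evaluated separately for
clone, neighbor-WT and far-WT cells (classification below).

## Spatial periodicity

The profile along a tissue axis is the mean intensity over the
orthogonal direction (after rotating the frame by `−axis_frame`, with a
weight image so rotation padding never enters the means). The dominant
period is read from the FFT power spectrum of the linearly detrended,
Hann-windowed profile, within the period band [2 µm, L/2]; sub-bin
precision comes from a parabolic fit to log-power around the peak.

A peak is only reported when its power exceeds 15× the background at
its frequency. Two details of this criterion are deliberate:

- *Threshold level.* For a band of N exponentially distributed noise
  bins the expected max/median ratio is ≈ (ln N + γ)/ln 2 ≈ 8 at
  N ≈ 200, so single-digit thresholds flag pure white noise as periodic
  almost surely. 15 puts the white-noise false-positive rate around the
  percent level for the band sizes in play.
- *Background estimate.* The background is a robust power-law fit
  (Theil–Sen regression of log power on log frequency). Random
  large-scale intensity variation reddens the spectrum; against a flat
  (median) background its low-frequency excess reads as a periodicity,
  while against the fitted power law only narrow peaks stand out. The
  robust fit is insensitive to the peak itself and to its harmonics.

The autocorrelation period — the lag of the first positive-lag local
maximum of the normalised ACF above 0.2 — serves as an independent
cross-check; on synthetic fiber scenes the two estimators agree to one
sample.

## Intensity partitioning and bleaching

Background subtraction removes the per-frame scalar mean of a
sample-free region, clamping negatives to zero. Photobleaching is
corrected by dividing out `A·exp(−t/τ)` fitted by least squares to the
log of the whole-field mean; the field-level fit is robust to
individual oscillating cells, and a non-decaying fit falls back to no
correction with a flag. τ on synthetic decays is recovered within 5%.

The central/lateral partition splits each cell along the AP axis at the
25th and 75th percentile of its AP pixel-coordinate extent: the middle
half is the medio-basal (central) region, the two quarter-bands are the
lateral regions near the anterior and posterior junctional membranes.
The two masks tile the cell exactly. Ratios use mean-per-pixel
intensity so region-area differences cancel; for a generator scene
allocating a fraction *f* of fiber intensity centrally on equal-area
bands the expected ratio is *f/(1−f)*, recovered within ~10% (the
shortfall is point-spread blur leaking intensity across the band
edges). Clone-relative intensity divides each clone cell's mean by the
mean over all non-clone cells in the same frame.

## Oscillation periods and rotation tracking

Per-cell traces are frame-wise mean intensities over a static label
mask (background-subtracted, bleach-corrected upstream). Cycle periods
are intervals between adjacent peaks with prominence ≥ 0.2× the trace
amplitude — a threshold that rejects noise wiggles at the default 5%
pixel noise while keeping every true cycle. The autocorrelation period
(first positive-lag ACF maximum of the detrended trace, height ≥ 0.2)
averages out irregular cycles; period histograms pool one
autocorrelation period per cell observed ≥ 25 min, in 2-min bins.

Nuclear tracking detects blobs as local maxima of the
Gaussian-smoothed frame refined to intensity-weighted centroids, and
links them frame-to-frame by nearest neighbour under a 3 µm gate. When
two candidates fall inside the gate the track is terminated and flagged
rather than guessed — rotation is slow and coherent, so ambiguity
signals a detection problem, not a hard assignment. The scene speed is
the mean of per-track mean speeds in µm/min.

## Ablation recoil by PIV

The displacement field between the pre-cut frame and the first post-cut
frame (2 s later by default) is estimated on a grid of 32-px windows
with 50% overlap. Each window is interrogated iteratively: the
post-frame window is resampled (cubic spline) at the running
displacement estimate and the residual shift of the Hann-apodised
windows is measured from the upsampled cross-correlation peak (×100),
up to four passes. One-pass correlation underestimates displacement
multiplicatively (~6% at this window size — the window-weighting bias);
the iteration drives the residual to zero, recovering rigid integer
shifts to ≤ 0.05 px and 0.1–0.5 px subpixel shifts to ≤ 0.01 px bias on
the synthetic textures. Outliers are removed by the normalised-median
neighbourhood test (3×3, threshold 2) plus a correlation-quality floor;
invalid vectors are excluded, never interpolated.

The *maximum recoil speed* is the mean velocity component orthogonal to
the cut, signed positive away from the cut, over valid vectors in a
5-µm-wide band starting 1 µm outside the zeroed cut band on both sides;
only vectors whose perpendicular foot lies on a dissected segment
count, which makes segmented (multi-piece) cuts work unchanged.
"Maximum" refers to the first post-cut interval, where recoil is
fastest — no per-vector maximum is taken, and a net negative mean is
reported as negative (a diagnostic for mis-specified cut geometry).
Anisotropy ratios are plain speed quotients of two such measurements.

## Synthetic scenes

Every generator is a pure function of its manifest (seed included), and
manifests round-trip through YAML. The packaged fixtures encode the
reference measurement conditions: single-cell AP/DV cuts at 0.22 and
0.01 µm/s, 100 µm tissue-scale cuts at 0.76 and 0.07 µm/s, a
dominant-negative-Cdc42 pair at 0.04/0.02 µm/s (factor-2 anisotropy,
with weaker and more disordered fibers), and a stage-10 fiber lattice
with 9 µm AP cell spacing. All at 0.2 µm/px, 5% Gaussian pixel noise
relative to mean foreground.

*Cell lattice.* Columns of exact `cell_len_ap` width tile the AP axis;
DV row boundaries are staggered and jittered independently per column
(brickwork). Follicular epithelia are staggered, not gridded — and a
perfectly regular lattice would imprint an artificial DV periodicity
that real tissue does not show.

*Fibers.* Each cell draws ~1.2 anti-aliased line segments per µm of AP
length, oriented about the DV axis with angular concentration κ
(axial wrapped distribution; per-cell true directors recorded in the
manifest). Fiber intensity is speckled along its length and the whole
canvas is modulated by a smooth random texture — punctate actomyosin;
without longitudinal intensity variation, motion parallel to the fiber
axis would be unobservable to any correlation-based flow estimator.
After rendering, each cell's fiber intensity is rescaled so that
exactly the manifest's `central_fraction` lies in the central AP band
(same band convention as the analysis partition). Filopodia are bright
short segments crossing DV cell boundaries, with jittered base offsets
so interdigitating protrusions overlap the boundary zone smoothly.

*Ablation pairs.* The post frame is the pre frame warped by
`d(x) = v_max·Δt·exp(−dist(x,cut)/λ)·n̂(x)`, n̂ pointing away from the
cut, then zeroed within 0.5 µm of the cut. The warp uses cubic-spline
inverse mapping: bilinear resampling attenuates the phase of
high-frequency texture, so a 0.1 px imposed shift would read ~30% low
to any correlation estimator — an artefact of the generator, not a
property of the analysis. The decay length λ = 40 µm is large compared
with the 5 µm measurement band, so the band-averaged speed is a direct
estimate of the imposed peak speed (the residual `exp(−d/λ)` factor
averages ≈ 0.91 over the band, the main contribution to the ~10%
systematic shortfall quoted above). The recoil field is a kinematic
stand-in with known ground truth, not a viscoelastic tissue model; λ
is not meant as a physical decay length.

*Oscillation movies.* Per-cell intensity
`baseline·(1 + A·sin(2πt/T + φ_cell))·exp(−t/τ_bleach)` with random
phases; defaults T = 6 min, A = 0.3, τ = 1000 s, 30 min at 30 s/frame.
*Rotation movies.* Gaussian nuclear blobs (σ = 1.5 µm) on the lattice
translating along DV at `nuclei_speed` (default 0.5 µm/min, 10 min at
30 s/frame).

## What the synthetic validation does and does not show

Passing the parameter-recovery suite shows the analysis chain is
internally consistent and unbiased against the stated image model:
rectangular-ish cells, line-segment fibers with punctate texture,
Gaussian noise, an exponential kinematic recoil field, sinusoidal
intensity dynamics. Real basal-surface data differ in ways the
generator does not emulate: curved epithelium and perspective
foreshortening, segmentation errors in the label masks (masks are
inputs here; no segmenter is provided), non-Gaussian camera noise,
membrane signal overlapping the fiber channel, viscoelastic recoil
whose decay is neither exponential nor stationary, and filopodia that
bend, branch and overlap. Accuracy figures quoted here are therefore
upper bounds on real-data performance, not guarantees.

## Numerical choices and degenerate inputs

- Period estimators are invariant to affine trace/profile transforms;
  constant inputs return "none" rather than a value.
- The 0.5 µm filopodium inclusion rule is applied before any per-cell
  averaging; owners with no retained filopodia report 0 with a flag.
- Zero lateral intensity makes the central/lateral ratio NaN
  (undefined), never infinite.
- Adjacency uses 8-connectivity; with `boundary_gap=1` (default) two
  cells sharing a background pixel's 8-neighbourhood are linked,
  bridging the 1-px ridges of watershed-style masks.
- The elongation ratio measures caliper extents along the rotated
  tissue axes (matching a length measurement on a micrograph); an
  inertia-ellipse variant is available behind `method="ellipse"`.
- Problem sizes in the test and acceptance runs — 4×4-cell scenes for
  single-cell cuts, 12×8 (≈ 110×80 µm) for tissue cuts, ten seeds per
  quantity — were chosen as the smallest scenes that contain the full
  measurement geometry (cut, flanking bands, ≥ 4 spatial periods).
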