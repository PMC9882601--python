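# Methods

`roboct` is a desk-scale simulator and analysis pipeline for a robotically
aligned, contactless retinal OCT system. It models the chain from patient
motion through two-tiered robotic alignment to motion-distorted volume
acquisition, then quantifies retinal thickness from the simulated volumes and
implements the paired device-agreement statistics used to compare such a
system against a technician-operated clinical OCT. This note records the
models, the defaults and why, and what the synthetic data can and cannot
show.

## Retina phantom

The phantom is an analytic model of the posterior pole: two height fields in
tissue-depth coordinates, the inner limiting membrane (ILM) and the retinal
pigment epithelium (RPE), with retinal thickness defined as
`T(x,y) = z_RPE − z_ILM` (µm) — the ILM-to-RPE convention of clinical macular
thickness maps.

- The RPE is a gentle bowl (1.5 µm/mm² curvature) at 360 µm depth plus a
  seeded band-limited undulation (≈2 µm amplitude, 0.2–0.8 cycles/mm) so
  that each phantom instance is unique but reproducible.
- Thickness is a 330 µm baseline plus a Gaussian peripapillary bump peaking
  at 450 µm at the optic nerve head (ONH) rim (σ = 0.8 mm), minus an inverted
  **super-Gaussian** foveal pit (order 6, FWHM 1.6 mm) whose depth is solved
  so the pit-floor thickness is exactly 280 µm. The flat-bottomed pit makes
  the central 1 mm subfield mean essentially equal the pit-floor value
  (≈280.6 µm), consistent with how central subfield thickness behaves in
  healthy maculae; a plain Gaussian pit would put the 1 mm mean ~18 µm above
  the floor.
- The ONH is a disc of radius 0.9 mm centred 4.0 mm nasal to the fovea
  (anatomically typical values; configurable). Inside it the RPE terminates
  and the ILM plunges as a parabolic cup; thickness is undefined (masked)
  there.
- Reflectivity between ILM and RPE is piecewise constant: a bright
  NFL-like band (0.55) over the top 15 %, two darker bands (0.30/0.18), and
  a hyper-reflective RPE band (0.90) of ±10 µm **centred on the RPE height
  field** — so a segmenter that returns the brightest-band centre measures
  the ground-truth surface directly. Vitreous is 0.02, choroid 0.12.
- Pathologies: cystoid edema adds a Gaussian thickening (peak = magnitude)
  with embedded hypo-reflective cavities; a macular hole is a full-thickness
  defect (masked lumen) with a 0.15 mm residual-wall annulus at the
  specified wall thickness and a 0.3 mm smoothstep return to ambient;
  epiretinal traction adds low-amplitude surface rippling.

## Patient motion

Globe position on the scanner axes (temporal–nasal, superior–inferior,
anterior–posterior) is an Ornstein–Uhlenbeck drift (θ = 0.7 s⁻¹) plus a slow
postural sway sinusoid (0.15–0.35 Hz, 35 % relative amplitude). The `tremor`
profile adds a 4–6 Hz oscillation with randomised frequency, phase and ±20 %
amplitude jitter — the band of Parkinsonian rest tremor.

Amplitudes are calibrated so that the **median per-axis excursion over a
4.14 s three-volume acquisition window** equals the clinically observed
(1.5, 0.7, 2.1) mm for the healthy profile and (2.5, 1.0, 3.4) mm for the
tremor profile. Calibration runs once per (window, dt): a fixed-internal-seed
Monte-Carlo estimates the unit-process median range, and tremor amplitudes
are found by bisection on the combined process. These observed ranges are
single-patient values treated as medians of the population of seeds.

An independent slow 2D gaze-drift walk (OU, 0.12 mm stationary SD) is
carried alongside: it is *untracked* by the alignment system and shifts the
imaged field of view, reproducing the gaze-drift FOV shifts seen clinically.

## Two-tiered alignment

Tier 1 (open loop): a face tracker abstracted as truth + isotropic Gaussian
noise (default SD 0.4 mm, 2 % dropout) at 14 FPS. The robot is commanded
toward the estimate with a 50 mm/s speed limit and 50 ms command latency.

Tier 2 (closed loop, 120 FPS): three pinhole pupil cameras on a 30 mm ring
at the 86 mm working distance view the eye. Frames are segmented by binary
morphology (Otsu dark-object threshold, opening/closing with a radius-2
disc, largest component within area bounds, darkness-weighted centroid) and
≥2 centroids are triangulated by least-squares ray intersection (rays closer
than an eigenvalue floor are flagged degenerate). The fast actuators track
the measured residual proportionally per tick (gain 0.8): lateral → 2D scan
mirror (±2 mm range), axial → voice-coil reference arm (±3 mm). The robot
tracks a low-passed (τ = 0.4 s) copy of the absolute eye estimate, draining
the DC component out of the limited-range fast actuators so they re-center.
An earlier formulation that offloaded `robot + lp(offsets)` self-referenced
the robot state and oscillated; targeting the filtered eye estimate is
stable by construction. All ranges and speed limits are enforced by
clipping, and a hard assertion in the log forbids limit violations.

A state machine gates acquisition: `searching_face → approaching` on a valid
face estimate, `→ pupil_locked` after 5 consecutive pupil frames,
back to `approaching` (aborting any acquisition) after 12 missed frames
(~0.1 s). Imaging is reachable only from `pupil_locked`.

For multi-seed property checks the pupil observation uses the camera
projection path (identical geometry, no rasterisation); the rendered-image
path is exercised by its own tests and by `render_images=True`.

With these defaults the closed-loop residual RMS after settling is
~15 µm lateral / ~35 µm axial for healthy motion, versus ~0.4 mm open loop —
the quantity the "closed beats open over ≥20 seeds" property locks in.

## Acquisition

Scan patterns: a 30°×30° volume of 900 A-scans × 125 B-scans at 100 kHz
(1.125 s active) and a 30°-wide repeated B-scan of 2000 × 100. The flyback
fraction defaults to 0.2267 so one volume cycle is 1.38 s and three
sequential volumes span exactly 4.14 s; the unreported gap between the
1.125 s active scan and the observed cycle time is treated entirely as
flyback. Scan angle maps to retinal millimetres at 0.288 mm/° (emmetropic
small-angle conversion); left eyes mirror the fast axis at render time.

Depth sampling is 1024 px over 3.8 mm in air (3.71 µm/px in air, /1.37 in
tissue) — a typical swept-source configuration, fully configurable. Per
A-scan, the residual error from the compensation log plus gaze drift
displaces the beam laterally, and the axial residual shifts the rendered
tissue by `Δz/pitch_air` pixels (1 mm ≈ 270 px). Intensity is the phantom
reflectivity times unit-mean exponential speckle (fully developed speckle)
plus a Gaussian noise floor, clipped at zero. Each volume stores the
displacement actually applied per A-scan, so the volume carries its own
motion ground truth. Triplicate acquisition re-runs motion + alignment
afresh per capture, emulating the engage/disengage protocol.

## Thickness quantification

Surfaces are minimum-cost left-to-right paths through a per-B-scan graph:
one node per pixel, edges to the next column within a ±2 px step limit,
weight `w = 2 − (g_u + g_v) + 10⁻⁵` where `g` is the normalised feature
image (signed vertical gradient for the dark-to-bright vitreoretinal
interface; plain intensity for the bright RPE band). Since edges only run
forward one column, the shortest path is computed by exact dynamic
programming with ties broken toward the lowest row, followed by 3-tap
parabolic refinement. **Order matters**: the strongest dark-to-bright
gradient in the image is the outer-retina/RPE edge, so the RPE (globally
brightest band) is segmented first and the ILM is then searched strictly
above it. Images are pre-smoothed (σ = 1 axial, 4 lateral) against speckle.

Pixel differences convert to microns as `px · pitch_air / 1.37` (group
refractive index of retina). ONH exclusion: columns whose RPE-path
brightness falls below half the cohort median are clustered; a disc fitted
to them (90th-percentile radius + 0.1 mm margin) is masked. Maps with >50 %
masking are flagged unusable.

Fovea finding is the automatic surrogate for the clinical manual selection:
centre of mass of the lowest-decile thickness within 1.5 mm of the FOV
centre after 0.3 mm median smoothing; when no distinct pit exists (<10 µm
spread, e.g. edema-filled pits) it refuses and demands an override — the
manual path accepts an explicit coordinate verbatim. Central foveal
thickness is the unweighted mean over a 1 mm diameter disc, requiring ≥50 %
unmasked coverage.

A note on the step limit: at the clinical 900-A-scan density the ±2 px/column
limit lets the path descend a macular-hole wall (~1.4 px/column); at coarser
test densities the same geometry is impossible by construction, which is why
the hole-wall recovery test runs at full fast-axis density.

## Repeated B-scan averaging

Frames are grouped in consecutive fours (a trailing pair is kept, a trailing
singleton dropped; 100 frames → 25 groups). Each group registers to its
first frame, averages, passes QC; surviving group-averages register to the
first survivor and average again. Registration is ORB keypoints +
cross-checked descriptor matching + RANSAC affine, refined by iterative
upsampled phase correlation on Hann-windowed, lightly smoothed frames; the
feature-based candidate races a pure-translation candidate and the better
post-warp similarity wins (translation wins ties, keeping noise-fitted
affine terms out of translation-dominated stacks). Transforms within 0.2 px
of identity snap to exact identity so aligned frames are not blurred by
interpolation. The QC similarity is normalised cross-correlation on
smoothed frames — raw NCC between fully-developed-speckle frames is ~0.4
regardless of alignment, so smoothing is what lets the default 0.5
threshold separate anatomy (~0.9) from blinks (~0). A blink group whose
reference is itself a blink self-registers at stage 1 and is rejected at
stage 2 against real anatomy. This module is for qualitative display only;
its outputs never feed the agreement statistics.

## Agreement statistics

Conventions were validated against the built-in 42-eye clinical cohort
fixture (25 patients; 20 healthy, 22 diseased eyes; triplicate means ± SD
per device): intra-session SD is the sample SD (n−1) of the triplicate;
population SD across eye means uses the population divisor (n) — these
reproduce every printed cohort statistic that is arithmetically consistent
with the table, and are deliberately non-configurable.

- Wilcoxon signed-rank: zeros discarded before ranking (classical
  convention; Pratt handling behind a flag), mid-ranks for ties, exact null
  by dynamic programming over doubled ranks for n ≤ 25 (identical to full
  sign enumeration), tie-corrected normal approximation with continuity
  correction beyond.
- ICC: two-way random-effects, absolute-agreement, single-measure ICC(2,1)
  from the mean-squares decomposition, with the standard Satterthwaite
  F-based 95 % interval. Cross-checked against an independent
  implementation in the test suite.
- Bland–Altman: mean difference ± 1.96 sample SD.
- Diagnostic 2×2: sensitivity/specificity/PPV/NPV as whole percents, with
  abnormal the positive class; the shipped matrices (14/1/1/9 and
  13/2/4/6 on 15 abnormal / 10 normal volumes) are the unique 2×2s
  consistent with the reported whole-percent values.
- Sample size: paired normal-approximation
  `n = ⌈((z₁₋α/₂ + z_power)·σ_d/δ)²⌉`, plus the back-solver for the implied
  σ_d (δ = 15 µm, 90 % power, α = 0.05 → n = 18 implies σ_d ≈ 19.6 µm; the
  assumed SD itself is not reported anywhere, only recoverable by
  inversion).
- Subgroups: gender, race (White/Black, the single Asian-descent patient
  excluded from race subgrouping only) and age bins 25–39/40–54/55–69/70+;
  subgroups under 3 pairs are reported as insufficient.

Known data caveats, recorded rather than patched: the printed all-eyes and
diseased RAOCT means differ from direct table recomputation by ~0.7–1.0 µm
(beyond integer rounding) and the printed per-population Wilcoxon p-values
do not reproduce from the rounded table (recomputed 0.43 healthy / 0.73
diseased; both non-significant, as reported). The package always reports
recomputed values.

## Problem sizes and runtime

The clinical scan geometry (900×125×1024) renders in ~14 s per volume and is
the CLI default. The test-suite and acceptance-script simulations use a
reduced geometry — 300×60 A-scans at 512 depth px with identical FOV, timing
fractions and depth pitch — which preserves every geometric relationship
while keeping a full phantom→motion→alignment→acquisition→segmentation round
trip under a few seconds; the multi-seed calibration and control properties
use 20–50 seeds. These sizes are the package's chosen defaults for its own
verification runs.

## What the synthetic data does not show

The phantom has piecewise-constant band reflectivities, no vasculature or
choroidal texture, no shadowing, and ideal A-scan point-spread; speckle is
uncorrelated between frames, which flatters frame-averaging slightly
relative to real partially-correlated speckle. Face and pupil trackers are
noise models, not vision algorithms, so tracker failure modes (occlusion,
eyelashes, specular overlap) appear only as dropout probabilities. Passing
the recovery tests therefore demonstrates internal consistency of the
pipeline — segmentation recovering known geometry under speckle at the
stated noise levels, and the controller's closed-loop benefit under the
calibrated motion model — not performance on clinical images. The cohort
statistics, by contrast, operate on the real per-eye clinical table and
reproduce its printed aggregates exactly as arithmetic.
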