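# Methods

## Scope and approach

The package quantifies aggrephagy from dual-excitation mKeima imaging of
inducible aggregates. Because no raw imaging data are available, the
analysis is validated entirely by *parameter recovery*: a simulator
scripts what each aggregate does (when it acidifies, when each marker is
present, how it moves), renders the script into realistic camera frames,
and the pipeline must read the script back from the pixels. The simulator
therefore defines the study conditions; its defaults are part of the
package contract and are listed below.

## Spectral model

The pH → ratio mapping is a logistic

r(pH) = r_acid + (r_neut − r_acid) · 1/(1 + exp(−h·(pH − pKa)))

with defaults `r_neut = 0.90`, `r_acid = 0.15`, `pKa = 6.5`, `h = 1`.
Only the qualitative behaviour of the mKeima excitation spectrum is
published (445-nm excitation dominates at neutral pH, 561-nm at lysosomal
pH); the asymptotes are instrument-dependent, so all four parameters are
config-exposed. The neutral asymptote is set at 0.90 — clearly above the
0.8 ratio threshold used by the DFCP1 timing rule — because a plateau
sitting exactly at a threshold makes the "drops and stays below"
crossing time undefined under any noise. The acidic asymptote 0.15 keeps
the two histogram modes well separated around the 0.35 clearance
threshold.

Acidification events are logistic in time, rescaled so the series starts
exactly at `r_neut`, ends exactly at `r_acid`, and crosses the half-way
ratio at onset + duration/2 (a raw logistic reaches its endpoints only
asymptotically). Default duration is 10 frames ≈ 3.3 min at the default
20-s frame interval. The scripted pH trajectory follows the same progress
curve between cytosolic pH 7.2 and lysosomal pH 4.7.

## Marker scripts

Marker windows are half-open `[start, end)` frame intervals (episodes
reported by the analysis use inclusive ends).

- **DFCP1** (omegasome): raised-cosine rise → plateau → fall, confined to
  the window; ramp 3 frames.
- **STX17** (autophagosomal SNARE): unit boxcar. In acidifying scripts
  the window closes at the frame nearest to the time at which
  acidification progress reaches 30%, and spans 21 frames (7 min) before
  that, so dwell and the progress-at-release statistic have known truth.
- **RAB7** (late endosome/lysosome): compound-Poisson accumulation —
  contact events arrive at 0.15/frame inside the window, each adding a
  small kiss-and-run gain (0.1) or, with probability 0.2, a large
  full-fusion gain (0.5). The trace is non-decreasing by construction,
  which is what the gradualness flag downstream verifies.

Scripted truth event frames (DFCP1 release, 0.8-ratio crossing, half-drop
frame, progress at STX17 release) are computed at script time from the
noiseless series using the same threshold definitions the analysis
applies, so recovery is measured against the construction rather than
against the pipeline itself.

## Motion

Aggregates are tethered (confined) before and during marker presence and
mobile after release. Both regimes take Gaussian steps of variance 2·D
per axis per frame (D = 0.5 px²/frame by default); confined steps are
additionally reflected into a disc of radius 0.5 px around the anchor.
The switch frame is the first frame after STX17 release (or the
acidification crossing when no marker is scripted); non-acidifying
aggregates stay confined.

## Rendering and camera model

Each aggregate is a pixel-integrated 2-D Gaussian (difference of error
functions, flux-conserving) of total budget ~2000 photons/frame
(per-aggregate log-normal spread, σ = 0.25 in log), split between the two
mKeima channels as ratio : (1 − ratio); the marker is rendered into the
GFP channel at the same centroid (1500 photons at unit script amplitude).
The cell is an ellipse covering ~57% of the field with background 20
photons/px/frame (2 outside). Noise is Poisson shot noise, linear gain,
and additive Gaussian read noise (σ = 2 counts); EM-register excess noise
is not modelled. A fixed-timepoint mode renders 3 planes 200 nm apart
with a minimal defocus model (lateral Gaussian width inflated off-focus,
flux conserved) to exercise the average z-projection path.

Randomness uses one master seed with per-aggregate, per-operation child
streams (`numpy` `SeedSequence` spawn keys), so adding an aggregate never
reshuffles the others and every stage is bit-reproducible.

## Detection

The assay's standard tooling for this step is the ComDet ImageJ plugin,
parameterized with particle size 4 px and SNR 8; since ComDet's internals
are not formally specified, detection here is a standard band-pass /
local-maximum / SNR pipeline: difference of
Gaussians (σ = size/4 minus σ = 2·size), local maxima above
`snr ×` the robust (MAD) noise s.d. of the filtered image, sub-pixel
centroids by intensity-weighted mean. ComDet bit-parity is a non-goal;
correctness is defined by recovery of simulator ground truth. Detection
runs on both mKeima channels and keeps the union (a fully acidified
particle is dim under 445-nm excitation), merging duplicates within the
minimum separation by SNR. Background is the median of in-cell pixels
farther than 2× the particle size from every detection; the cell mask is
the Otsu-thresholded, morphologically closed union of both mKeima
channels, falling back to the whole field when the image has no resolvable
cell background (noiseless renders). Negative background-subtracted
intensities clamp to zero so ratios stay in [0, 1]; border-clipped
windows are flagged and excluded from ratio statistics.

## Ratiometry

`r = i445/(i445+i561)`; cleared means `r < 0.35` strictly. The cleared
fraction is computed per replicate and averaged without weighting
(replicates, not particles, are the experimental unit). The alternative
formulation summing histogram bins below the threshold is available as
`method="histogram"`; the direct count is canonical because it is
bin-independent. Histogram bins are 0.05 wide, left-closed right-open,
last bin closed.

## Tracking

Manual tracking is replaced by a per-frame linear assignment problem
minimizing summed squared displacement, rejecting links beyond 5 px per
elapsed frame, bridging up to 2 missing frames with linearly interpolated,
gap-flagged positions; ties resolve to the lower track id. Traces
integrate all three channels in the detection window along the track and
subtract per-frame, per-channel backgrounds; the marker series is kept
both raw and max-normalized.

## Event analysis

- Episode scoring is hysteresis thresholding on the max-normalized marker:
  on at ≥ 0.5, off only after two consecutive frames < 0.4, minimum 2
  frames. This makes single-frame dropouts (the ambiguity a manual scorer
  resolves by eye) deterministic.
- "Dropped and stayed below" is the strict suffix reading: below the
  threshold at every subsequent non-missing point.
- The pre-event plateau `r_start` is the mean of the first 5 non-missing
  ratio points; the half-drop anchor is the first frame at or below
  `(r_start + r_min)/2`.
- Negative DFCP1 intervals are reported with their sign, not discarded.
- Phase-resolved mobility assigns the interval stepping out of the last
  marker-positive frame to "after" (that step is the first untethered
  one); the switch estimator is a two-segment exponential change-point on
  squared displacements (maximum likelihood split).
- Interpolated (gap) frames contribute to series but are ignored when
  locating anchors; frames flagged missing (border-clipped windows) are
  excluded everywhere.

## FACS module

Populations are two-component log-normal mixtures in (i_neutral, i_low);
the shifted component is displaced ≥ 1 decade along i_low. Positivity
gating is a total-intensity threshold (scatter-based singlet gating is out
of scope); ROI gates are simple polygons in log10 space with boundary
points counted inside. Gate geometry from the original cytometry is not
published, so no numeric gate reproduction is attempted.

## Validation cohorts and problem sizes

`aggrephagy.benchmarks` runs the recovery experiments end to end:
20 noiseless + 20 noisy detection fields (10 spots each), 500-particle
ratio-fidelity fields, clearance cohorts of 3 replicates × 500 particles
over 10 seeds for scripted probabilities 0.1/0.4/0.7 plus a blocked
scenario, 50 single-event movies each for STX17 (60 frames) and DFCP1
(110 frames) at default noise, 100 confined→diffusive tracks, and
10 × 20,000-event FACS mixtures. These sizes give sampling errors several
times smaller than the recovery tolerances they are checked against.

## Known limitations

- The simulator omits photobleaching, chromatic aberration, 3-D PSF
  structure, organelle-textured backgrounds, cell migration, and particle
  merge/split events; passing tests demonstrate correctness of the
  measurement chain under the stated image model, not robustness to
  every real-microscopy artefact.
- Absolute mKeima ratio asymptotes are placeholders, not calibrated
  values; only threshold-relative statements (cleared fractions, timing
  anchors) transfer to real data after per-instrument calibration.
- The STX17 release time sits at a fixed fractional offset from the frame
  grid (integer onsets, fixed duration), so the frame-rounded progress at
  release is systematically ~0.26 rather than the scripted 0.30; the
  deviation is within one frame of kinetics and shared by every event.
- Per-track mobility-switch recovery within ±2 frames holds for ~90% of
  tracks; the residual errors reflect the intrinsic randomness of the
  walk (a confined stretch can by chance look diffusive), not estimator
  bias — the cohort median error is 0.
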