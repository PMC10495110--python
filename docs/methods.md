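# Methods

`dcvpipe` quantifies dense-core-vesicle (DCV) secretion and trafficking from
fluorescence time-lapse recordings. This note documents the models and
procedures it implements, the parameters that matter, what the synthetic
data does and does not emulate, and the design choices made where the
procedure was genuinely open.

## Signal model and units

All stacks are indexed `(frame, row, col)`, pixels 0-based in `(row, col)`
order, times in seconds (minutes for RUSH, whose frames are minutes apart),
distances in micrometres. A `Movie` carries its frame interval and pixel
size; on disk these live in a JSON sidecar next to the 16-bit multi-page
TIFF, because TIFF metadata dialects are not reliable.

## Fusion-event detection (`dcvpipe.fusion`)

NPY-pHluorin is quenched in the acidic DCV lumen and dequenches on fusion,
so a fusion event is a sudden rise of fluorescence at a punctum. The
detection chain:

1. **ROI placement** — candidate sites are local maxima of the
   Gaussian-smoothed maximum projection of the baseline-subtracted stack
   over the stimulation window, above the projection mean + 5 SD; maxima
   closer than `min_separation` (4 px) merge toward the brighter one.
2. **Traces** — 3×3-px ROI means, normalized as R = F/F0 with F0 the mean
   of the first 10 frames. R is scale-free: detection is invariant to
   multiplying the movie by any positive constant.
3. **Criteria** — a 3-frame running median stands in for manual trace
   curation (it deterministically rejects single-frame noise spikes).
   Candidate events are maximal runs of the filtered trace above
   μ_b + 2σ_b, where μ_b, σ_b are the baseline (first 30 s) mean and SD.
   A run becomes an event when
   - its raw peak exceeds μ_b by ≥ 2σ_b (the amplitude criterion),
   - its rise time is < 1 s,
   - it lasts ≥ 3 frames (an event stays bright while the released
     pHluorin disperses; threshold-grazing noise does not), and
   - the trace has returned below μ_b + σ_b since the previous excursion
     (hysteresis: a slow decay hovering at threshold is one event, not
     several).

Three numerical choices depart from the most literal reading of the
criteria, each because the literal version mis-measures the rise time in
noise:

- σ_b is measured on the *unfiltered* baseline R (configurable via
  `baseline_stats`). Measuring it after the median filter shrinks σ_b by
  ~2× and silently re-admits the single-frame spikes the filter exists to
  reject.
- The onset is the last frame below the *run threshold* (configurable via
  `onset_threshold_sd`). Walking back to the last sub-(μ_b+σ_b) frame
  instead attributes ordinary baseline fluctuation (16% of frames lie
  between 1σ and 2σ) to the event's rise and rejects a large fraction of
  genuinely instantaneous events.
- Rise time runs from the onset to the first frame within 3σ_b of the
  *filtered* run maximum (`rise_tolerance_sd`). The literal argmax drifts
  along a slow decay under shot noise (which grows with the signal), again
  inflating the apparent rise of step-like events. A rise genuinely spread
  over several frames still reaches the maximum late and is rejected.

With the defaults, on the synthetic suite (events ≈6–9σ_b, shot + read
noise): recall 0.92–0.95 and 0.01–0.03 false positives per 240-frame
event-free trace.

The per-neuron summary reports the cumulative event count keyed on peak
frames, the mean peak ratio (missing when no events), and the pre/stim/post
split against the stimulation protocol (default: 30 s baseline, then 16
trains of 50 pulses at 50 Hz separated by 0.5 s, i.e. 30–53.5 s).

## Pool counting and released fraction (`dcvpipe.pool`)

An NH4Cl pulse at the end of the recording neutralizes every vesicle lumen
and reveals the whole labelled pool. The pool image is mean(NH4Cl frames) −
mean(pre-pulse frames), which isolates dequenched vesicles from signal that
was already bright. It is band-passed with a difference of Gaussians
(σ = 1 and 3 px), binarized at background mean + 4 SD (background = pixels
below the image median), and 8-connected components with area 3–200 px
count as puncta.

Overlapping vesicles merge into one component; the correction divides each
component's area by the median area of solitary-looking components (area
≤ 1.5× the median of all areas) and rounds, each component contributing at
least 1. On crowded synthetic fields the corrected count is at least as
close to truth as the raw count in ≥ 90% of seeds. The correction is
parameter-free and invariant to intensity scaling.

Released fraction = events per neuron / corrected pool. Values above 1 are
allowed with a warning (they indicate pool undercount). The end-to-end
pipeline excludes frames from NH4Cl onset onward from event detection: the
dequench step is itself a sudden rise in every ROI and would otherwise be
counted as fusion.

## RUSH Golgi-flux kinetics (`dcvpipe.rush`)

In the RUSH pulse-chase, biotin releases an ER-retained SBP-EGFP-NPY cargo
as a synchronized wave; the Golgi fills to a peak and drains with
approximately first-order kinetics. The chain: integer-pixel phase-
correlation registration against frame 0 (at one frame per 5 min, sub-pixel
drift is negligible); mean intensity in a fixed user-supplied Golgi mask,
normalized to the pre-biotin baseline; then kinetics:

- t_peak: argmax of the 3-frame median-filtered normalized trace, refined
  to the raw argmax within ±1 frame (the filter alone erases a sharp
  fill-to-drain transition and biases k even without noise).
- Decay fit from the peak onward:
  `I(t) = plateau + (I0 − plateau)·exp(−k·(t − t_peak))`, least squares
  with k > 0, plateau ∈ [0, max(I)] and free I0 — the standard one-phase
  decay parametrization of common curve-fitting software. A free plateau
  matters because export is incomplete within 2 h, and any background
  inside the mask also appears as a plateau. A grid of k starting values
  (0.3–10 per decay span) guards against local minima; a non-convergent
  fit raises with diagnostics.

Noise-free round trip recovers k to 1e-15; with 5% noise over 50 seeded
25-frame traces, the median |k̂−k|/k is ~0.2% and t_peak is exact in the
median. k is invariant to intensity scaling and halves when the time axis
is stretched ×2.

## Kymograph transport analysis (`dcvpipe.kymo`)

The neurite path (soma first) is resampled at 1-px arc length; at each
position the intensity is the maximum over `line_width` (3) perpendicular
bilinear samples — maximum, not mean, preserves punctate signal. Rows are
time, columns are position, so a particle at constant velocity is a sloped
ridge.

The tracer is deterministic: per row, candidates are intensity-weighted
centroids of runs above `row median + 5× robust noise scale` (MAD-based;
the plain row SD is inflated by the spots themselves and collapses to zero
in empty rows, producing spurious tracks). Centroids within 3 px of either
end are dropped (clipped spots bias inward). Linking is greedy
nearest-neighbour against each track's constant-velocity prediction within
`max_step` (16 px/frame ≈ 1.6 µm/s at the default scale), ties toward the
smaller displacement then smaller position; a track missing a candidate —
typically while two particles cross and merge into one run — coasts on its
prediction for up to 2 frames. Tracks spanning < 8 frames are discarded.

Classification: net displacement = (last − first position)·pixel size,
signed with the soma at 0; |net| < 2 µm (configurable; the value is a
declared stand-in, not a published criterion) is stationary, positive is
anterograde. Speed = |net| / duration for moving tracks. Fractions are
reported over moving tracks and over all tracks. Reversing the path swaps
the labels exactly.

## Statistics (`dcvpipe.stats`)

- **SuperPlot comparison**: the biological replicate (culture preparation)
  is the experimental unit. Units are averaged per replicate; groups are
  compared by a two-tailed unpaired Student t on replicate means (df =
  n_a + n_b − 2; Welch via `equal_var=False`). Identical constant groups
  report t = 0, p = 1. The test is exact under normality: simulated null
  calibration gives a type-I error of 0.05.
- **Comparative Ct**: ΔCt = Ct_target − Ct_reference per sample,
  ΔΔCt per matched sample pair, FC = 2^−ΔΔCt; the summary is the geometric
  mean (and geometric SD) of FC and a one-sample two-tailed t of log2 FC
  against 0, since fold changes are lognormal-ish and the published
  analyses run on the log scale. Zero-variance log2 FC (e.g. a gene
  compared against itself) is flagged rather than tested.
- **Morphometry**: volume change = 100·(1 − (d_test/d_control)³) for
  spherical vesicles; relative prevalence change = 100·(1 − p_test/p_control);
  diameter histograms use half-open bins [lo, hi).

## Synthetic data (`dcvpipe.simulate`)

The generators realize exactly the signal models above, with known ground
truth:

- **Secretion movies**: Gaussian puncta (σ 1.2 px, amplitude 60 a.u.) on a
  flat background (20 a.u.); each event multiplies its punctum by
  `peak_ratio` with a linear ramp over `rise_time` then exponential decay
  (`decay_tau`, default 5 s — the event decay kinetics are not a published
  quantity; this is a simulation parameter, not a biological claim). Event
  onsets and rises are snapped to the frame grid so that frame-level
  rise-time criteria can be tested without aliasing: an off-grid sub-frame
  rise would otherwise place one sampled frame mid-ramp and read as a
  2-frame rise. The NH4Cl window multiplies all puncta simultaneously by
  `dequench_factor`. Noise is Poisson on the signal (scaled) plus additive
  Gaussian — the standard shot + read camera model — added last. Identical
  configs and seeds give bit-identical stacks.
- **RUSH movies**: a disk-shaped Golgi region whose normalized trace is 1
  until biotin (frame 3), rises linearly to `peak_value` (4) at
  `t_peak_true`, then `plateau + (peak − plateau)·exp(−k_true·(t−t_peak))`;
  optional whole-frame drift in integer pixels per frame.
- **Transport movies**: Gaussian spots moving at constant signed velocity
  along a straight horizontal path, truncated at the field edge.

What the synthetic data does **not** emulate: photobleaching, z-drift,
neurite morphology, inhomogeneous backgrounds, pausing or reversing
particles, camera gain calibration. Passing the suite therefore shows the
procedures are correct under their stated signal models, not that they are
robust to every artifact of real recordings.

## Benchmark study conditions (`dcvpipe.benchmarks`)

Chosen once as realistic for this assay class and sized to run in minutes
on one CPU:

- Detection: 50 movies × 5 puncta, events `peak_ratio` 2.0 (≈6–9σ_b in
  F/F0 after background dilution — comfortably above the 4σ_b regime the
  recall claim addresses), onsets inside the stimulation window; 50
  event-free movies for specificity.
- Released fraction: 20 neurons, pool 25, 2 events (target 0.08, the order
  of magnitude reported for strong stimulation), full pipeline including
  automatic ROI placement.
- RUSH: 50 traces, k_true 0.1/min, t_peak 45 min (cargo traverses the
  Golgi in roughly 45 min), 25 frames at 5 min, 5% Gaussian noise.
- Transport: 250 sparsely labelled movies (one vesicle each), exactly 2/3
  of particles anterograde (stratified assignment, so the design fraction
  is realized exactly), speeds 0.5–1.5 µm/s. Sparse labelling isolates
  tracer performance from particle-collision effects; crowded fields are
  available via `particles_per_movie`.
- Statistics: 1000 null simulations (3 replicates × 8 units per group).

## Known limitations

- The overlap correction assumes roughly uniform punctum size; strongly
  size-dispersed pools would bias the area quotient.
- The tracer handles crossings by prediction and short gap closing but has
  no global assignment step; dense fields with many similar-velocity
  particles can still merge or swap tracks.
- The event detector's hysteresis means a second fusion at the same punctum
  during the first event's decay (before R returns below μ_b + σ_b) is not
  counted separately.
- Sub-pixel event localization and axon/dendrite classification are out of
  scope.
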