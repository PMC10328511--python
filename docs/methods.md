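# Methods

This note documents the models, estimators and numerical choices in
`mismatch2p`, and what the synthetic-data generator does and does not
emulate.

## The paradigm and its quantities

In the closed-loop condition the visual-flow speed of a virtual tunnel
equals the animal's locomotion speed times a constant coupling gain;
flow is stored in locomotion-equivalent cm/s so the gain defaults to 1
and flow direction (nasotemporal vs temporonasal) is trigger metadata,
never a sign on the speed trace.  Mismatches clamp flow to zero for
1 s, scheduled at 12±2 s gaps regardless of behavior.  Open-loop
sessions either replay a previous closed-loop flow trace (turning the
clamps into "playback halts") or present 1 s fixed-speed stimuli
(24 cm/s-equivalent) at 9±3 s or 7±1 s gaps depending on protocol.

The unsigned visuomotor error is |Error|(t) = |speed_loco(t) −
speed_flow(t)/gain|.  Under coupling it is identically zero, so the
error step of a mismatch equals the running speed, and for a stationary
animal in replay it equals the flow speed.  Δ|Error| of a trial is the
mean |Error| over a window equal in length to the ΔF/F response window
but shifted 0.66 s earlier, minus the mean over the 1 s pre-stimulus
window — a mean difference, not an endpoint difference, matching the
per-trial averaging of the responses it is compared against.

## ΔF/F and ROI quality control

ΔF/F = (F − F0)/median(F), with F0 the running 8th percentile of F over
a 1000-frame window.  The window is centered and shrinks at the trace
edges; a centered window avoids the onset-lagged baselines a trailing
window produces.  The median in the denominator is taken over the raw
trace (a config flag switches to the drift-corrected trace).  The
result is invariant to multiplicative rescaling of F.

The circularity index CI = 4π·area/perimeter² uses the
marching-squares contour length (`skimage.measure.find_contours` at
level 0.5 on a zero-padded mask) as the perimeter.  Pixel-edge-counting
perimeters overestimate the boundary of smooth shapes by up to a factor
π/2 and would push discs far from CI = 1, so the convention is part of
the interface: the 0.14 threshold is calibrated against contour
lengths.  Under this convention a rasterized disc reads CI ≈ 1.0 and a
3×150 px bar reads CI ≈ 0.06.

The activity screen computes the periodogram of the mean-subtracted
ΔF/F and takes the ratio of mean power over strictly interior bins of
0.05–1 Hz (calcium band) to 3–8 Hz (noise band); ROIs below 10 are
dropped.  It therefore requires a frame rate above 16 Hz and at least
40 s of data, and is applied to the unfiltered 60 Hz ΔF/F before the
10 Hz low-pass (a zero-phase 4th-order Butterworth, unit DC gain), in
the order the processing chain states it.  Axon-segment ROIs surviving
both screens are averaged into one trace per field of view.

## Trial responses and sham correction

A trial response is the mean ΔF/F over the response window minus the
mean over the baseline window, windows specified in seconds and mapped
to frames by rounding (at 60 Hz the 0.66 s offset is exactly 40
frames; at 15 Hz the somatic 0.33–2.33 s window is frames 5–35).
Windows: axonal mismatch/playback halt respond at 0.66–1.66 s
(baseline −1–0 s); replay flow onsets are delayed 400 ms further for
the slower stimulus ramp; somatic stimuli use 0.33–2.33 s; locomotion
onsets use −2 to −1.5 s baselines (axonal, 0–3 s response) or −2 to
−1 s (somatic, 0.66–4 s response).  A condition average is valid only
with ≥3 trials.  For state-selected conditions, sham triggers (120 for
axonal, 1000 for somatic analyses) are drawn uniformly over the same
condition segment, excluded within one response-window length of real
triggers, sub-selected by the same locomotion-state criterion, and
their mean response subtracted — removing whatever part of the signal
is explained by being in that behavioral state rather than by the
stimulus.

Degenerate inputs: out-of-range windows drop the trial (NaN, excluded
from counts); the LMI is flagged undefined when √(R_loco² + R_stat²)
falls below 10⁻⁹ (0/0 guard); speed bins are left-open/right-closed so
a boundary speed joins the slower bin; percentile thresholds for cell
typing use linear interpolation and ties go to "other".

## Hierarchical bootstrap

Each replicate draws imaging sites with replacement (as many as
observed), pools the drawn sites' values with multiplicity, draws that
many values with replacement from the pool, and computes the statistic;
10,000 replicates by default.  The second-level sample size follows the
drawn sites rather than the original total — a seed-stable convention
that respects replicates dominated by large sites.  p-values are tail
proportions of the replicate distribution (two-sided: twice the smaller
tail, capped at 1), floored at 1/n_boot, never 0.  The slope variant
computes an OLS slope per replicate and redraws replicates whose
resampled x is constant.  Two-sample comparisons pair replicates by
index (O(n_boot)); an all-pairs mode exists for small runs.

Like any nonparametric cluster bootstrap, the site-level resample
underestimates between-site variance by a factor (S−1)/S, so the test
is mildly anticonservative when few sites carry most of the variance:
measured type-I at α = 0.05 under a balanced two-level Gaussian null is
≈0.09 with 10 sites and ≈0.06 with 16–30 sites.  The calibration test
therefore runs at 20 sites × 20 units — enough clusters for the
method's nominal behavior — and the packaged experiment designs use
16–24 sites, matching the scale of multi-session datasets this kind of
study actually collects.  Flat tests (FoV- or mouse-level data) select
between t and rank statistics by Shapiro–Wilk and Levene pre-checks at
α = 0.05.

## The synthetic generator

The generator exists to give every estimator a ground truth; it
emulates the behavioral, stimulus and population structure of the
paradigm, not raw imaging movies (no PSF, motion or pixel noise; ROI
masks and pupil diameter are generated directly).

**Behavior.**  A two-state semi-Markov bout process: exponential dwell
times (default 8 s in each state), per-bout plateau speeds uniform in
5–25 cm/s, 0.25 s Gaussian transition smoothing and sub-0.4 cm/s
stationary jitter.  Equal dwell means target ~50% time locomoting above
4 cm/s, comfortably passing the 15% inclusion rule.  The study this
layout follows does not publish bout statistics; these defaults are
config-exposed choices, not claims about real mice.

**Schedulers.**  Inter-event gaps are normal with the protocol's
mean ± SD, truncated at a 2 s floor (resampling via `truncnorm`).  For
9±3 s the truncation raises the long-run mean by ≈0.9%; the moment
checks compare against the truncated distribution's analytic moments.

**Calcium.**  Linear rate → fluorescence: difference-of-exponentials
kernel normalized to unit peak (GCaMP6s-like 0.18/1.0 s for axons,
jGCaMP8m-like 0.04/0.25 s for somata), amplitude, baseline, linear
drift, white Gaussian noise.  No spiking or saturation — the
downstream estimators are linear in the signal, so a linear forward
model exercises all of them.

**Axonal population.**  One latent rate per field of view:
baseline + error_gain·|Error|(t) + onset_gain·K(t) at locomotion
onsets; ROIs share the latent rate with lognormal per-ROI gain jitter
and independent noise, reproducing the high within-FoV correlation that
justifies pooling.  Lognormal mouse- and FoV-level gain effects create
the nested variance.  Signs follow directly: mismatch responses grow
with running speed, stationary playback halts deflect negative.

**Somatic population and plasticity.**  Each neuron has a visual
amplitude, mismatch amplitude, locomotion gain g (mean 1.6 > 1, the
canonical locomotion gain), class-dependent closed−open
locomotion-onset difference (NPE −, other 0, PPE +, planted for ≥90%
percentile-split recovery), nested lognormal amplitude effects, and
independent per-trial multiplicative response variability (CV 0.35 —
single-trial V1 responses are highly variable, and without this the
within-site variance is unrealistically small relative to shared
behavioral noise).  An experiment simulates one pre/post session pair
per imaging site, each with its own behavior; this per-site
independence is what makes site-level resampling meaningful downstream.
Each epoch is a closed-loop segment (mismatches + laser trains) followed
by an open-loop fixed-speed segment (both flow directions,
pseudorandom).  Between epochs, and only in the closed-loop-pairing ×
high-expression arm, the nasotemporal locomotion gain is reduced as
g → g·(1 − ρ·min(s, 20)/20) per trial speed s (ρ = 0.6), leaving
temporonasal and all stationary responses untouched.  The change is
instantaneous between epochs because the readout is pre vs post, not a
learning curve.  Default experiment scale is 300 s closed + 600 s open
per epoch and 24 sites — the 5–10 min epochs and multi-session scale of
the real design.

**Opto and pupil.**  Laser trains are 15 ms pulses at 20 Hz for 1 s
(duty cycle exactly 0.30 by construction), scheduled at 7±1 s,
optionally gated by locomotion >4 cm/s.  Trains are sampled onto the
session clock, so the on-fraction is exact only on grids that resolve
15 ms; the analytic duty cycle is exposed separately.  Pupil diameter
is baseline + slow noise + a dilation kernel at train onsets (amplitude
scaling with expression level) with short blink dropouts flagged in a
mask.

**What passing tests do not show.**  The generator contains no
registration artifacts, neuropil contamination, bleaching
nonlinearities, eye movements, or reward/arousal covariates, and its
noise is Gaussian; recovery of planted effects here demonstrates the
correctness of the estimators, not their robustness to every failure
mode of real two-photon data.

## Problem sizes used in the packaged checks

Scheduler moments use ≥1,000 gaps; the axonal recovery check runs 3
mice × 2 FoVs × 600 s at 60 Hz; the plasticity check runs four arms of
6 mice × 4 sites × 25 neurons with 900 s epochs at 15 Hz; calibration
runs 1,000 nested-null repeats at 1,000 replicates each.  These sizes
were chosen as the smallest at which the respective effects and error
rates are stable properties of the design rather than of a particular
seed.

## Known limitations

* The bootstrap's small-S anticonservatism is documented, not
  corrected; a variance-inflation or studentized variant is out of
  scope because the inference procedure itself is part of the protocol
  being reproduced.
* Blink detection is an input mask; the provided default detector is a
  simple outlier rule and config-replaceable.
* A third (mouse-level) resampling layer is available behind a flag and
  off by default; the procedure specified for neuron-level data names
  sites and neurons only.
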