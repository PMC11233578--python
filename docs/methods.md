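# Methods

This note documents the models, conventions and design choices behind
`gabacircuit`, in the order data flows through the pipeline.

## ΔF/F0 definition and conventions

ΔF/F0(t) = (f(t) − f_b) / f0(t) with two baselines serving different
purposes:

* **f_b** (event-local): mean fluorescence over the 0.5 s preceding
  each stimulus onset. Removes the event-local offset so the aligned
  pre-onset mean is ~0 by construction.
* **f0** (slow): 8th percentile of the ROI fluorescence plus the
  estimated background signal overlapping the ROI, over a 1-s moving
  window. Including the background makes the denominator robust to
  imperfect source separation; the low percentile tracks the
  non-transient floor of the signal.

Conventions that a re-implementation must match to reproduce our
numbers exactly:

* The percentile window is **centred** on the current frame
  (a trailing window is available via `DffParams.percentile_centered`;
  which variant the field's common pipelines use is rarely stated, so
  both are supported). Edges use truncated windows.
* Percentiles interpolate **linearly between order statistics**
  (numpy's default), so a sort-and-index oracle agrees to machine
  precision.
* Frame intervals are half-open [t, t+Δ); the onset frame belongs to
  the post-stimulus window.
* Segments where f0 ≤ 0 anywhere are flagged invalid and excluded
  (reported, never silently dropped).
* Gaussian smoothing (σ = 100 ms) exists for display only and is never
  applied before statistics.

AUCs use trapezoidal quadrature. A window's integral runs to the first
frame at/after the window end (using it as the closing edge when it
exists), so AUC(0–5) = AUC(0–1) + AUC(1–5) holds exactly. Fold change
is (AUC_target − AUC_ref)/|AUC_ref|; a zero reference yields an
undefined (flagged) value that group statistics exclude. Layer
assignment is a half-open interval lookup on the medio-lateral
coordinate; the depth boundaries are configuration (defaults 100 µm
and 300 µm for the L1/L2-3 and L2-3/L5 transitions, 900 µm maximum)
because published protocols specify the lens geometry rather than
numeric boundaries.

## Circular-shift responsiveness test

The test statistic is the across-event mean of the ΔF/F0 average over
the 0–1 s post-onset window (configurable). The null is built by
rotating the session-long activity by 1000 uniform integer shifts in
[1, T−1], drawn with replacement (shift 0 excluded), and recomputing
the identical statistic at the fixed event times. A neuron-session is
responsive when the observed statistic falls strictly outside the
[2.5, 97.5] percentile band of the null; the exceeded side gives the
direction (activated / suppressed). Strict inequality means a
constant trace — whose null collapses to a point — is never called
responsive.

Two implementation points matter for exchangeability:

* The statistic is computed through the decomposition
  dff(t; o) = f(t)/f0(t) − f_b(o) · (1/f0(t)), which lets one
  precompute three rolling-mean tables and evaluate all 1000 rotations
  by indexing. Under rotation, f and f0 rotate **jointly** (f0 is a
  sliding functional of f, so it travels with the trace) and f_b is
  recomputed on the rotated trace. Observed and null therefore run
  through literally the same code path.
* A `rotate_level="raw"` mode instead recomputes f0 from scratch on
  each rotated trace; it differs only in the percentile window's edge
  handling and is provided for sensitivity analyses.

An earlier variant of the statistic (event contrast of the f/f0 ratio
trace) was abandoned: because f0 is a percentile over a 1-s window it
moves on the indicator's own timescale, and that variant attenuated
genuine responses roughly threefold relative to the ΔF/F0 definition.

No multiple-testing correction is applied across neurons at this
step; the union-over-sessions filter (responsive in ≥ 1 of 3 sessions)
defines the inclusion set for ensemble analysis.

## Ensemble discovery

Features: per-session trial-mean ΔF/F0 from −1 s to +2 s around onset,
binned at 0.1 s (30 bins) and concatenated across the three sessions
(90 features). Columns are mean-centred but **not** variance-scaled —
the clusters are defined by response amplitude and sign, which
z-scoring would distort. PCA keeps 4 components (a warning fires if
they explain < 60% of variance). K-means uses Euclidean distance with
50 seeded restarts, keeping the best inertia; k is chosen from 2–6 by
the mean silhouette index, ties breaking to the smallest k. With
k = 2, the cluster with the larger session-1 (post − pre) contrast is
vF-activated; exact ties default to cluster 0 with a warning. Control
and opsin-expressing animals are clustered jointly, with group labels
carried through for downstream proportion tests.

## Intrinsic-feature extraction

All features are baseline-relative (median pre-step voltage), so they
are invariant to DC offsets except the AP threshold, which is an
absolute voltage. Protocol: 1-s current steps, −50 to +50 pA in 10 pA
increments at 20 kHz.

* **Input resistance**: slope of the median steady-state deflection
  (last 0.3 s of the step — mirroring the sag definition's window)
  against current, over non-spiking sweeps with |I| ≤ 30 pA.
* **Membrane τ**: single-exponential least-squares fit to the first
  0.1 s of the −50 pA relaxation.
* **Sag ratio**: median deflection over the last 0.3 s ÷ minimum
  deflection in the first 0.3 s of the −50 pA step (1 = no sag).
* **AP detection**: dV/dt by central differences on a 4-pole 3-kHz
  zero-phase Butterworth-filtered trace (mirroring a typical
  acquisition filter); threshold is the first sample above 50 V/s of
  each contiguous supra-threshold region; peak is the voltage maximum
  within 5 ms.
* **First spike latency** is measured at the AP **peak** (not the
  threshold crossing) relative to step onset — unusual, but kept
  because it is the convention the downstream classification was
  built on.
* **First AHP latency**: threshold crossing to the post-spike voltage
  minimum, bounded by the next spike's threshold or the step end;
  truncated AHPs are flagged.
* **Depolarising hump**, two rules: early-spiking cells use (first-AP
  threshold − V at 0.3 s); late-spiking cells use (max V in first
  0.3 s − V at 0.3 s), with AP excursions masked out of the early
  maximum.
* **Classification**: threshold rule on (first spike latency, first
  AHP latency); the default boundary (spike latency ≥ 0.1 s → pNGF)
  is configuration, since published numeric boundaries live in
  supplementary material rather than the text. Boundary cases tie to
  pNGF. A 2-class Gaussian fallback is the documented alternative
  when no thresholds are configured.

## Feedforward-IPSC isolation

With the compound PSC recorded near −50 mV and the pure EPSC at
E_GABA = −92 mV, both averaged over trials:

1. Onsets are detected as the first crossing of 5% of the
   post-stimulus peak on a 3-kHz-filtered trace (the 5% criterion and
   the 0.5-ms initial-slope window are package conventions; published
   descriptions say only "initial slope").
2. The scale factor is slope_compound / slope_pure over the 0.5 ms
   from onset (short enough that a ≥ 1 ms-latency IPSC cannot
   contaminate it).
3. FF-IPSC(t) = compound(t) − scale · pure(t). We subtract the scaled
   EPSC from the compound (rather than scaling the compound to the
   EPSC) so the isolated IPSC keeps the amplitude it has at the
   compound's holding potential.
4. Latency = IPSC onset (on the residual) − EPSC onset (on the pure
   trace). An undetectable residual means no feedforward inhibition
   and returns the ~zero trace flagged `ipsc_detected=False`.

Exclusion rules: a recording is discarded when outward IPSCs appear on
100% of −50 mV trials, or when the latency is < 1 ms — both indicate
antidromically activated interneurons rather than feedforward
recruitment. Per-trial outward detection thresholds the residual
(trial − scale·pure) at max(3 × pre-stimulus SD, 5 pA) in a 10-ms
window starting 1 ms after the EPSC onset; the threshold rule is a
package decision, as per-trial detection criteria are generally
unpublished.

Inward charge integrates only the negative (inward) rectified current,
trapezoidally, with the closing sample included so adjoining windows
add exactly; 1 pA·s = 1 pC.

## Statistics module

Standard tests (Wilcoxon signed-rank, Mann–Whitney U, Fisher exact,
χ², Friedman, one-sample t against 50%) are delegated to scipy; the
module's job is correct pairing, family definition and Bonferroni
correction (corrected p = min(1, raw × family size)). Dunn's post-hoc
z after Friedman is implemented locally (no pre-packaged
implementation in the dependency stack): within-subject average ranks,
z = (R̄_i − R̄_j)/√(k(k+1)/6n), ties handled by average ranks. The
session-proportion trend runs an overall χ² then session-1-referenced
pairwise Fisher tests with family = number of pairwise tests.
Degenerate inputs (e.g. identical paired samples, which leave no
signed ranks) are flagged rather than producing a spurious p.

## Synthetic-data forward models

**Imaging sessions.** Spiking is an event-rate model: every neuron
fires spontaneous Poisson transients (2 Hz, amplitude 0.05 ΔF/F0
units); during each 1-s stimulus, activated neurons receive an extra
20-Hz Poisson drive whose per-spike amplitude is normalised so the
expected evoked transient peaks at `evoked_amplitude` (default 0.2,
i.e. 10 × the 0.02 frame noise SD), and inactivated neurons have their
spontaneous drive suppressed (default fully), producing a dip set by
the tonic calcium level times the indicator decay fraction (~0.05
ΔF/F0 over the stimulus second). Spikes are convolved with a
double-exponential indicator kernel (rise 0.2 s, decay 1.6 s,
GCaMP6s-like — chosen to produce the seconds-scale transients typical
of that indicator). Fluorescence is F0·(1 + calcium + drift + noise)
with per-neuron F0 ~ lognormal around 100, sinusoidal drift (5%
amplitude, 300-s period, random phase) and white noise. The background
channel is a positive offset plus low-pass-filtered shared noise, so
the f0 definition (percentile of ROI + background) is exercised
non-trivially. Session 2 multiplies evoked amplitudes by
`opto_gain_session2` (default 1.5) and sets the opto flag. Stimulus
onsets are scheduled with uniform random gaps within configurable
bounds (protocols state only "random intervals"); the withdrawal flag
thresholds the noisy summed activated-population response per trial,
as no withdrawal mechanics are published for head-fixed implanted
animals. Class fractions default to 40% activated / 25% inactivated /
35% nonresponsive, matching reported proportions (~65% responsive,
with activated the larger ensemble); `evoked_amplitude = 0` plants an
all-nonresponsive null population. Everything is deterministic under
the config seed.

What this generator does **not** emulate: pixel-level movies, motion
artefacts, source-extraction crosstalk beyond the single background
channel, bursting statistics, or non-stationary arousal effects.
Passing recovery tests therefore demonstrate correctness of the
analysis chain on data with the assumed statistical structure, not
robustness to real-data pathologies.

**Fixture scale.** Recovery and calibration runs use the full
recording protocol — three 900-s sessions at 20 Hz with 24 stimuli
each — because compressing the schedule into shorter sessions raises
the fraction of the trace occupied by evoked transients and thereby
inflates the rotation null; with the full protocol the 2000-neuron
null calibration completes in about two minutes. Short sessions are
used only for I/O and plumbing tests where detection power is
irrelevant.

**Current-clamp sweeps.** Subthreshold responses follow
V(t) = I·R_in·(1 − e^(−t/τ)); hyperpolarising sweeps add a delayed
sag component (an alpha function starting 120 ms into the step,
peaking before 0.3 s, scaled with |I|) so the τ fit window stays
clean, as Ih activates slowly. Spikes are stereotyped waveforms —
half-cosine rise (80 mV over 1.2 ms), cosine fall to the AHP minimum,
curvature-matched cosine recovery — inserted at the archetype latency
(SBC-like: 20 ms atop a fast depolarising hump; NGF-like: 400 ms after
a small early hump). All planted feature values are computed from the
closed-form waveform design on a dense 1-µs grid (latencies mapped to
the 20-kHz recording grid), independently of the feature-extraction
code, so extraction-vs-planted comparisons are a genuine dual-route
check.

**PSC trials.** Biexponential kernels (EPSC: rise 0.5 ms, decay 5 ms,
100 pA at −92 mV; IPSC: rise 1 ms, decay 12 ms, 50 pA outward at
−50 mV) with a 1-ms synaptic delay; the −50 mV compound scales the
EPSC by the driving-force ratio (−50/−92) and adds the IPSC with
per-trial Bernoulli release at the planted latency (default 3 ms).
−92 mV trials never contain the IPSC (E_GABA).

## Numerical choices and degenerate inputs

* Percentile interpolation linear; documented so oracles match.
* Ties: silhouette k-selection → smallest k; ensemble-label contrast
  → cluster 0 activated (warned); classification boundary → pNGF.
* Strict inequalities in the bootstrap make constant traces
  non-responsive rather than arbitrarily significant.
* Rank-deficient PCA inputs report fewer non-zero components instead
  of failing.
* Seeds: every stochastic component takes an explicit seed; model
  objects derive per-neuron substreams from a master generator, so
  results are reproducible bit-for-bit and independent of neuron
  iteration order changes within a version.

## Known limitations

* The pNGF/pSBC decision boundary defaults are plausible but not
  validated against a published supplementary table; users with real
  recordings should calibrate `ClassifierConfig` on their own data.
* The bootstrap assumes circular stationarity of the session; strong
  monotone drift within a session (beyond the gentle sinusoidal drift
  modelled here) would distort the null despite the pre-onset
  baseline.
* FF-IPSC onset detection at 5% of peak is biased late by a fraction
  of the rise time; the bias largely cancels in the EPSC–IPSC latency
  difference but not in absolute onsets.
* The statistics module implements the comparisons the pipeline
  needs; it is not a general post-hoc framework (only Dunn after
  Friedman, only Bonferroni correction).
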