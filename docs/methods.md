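# Methods

This note documents the models, the defaults and the genuinely open
design choices in `lfpdecode`, and what the synthetic data can and cannot
show.

## Synthetic cohort generator

The generator emulates laminar LFP recordings from mouse barrel cortex
during a go/no-go whisker detection task. Each trial is a channels ×
540-sample matrix in mV at 1 kHz spanning [−420, +120) ms around stimulus
onset (all windows in the package are half-open, 0 = stimulus onset).
Per session the stimulus list holds `n_catch` catch trials (0 %) and
`intensity_repeats` repeats of each intensity in {20, 40, 60, 80, 100} %,
presented in randomized order; with the protocol's 50/50 counts this
yields 300 trials of which 5/6 (83 %) carry a stimulus.

**Background activity.** The protocol does not constrain spontaneous LFP
statistics, so the simplest model with realistic autocorrelation is used:
per-channel AR(1) noise (`ar_coeff` 0.97, i.e. ~30 ms correlation time;
stationary SD `noise_scale_mv` 0.1 mV) whose innovations share a common
component across channels (`channel_correlation` 0.2). Crucially, the
background is independent of the trial label, which makes the PRE-window
negative control exact: no decoder can beat chance there except by
finite-sample luck.

**Evoked response.** A difference of exponentials (rise 2 ms, decay
15 ms) scaled to a most-negative value of `peak_amplitude_mv` (0.4 mV at
100 % intensity) at `peak_latency_ms` (7 ms, inside the physiological
5–10 ms range), zero before onset, amplitude linear in intensity.
Evoked LFP amplitudes of a few hundred µV over ~0.1 mV background are
typical for strong whisker deflections in L4. Per-channel amplitude is
the layer multiplier (L4 1.0 > L5 0.7 > L2/3 0.5 > L6 0.4) shaped by a
within-layer taper so the depth profile is most concave at the L4 centre
channel — this is what anchors the CSD sink used for layer assignment.
The mapping from physical stimulus amplitude/velocity to LFP response is
not specified by the protocol; intensity-to-amplitude is therefore an
exposed configurable curve (linear by default). An optional 60 Hz
stimulus-following component confined to the 100 ms vibration is off by
default (such frequency-following patterns are inconsistent in practice).

**Behaviour.** Response probability follows a Weibull psychometric
p(I) = fa + (asym − fa)(1 − exp(−(I/mid)^slope)) with defaults fa = 0.1,
asym = 0.95, mid = 40 %, slope = 2 — it equals the false-alarm rate
exactly at 0 % and rises monotonically. Lick latencies are truncated
normal (220 ± 80 ms) inside the +100–500 ms window of opportunity.
Early licks (in [0, 100) ms), whose muscle artifact contaminates the
evoked response, exist only as an injectable artifact; the RP label is
positive iff the lick falls inside the window of opportunity, and trials
with earlier licks must be removed by QC before labelling (labelling such
a trial raises).

**Artifacts** are constructed to close the loop with their detectors:
saturation adds a pulse beyond ±2 mV; a burst writes one 20 ms
high-amplitude waveform identically onto every channel; line noise adds a
continuous 50 Hz sinusoid (0.5 mV); an early lick sets a latency in
[0, 100) ms plus a broadband transient. Default injection rates are 0 so
the baseline cohort is clean; tests inject explicitly.

## Quality control

Four detectors run over the full −420…+120 ms range; a trial is kept only
if all are silent, and every triggered reason is recorded per rejected
trial. The protocol fixes the ±2 mV cutoff, the 20 ms burst window and
the 50 Hz criterion but quantifies neither the burst-correlation strength
nor how much 50 Hz power counts as excessive; the package's defaults are: burst windows slide
with 10 ms stride and fire when the *minimum* pairwise Pearson r reaches
0.8 (constant channels contribute r = 0); line noise fires when Welch
power within 50 ± 1 Hz exceeds 25 % of the 1–150 Hz total on any channel.
At these defaults, on 1,000 clean generated trials the false-rejection
rate is ~1–2 % (the residue being genuine cross-channel correlation of
strong evoked responses) and injected artifacts are detected at ~100 %.

## Filtering, CSD, layers

Decoding features use causal Butterworth filtering (first-order 150 Hz
low-pass, then sixth-order 47–53 Hz band-stop, applied as second-order
sections with zero initial conditions). Causality is deliberate — the
pipeline emulates an online decoder — so each trial's first samples carry
a transient; train and test trials are treated identically, which keeps
this from biasing any comparison. "Sixth-order" is interpreted as design
order 6 of the band-stop prototype and is configurable.

The CSD is the negated second spatial difference of the trial-averaged
evoked LFP (sink negative, no end-point padding, two fewer rows than
channels, 25 µm spacing). L4 is the channel with the most negative CSD
within 0–25 ms post-onset after a 5 ms boxcar smoothing in time (the
smoothing suppresses the noise bias of a running minimum; ties break to
the shallowest channel; a flat CSD raises). Other layers sit at fixed
channel offsets from L4, mirroring a depth-based border estimate.
Sessions carry their generative layer map; recovery via the CSD is
verified in tests with ≥30 high-intensity trials per session.

## Features and scaling

RAW features are the filtered trace at 1 kHz over PRE [−400, 0),
PERI [0, 100) or FULL (PRE then PERI): 400/100/500 values per layer, the
ALL selector concatenating L2/3, L4, L5, L6 in that order. FFT features
transform PRE and PERI separately (their spectra differ strongly) and
concatenate for FULL: with caps at 147.5 Hz (PRE, 2.5 Hz spacing) and
140 Hz (PERI, 10 Hz), this gives 60/15/75 amplitudes. The "strength" of
a component is the single-sided amplitude 2|X_k|/N for k ≥ 1 and the
signed mean X_0/N for k = 0, so bin 0 equals the window average exactly.
Caps are Hz thresholds, not counts, so truncated peri windows (the
shortened-signal sweep) degrade gracefully. Min-Max scaling learns
per-feature extrema from training rows only; test values are not clipped,
and constant training columns scale to 0 with a warning.

## Liquid State Machine

The protocol treats the LSM's internals as external, so all internals
here are package decisions following the classical construction:
135 LIF neurons on a 3×3×15 grid, 80 % excitatory; connection probability
C_type·exp(−(d/λ)²) with λ = 2 grid units and C of 0.3/0.2/0.4/0.1 for
EE/EI/IE/II; half-normal weight magnitudes scaled per synapse type (EE
0.5, EI 0.5, IE 1.0, II 0.5), excitatory outgoing weights ≥ 0 and
inhibitory ≤ 0, no self-connections. Dynamics (dimensionless, threshold
θ = 1): v ← v + (dt/τ_m)(−v + I), τ_m = 20 ms, dt = 1 ms matched to the
LFP grid, reset 0, refractory 2 ms, one-step spike propagation.

Input encoding is deliberately simple to avoid inventing an unverifiable
spike-coding scheme: RAW traces are injected as analog currents onto a
seeded random 30 % neuron subset with positive gains (gain 4, uniform
±50 % heterogeneity; zero input ⇒ zero current); FFT vectors are
projected once and held as constant currents for 50 steps.

The readout is a ridge-penalized logistic regression on exponentially
filtered spike counts (τ_s = 20 ms) sampled every `readout_interval_ms`
(default 10 ms, window-start anchored, final step always included). A
single end-of-window snapshot was evaluated first and discarded: with any
plausible τ_s the filter forgets the 5–25 ms evoked transient by the end
of a 100 ms window and leave-one-mouse-out accuracy stalls near 0.55–0.7,
whereas sampled states retain the transient and reach ≥ 0.9. Anchoring
the sample times at the window start (rather than its end) makes
truncated-window results comparable across lengths. Inference is
noise-free; (config, seed, data) fully determine the model. A diagnostics
warning fires if the mean firing rate leaves 1–100 Hz. Reservoir states
are memoized per (structure, input row) — a pure compute cache shared
across bootstraps and grid points that changes no result.

## Baselines

DT/RF/GLM are scikit-learn, XGB is xgboost, all seeded. RCKT implements
the random-convolutional-kernel transform in-repo (lengths {7, 9, 11},
mean-centred Gaussian weights, uniform bias, exponential dilation,
optional padding; max + proportion-of-positive-values pooling; logistic
readout; multichannel input mixes a random channel subset per kernel) so
that its transform cost is honestly visible in inference runtimes. The
published hyperparameter grids are unavailable, so each algorithm carries
a small documented default grid (≤ 4 points; the GLM grid spans four
orders of regularization magnitude).

## Validation protocol

Leave-one-mouse-out: all trials of one mouse form the test set; per
held-out mouse, 10 bootstrap resamples of the training trials give 10
models (4 mice × 10 = 40 evaluations per scenario-algorithm). Bootstrap
seeds are drawn once in the split plan, so all algorithms see
byte-identical training multisets per (mouse, bootstrap) — the basis for
the paired Wilcoxon test. Order of operations per split (the protocol
does not state it; chosen to keep every training multiset exactly 50 %
positive): balance by downsampling the majority class, then bootstrap
with replacement to the balanced size, then fit the Min-Max scaler on the
resample, then stratified 3-fold grid search (ties to the earlier grid
point), then the final fit. Test sets are left at their natural mix; for
the 0-vs-100 % scenarios they are balanced by construction. Accuracy uses
the fixed 0.5 threshold throughout (decision-threshold optimization is
out of scope); ROC AUC is trapezoidal, PR AUC is average precision, Brier
is mean squared probability error. Runtime is wall-clock seconds per
sample, train and inference phases always reported separately.

Platt calibration refits the primary model on a stratified 67 % of the
training set and fits a univariate logistic map on the 33 % hold-out's
(probability, label) pairs; test data never enters calibration. The
Wilcoxon wrapper drops zero differences (classic convention), returns
None below two non-zero pairs, and uses scipy's exact distribution for
small tie-free samples and the corrected normal approximation otherwise.
Fisher's test against chance builds the 2×2 table of observed
correct/incorrect counts versus the chance-expected counts.

## Desk-scale study conditions

The heavy controls run on 4 mice × 1 session × 72 trials (12 catch + 12
per intensity) — the package's chosen desk-scale conditions, preserving
the protocol's structure (4 individuals, 40 evaluations, 83 % stimulus
fraction) at a size where the full suite runs in minutes. QC operating
rates use 1,000 trials; calibration checks use n = 2,000 synthetic
probabilities. The shortened-signal analysis uses a generator whose
evoked response is confined to the first ~40 ms (rise 3 ms, decay 10 ms,
peak at 12 ms), and "plateau" is assessed as: mean accuracy at length L
within 2 combined SEMs of the 100 ms value. Monotonicity checks
(amplitude, intensity) compare 40-evaluation means and tolerate one
combined SEM, the measurement granularity of small test sets.

## What passing tests do and do not show

The generator is stationary, Gaussian-driven and layer-stereotyped; real
recordings have non-stationary states (attention, movement), cross-trial
drift, spike-bleed, and behaviourally correlated pre-stimulus structure.
Consequently the PRE-window control is exactly uninformative here but
only approximately so in vivo, and absolute accuracies on synthetic
cohorts say nothing about accuracies on real data — the tests validate
the *procedure* (no leakage, correct accounting, correct statistics,
recoverable signal when one is planted), not the biology. Runtime values
are hardware dependent and only their accounting (per-sample
normalization, phase separation) is asserted.

## Interface note

The package is a library: the importable API plus `examples/` scripts are
the interface, and `scripts/acceptance.py` reproduces the headline
numbers; no shell CLI is provided since every entry point is a few lines
of Python against documented functions.
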