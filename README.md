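# lfpdecode

Decoding whisker stimuli from laminar local field potentials (LFPs) with
classical machine learning and a from-scratch Liquid State Machine — on
fully synthetic data.

## The problem

In a go/no-go task, a head-fixed mouse reports a 100 ms vibration of a
single whisker (intensity 0–100 % of maximal deflection) by licking a
water spout. A laminar multi-electrode probe records LFPs across cortical
layers L2/3–L6 of the corresponding barrel column. Two binary decoding
tasks arise per trial:

* **SD** (stimulus detection): was a stimulus presented? (label: intensity > 0)
* **RP** (response prediction): did the animal lick inside the +100–500 ms
  window of opportunity?

`lfpdecode` implements the complete analysis as a reusable, tested
pipeline and replaces the recordings with a synthetic cohort generator,
so every procedural claim is exercisable at desk scale: trial quality
control, causal filtering, feature construction, six classifiers, and
strict cross-individual validation.

## What is implemented

* **`lfpdecode.synth`** — cohorts of trials at 1 kHz spanning −420…+120 ms
  around stimulus onset: AR(1) background activity on a 25 µm-spaced
  laminar probe, a difference-of-exponentials evoked deflection (most
  negative 5–10 ms post-onset, largest in L4, amplitude linear in
  intensity), a monotone Weibull psychometric lick response, and
  injectable artifacts (saturation, bursts, 50 Hz line noise, early
  licks). Deterministic given a seed; archivable to disk.
* **`lfpdecode.preprocess`** — the four trial filters over −420…+120 ms
  (|v| ≥ 2 mV saturation; 20 ms windows in which all electrode pairs are
  Pearson-correlated; excess 50 Hz power; licks in [0, 100) ms), causal
  Butterworth filtering (first-order 150 Hz low-pass + sixth-order
  47–53 Hz band-stop), and layer assignment from the short-latency
  current-source-density sink.
* **`lfpdecode.features`** — RAW features (the filtered trace: 400 / 100 /
  500 samples for the PRE [−400, 0) / PERI [0, 100) / FULL windows per
  layer) and FFT features (single-sided amplitudes: 60 bins at 2.5 Hz up
  to 147.5 Hz for PRE, 15 bins at 10 Hz up to 140 Hz for PERI, 75 for
  FULL; bin 0 is the window mean), with Min-Max scaling anchored to the
  training set only.
* **`lfpdecode.lsm`** — a from-scratch Liquid State Machine: 135 leaky
  integrate-and-fire neurons on a 3×3×15 grid, 80 % excitatory,
  distance-dependent random connectivity `C·exp(−(d/λ)²)`, 1 ms steps
  matched to the LFP sampling, analog current injection of the trace, and
  a regularized logistic readout on exponentially filtered spike counts
  sampled across the window.
* **`lfpdecode.baselines`** — Decision Tree, Random Forest, XGBoost,
  logistic regression (GLM), and an in-repo random-convolutional-kernel
  transform (RCKT) with max/PPV pooling, all behind one
  `fit`/`predict_proba` contract with small documented hyperparameter
  grids.
* **`lfpdecode.validation`** — leave-one-mouse-out splits × 10 bootstraps
  (40 evaluations for four mice), class balancing by downsampling,
  stratified 3-fold grid search, ROC/PR AUC + Brier metrics, Platt
  calibration on a 33 % hold-out, Wilcoxon signed-rank and Fisher exact
  tests, and per-sample runtime accounting.
* **`lfpdecode.experiments`** — scenario runner for the benchmark grid
  (task × window × feature type × layer × intensity subset), the
  peri-length × intensity sweep, and the imbalanced-data/calibration
  analysis.

## Worked example

```bash
python examples/03_benchmark.py
```

runs the 40-evaluation cross-individual protocol for the peri-stimulus
RAW stimulus-detection scenario (0 vs 100 % intensity) and prints:

```
scenario SD:PERI:RAW:L4:0-100: 40 evaluations per algorithm
algorithm  median acc  median ROC AUC  train s/sample
DT             0.955          0.958       1.72e-05
RF             0.955          1.000       1.53e-03
XGB            0.955          0.954       1.18e-04
RCKT           0.958          1.000       1.72e-04
GLM            1.000          1.000       4.93e-05
LSM            0.909          0.972       1.38e-04
```

Each row aggregates 40 models, every one tested on a mouse never seen in
training: the evoked deflection in layer 4 separates stimulus from catch
trials across individuals, and the spiking LSM competes with the
conventional classifiers while admitting neuromorphic implementation.
Runtimes are wall-clock seconds normalized by set size. The other
examples cover cohort generation and archiving (`01`), QC and CSD layer
recovery (`02`), the shortened-signal sweep (`04`) and calibration on
imbalanced data (`05`).

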