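# Methods

`erpgraph` turns multichannel single-trial EEG epochs into
wavelet-coherence connectivity graphs per ERP component window and
frequency band, summarizes each graph with six surrogate-normalized
metrics, and discriminates two mental states with feature selection and
cross-validated classifiers.  This note documents the model, the
estimator choices, the synthetic-data generator, and the numerical
conventions, including where the design was genuinely open and what we
chose.

## Pipeline model

A trial is an epoch `x(t)` of C channels, sampled at `fs`, spanning
−200…1000 ms around stimulus onset.  For each ordered pair of channels
the wavelet auto- and cross-spectra are

    W_ab(t, f) = ∫_{t−δ/2}^{t+δ/2} S_a(τ, f) · S_b*(τ, f) dτ,   δ = c / f,

where `S_a` is the analytic Morlet CWT (center-frequency parameter
ω₀ = 6) and `c` is the number of integration cycles (default 3; the
window is truncated at the epoch edges).  Magnitude-squared coherence
is the normalized cross-spectrum

    WCoh_ab(t, f) = |W_ab| / sqrt(W_aa · W_bb)  ∈ [0, 1],

averaged over the samples of an ERP component window (defaults
N100 = 70–140 ms, N200 = 150–250 ms, P300 = 250–500 ms) and over the
scales whose center frequency falls in a band (delta 1–4, theta 4–8,
alpha 8–13, beta 13–30 Hz).  The result is one symmetric C×C matrix
with unit diagonal per (trial, component, band).

Each matrix is proportionally thresholded — the top `sparsity`
(default 0.2, the middle of the conventional 0.1–0.3 range) fraction of
channel pairs is kept with its weights, ties broken by channel-pair
order — and summarized by six metrics: node strength and Onnela
clustering per channel (local), and spectral graph energy
(Σ|eigenvalues|), global efficiency, transitivity, and characteristic
path length (global).  Path metrics use edge length 1/w; the
characteristic path length averages over connected ordered pairs only,
with the disconnected count available separately (harmonic averaging is
already captured by efficiency).  Clustering and transitivity use
weights normalized by the graph maximum, so they are invariant to an
overall weight scale.

Each metric is z-scored against an ensemble of `n_surrogates`
(default 100) surrogate graphs built by degree-preserving double-edge
swaps (10 attempted swaps per edge) followed by random reassignment of
the original edge-weight multiset; node count, degree sequence and
weight multiset are preserved exactly.  When rewiring cannot succeed
(e.g. a star topology) the surrogate falls back to weight permutation
on the original topology, and the ensemble is flagged.

Per trial the feature vector concatenates, for each component window in
the chosen combination, `[strength(1..C), clustering(1..C), energy,
efficiency, transitivity, path length]` — 2C + 4 features per
component, so 64 for a 30-channel montage with one component, 128 for
62 channels, 192 for three components at 30 channels.

Classification is within-subject, stratified k-fold (default 10)
repeated R times (default 100; the self-contained studies in this
repository use R = 10).  Feature ranking — two-sample t statistic,
ReliefF (k = 10 nearest hits/misses on min–max-scaled features, all
instances; k clamped to class size − 1 on small training folds), or
greedy MRMR on tertile-discretized mutual information — is re-fit
inside every training fold; the top `n_top_features` (default 20) enter
the classifier.  Classifiers: SVM with RBF kernel
K(a,b) = exp(−‖a−b‖²/s²), Fisher LDA without regularization, and the
single Euclidean nearest neighbor; features are standardized with
training-fold statistics.  Confusion counts accumulate over folds;
accuracy, sensitivity, specificity and F1 are computed per repeat and
averaged.

## Estimator design

**Scale grid.**  `scale_grid` produces `floor(log2 N) − 1`
logarithmically spaced center frequencies between a lower bound set
jointly by the signal length and the wavelet's time-frequency extent —
largest scale `T/(2√2)` seconds, i.e. `f_min = ω₀√2/(πT)` — and the
Nyquist frequency.  This coarse grid (~1 scale per octave) is exposed
because it is the transparent, minimal description of the transform;
but a single-voice grid cannot support a usable single-trial coherence
estimator at the delta band of a 1.2 s epoch: with c = 3 integration
cycles each smoothed estimate holds only ~1.5 independent samples and
the null bias is ≈ 0.7–0.9 regardless of true coupling.  The
production path (`coherence_tensor`) therefore uses a multi-voice
filterbank — 12 voices per octave spanning the analysis bands padded by
half an octave, clipped to the same extent/Nyquist bounds — and smooths
the auto- and cross-spectra with a one-octave moving average across
scale *before* the ratio, the standard practice of wavelet-coherence
estimators.  Time smoothing is exactly the δ = c/f boxcar above.  This
raises the effective degrees of freedom several-fold; the residual
small-sample bias (independent channels score ≈ 0.6 rather than 0) is
inherent to 1.2 s epochs at slow frequencies and is shared by all
trials, so it shifts but does not blur the class contrast.

**Precision.**  The spectra stream per scale in single precision by
default (`PipelineConfig.single_precision`), which halves memory
traffic; coherence values are then accurate to ~1e-6.  Identity-level
checks (self-coherence, amplitude invariance to 1e-9) use the double
precision path.

**Cone of influence.**  Not masked.  The CWT is computed on the full
epoch and windowed afterwards, which keeps component windows away from
the worst edge effects, but low-frequency estimates near the epoch
edges remain edge-contaminated; a documented limitation.

## SVM hyperparameters

The kernel scale is genuinely ambiguous in the tradition this pipeline
follows: a fixed unit kernel scale on ~20 standardized features makes
the RBF kernel nearly diagonal (‖a−b‖² ≈ 2d), collapsing the SVM into
a local voter no better than 1-NN.  We therefore tune both the box
constraint (log grid 1e-2…1e2) and the kernel scale
(s ∈ {1, √d/2, √d, 2√d}) by a seeded 5-fold search on the training fold
only — the unit scale remains in the grid, and no test-fold information
enters the search.

## Synthetic-data generator

The generator is the package's test bed and defines its study
conditions; it emulates a two-condition visual ERP session at 250 Hz,
30 channels (the standard 10–20 montage), −200…1000 ms epochs:

- **ERP morphology** — Gaussian-windowed deflections at 100 ms
  (−5 μV, 30 ms), 200 ms (−4 μV, 40 ms) and 350 ms (+8 μV, 80 ms) on
  every channel, identical across conditions (the planted effect is in
  connectivity, not amplitude).
- **Background** — per-band narrowband Gaussian noise (4th-order
  zero-phase band-pass of white noise), RMS 5/4/6/3 μV for
  delta/theta/alpha/beta, plus 2 μV white sensor noise.
- **Planted effect** — a condition-dependent reorganization of
  delta-band synchrony: two 8-channel assemblies (frontal F7, F3, Fz,
  F4, F8, FC3, FCz, FC4 and parietal P7, P3, Pz, P4, P8, CP3, CPz,
  CP4).  Members of an assembly receive `κ·s + √(1−κ²)·n` where `s` is
  the assembly's shared delta-band source and `n` an independent
  residual, so the asymptotic pair coherence is ≈ κ².  In condition A
  the frontal assembly has κ = 0.95 and the parietal κ = 0.35; in
  condition B the roles swap.  The within-assembly coupling gap between
  conditions is therefore 0.6.  The zero-gap null sets κ = 0.65
  everywhere.
- **Artifacts** — optionally, a fraction of trials receives a slow
  Gaussian transient (150 ms width) of specified peak amplitude on
  frontal channels, mimicking eye blinks at the level the max–min rule
  operates on; affected trials are recorded in provenance.

What the generator does *not* emulate: volume conduction and realistic
leadfields, 1/f spectral shape beyond the four-band mixture,
non-stationarity of coupling within an epoch, realistic blink/EMG
morphology, or inter-subject variability.  Passing tests therefore
demonstrate that the pipeline recovers a known connectivity contrast
through the full estimator/graph/selection/classification chain — not
that it attains any particular accuracy on real recordings.

## Self-contained studies and problem sizes

`erpgraph.evaluation.planted_effect_study` is the quantitative anchor
(also recomputed by `scripts/acceptance.py`): 200 trials per condition,
the default pipeline (three-component combo, sparsity 0.2, 100
surrogates, ReliefF top-20, SVM-RBF), stratified 10-fold
cross-validation with 10 repeats, for all four bands plus the zero-gap
null in delta.  Ten repeats (rather than 100) and 200 trials per
condition are the problem sizes used by this repository's studies;
they bound the Monte-Carlo error of a mean accuracy to well under one
percentage point.  Expected behavior: delta accuracy well above 85%,
theta/alpha/beta near chance (no planted effect there), null at
45–55%.

## Numerical conventions and degenerate inputs

- Sample ranges are 0-based and half-open; a component window must
  contain at least 8 samples at the working rate.
- Proportional thresholding keeps `ceil(sparsity × n_pairs)` edges;
  exact weight ties break by channel-pair lexicographic order (with a
  warning when all weights are equal).
- A zero surrogate standard deviation yields z = 0 with a warning;
  an empty graph has path length defined as 0 in the metric set (the
  standalone function raises).
- Rejection rules are pure predicates of their input; the kept set is
  the complement of the union of rejections and is order-free.
- The 0.1 Hz high-pass edge of the band-pass filter rings for tens of
  seconds; `bandpass` pads `filtfilt` with ≈ 3 periods of the low edge
  and should be applied to continuous data, not to cut epochs.
- All randomness flows from explicit integer seeds through
  `numpy.random.default_rng` / `SeedSequence`; identical seeds give
  byte-identical outputs.

## Known limitations

- The single-trial coherence bias at delta in 1.2 s epochs compresses
  true coherence contrasts (κ² = 0.90 vs 0.12 appears as roughly 0.85 vs
  0.63 after estimation); discrimination rests on the contrast, not
  the absolute level.
- ICA-based artifact decomposition is out of scope; the pipeline
  expects cleaned or synthetic data and offers only the threshold
  rules.
- The characteristic path length of a disconnected thresholded graph
  averages finite pairs only; comparing it across graphs with very
  different disconnected-pair counts conflates two effects (efficiency
  is the robust companion metric).
- EDF export covers the minimal 16-bit continuous layout (integer
  sampling rates only).
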