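# Methods

## The forecasting problem

A stay is a minute-indexed matrix of physiological signals plus six static
covariates. Samples are anchored at 1-based minutes `t ∈ {60, …, T−5}`:
the model sees the 60-minute history `X[t−59 : t]` of each signal and
predicts whether the 5-minute future `X[t+1 : t+5]` of one target signal
violates its outcome threshold (strict inequalities: min SAO2 < 93,
min ETCO2 < 35, min NIBPM < 60, max NIBPM > 110; drug outcomes test
whether the binary administration channel is ever 1). Internally all
indexing is 0-based half-open; the 1-based inclusive convention is mapped
once at the window boundary (`i = t − 1`, history `[i−59, i+1)`, future
`[i+1, i+6)`).

Labels are computed on raw recorded values — never on imputed or
standardized ones. A window whose future block has any missing value of
the target signal is excluded from that outcome rather than imputed: an
imputed future would fabricate the outcome, and exclusion is why each
outcome has its own effective sample count. Histories, in contrast, may
be imputed freely.

## Preprocessing

Per-variable means and population standard deviations are fitted on the
*training stays only* and reused everywhere (validation, test, foreign
sites), preventing leakage through normalization. Missing signal entries
are imputed with the train mean; standardization (zero mean, unit
variance — our reading of "unit mean and variance") applies only to
inputs of the sequence models. The tree downstream model receives
unstandardized features in clinical units; the optional MLP downstream
standardizes internally. A constant variable's sd is replaced by 1, so
standardizing degenerates to a shift. Drug channels are imputed to 0 and
never standardized. Splits are at the stay level (largest-remainder
rounding, ties resolved train → val → test) so overlapping windows of one
stay can never straddle a split boundary.

## Embeddings

*raw* is the identity on the 60-minute window. *ema* is
`(EMA(0.1), EMA(1), EMA(5), EMV(5))` with the recursions applied exactly
as printed, initialized at the first window value (EMA) and at zero
(EMV), the EMV recursion sharing one EMA state. Literal mode is the
default even for α = 5, where the recursion is formally divergent
(weights alternate in sign and grow); it remains deterministic, and tree
models are invariant to per-feature monotone scale, but a span
interpretation (smoothing factor `2/(α+1)`) is provided because α = 5
almost certainly descends from a span/decay convention in the
feature-engineering tradition. EMV initialization at 0 reflects that a
single point carries no deviation information.

The sequence embeddings use a single-layer LSTM (hidden size =
embedding dimension, 200 by default) with a linear task head, implemented
directly on numpy with full backprop-through-time; the only architectural
constraints we treat as fixed are the 60-step input, the task-specific
head widths (60 / 5 / 1 linear, 1 sigmoid), and the final-hidden-state
embedding with the head removed. Training uses Adam (lr 3·10⁻³ in the
benchmarks, 10⁻² default elsewhere), mini-batches of 128, global gradient
clipping at norm 5, early stopping on validation loss, and returns the
checkpoint with the lowest validation loss; the full loss curve is kept
for convergence comparisons. Weight initialization, batch shuffling and
everything downstream are driven by explicit seeds; a (seed, data) pair
reproduces a model bit for bit. Self-supervised regression targets
(auto/next/min) are computed on the standardized signal — the same space
as the inputs — keeping MSE magnitudes comparable across signals. `hypo`
models are trained per (signal, outcome) pair with binary cross entropy.
`rand` models are built and never trained (asserted by weight digest in
the tests). The jointly trained variant consumes all input channels at
once and forecasts the next 5 minutes of every channel (head width 5·V);
its extraction yields one shared embedding.

Models are serialized as single-file `.npz` bundles holding weights,
architecture, task, provenance chain, and the training-split
normalization statistics. **Under transfer, a foreign model standardizes
target signals with its own bundled statistics**, not the target's: the
bundle is then self-contained at a site that never sees source data. This
choice affects transfer results and is therefore stated prominently; the
alternative (re-standardizing with target statistics) is a one-line
change at the call site.

## Downstream model and evaluation

The downstream classifier is LightGBM with logistic loss (31 leaves,
learning rate 0.1, up to 200 rounds, early stopping after 20 rounds
without validation-AP improvement, single-threaded and deterministic);
these are our documented defaults, not claimed as anyone else's. Average
precision is computed step-wise over the score-sorted PR curve with tied
scores grouped into one threshold — the same convention as the
brute-force oracle in the test suite. ROC AUC is reported alongside but
AP is primary: at base rates of a few percent it is the informative
metric. Confidence intervals are percentile bootstrap over test windows
(99%, 200–1000 resamples); resamples without a positive are redrawn (at
most 10 attempts each) and counted. Percent improvement is
`100·(AP_method − AP_raw)/AP_raw`; cross-dataset pooling averages the
per-dataset means and the per-dataset standard errors — reproduced as
stated by its source even though it is not the usual variance-pooling
rule.

## Attributions

Interventional Shapley values for the tree model are computed exactly,
per (sample, reference) pair, in the model's native log-odds space. For
each leaf, the distinct features on its root path are classified against
the pair: features the sample satisfies but the reference does not must
be in the coalition (set A), the reverse must be out (set B), features
both satisfy are free, and a feature neither satisfies makes the leaf
unreachable. The leaf's indicator game then has closed-form Shapley
values `±v·(a−1)!·b!/(a+b)!` (sign by membership in A or B), summed over
leaves and trees and averaged over a seeded background subsample of
training windows (default 100). The test suite verifies exact agreement
with exhaustive 2^F subset enumeration on shallow ensembles and the
efficiency identity `Σφ + base = f(x)` to 10⁻⁶ everywhere. Per-variable
attributions *sum* (never average) a signal's feature attributions, which
keeps efficiency and puts signal attributions on the same log-odds scale
as the untouched static attributions. Efficiency holds in log-odds space
specifically; probabilities are a nonlinear transform away.

## The synthetic cohort generator

Each signal is an AR(1) latent process around a clinically plausible
baseline plus independent observation noise. Adverse episodes are
planted: a linear drift starts 30 minutes before the latent trace crosses
the threshold (per-episode depth jitter ≥ 1 guarantees crossing), holds 6
minutes, recovers. Benign near-miss dips — the same drift shape stopping
short of the threshold (relative depth < 1) — and transient single-minute
measurement artifacts on SAO2 (5% of minutes, 2–5 units deep, affecting
observed values only) make forecasting genuinely uncertain: whether an
unfolding excursion will cross is only decidable from the filtered level
and trend of a noisy history. SAO2 is deliberately long-memory
(ρ = 0.97, small innovations, observation noise 1.0): estimating its
level well requires smoothing over tens of minutes, which is what a
trained recurrent filter does and axis-aligned splits on single noisy
minutes do not. Phenylephrine pulses follow hypotension episodes with
probability 0.7 (epinephrine rarely), missingness is independent
per entry (2% default), and the ICU-style profile raises missingness of
everything except SAO2 to ~100%. Hazards were calibrated once so that
window-level base rates of the threshold outcomes land in the 1–11% band
reported for the real cohorts this generator emulates. Stays are pure
functions of (profile seed, stay index) via counter-based seeding, so
cohorts are order-independent and reproducible; the noiseless latent path
can optionally be stored for oracle analyses.

What the generator does *not* emulate: physiological mechanism (no
cardio-respiratory dynamics), cross-signal coupling beyond the drug
response, sub-minute structure, informative missingness, and real
artifact morphology. Passing benchmarks on it therefore demonstrates that
the pipeline recovers planted temporal structure under noise, covariate
shift, and transfer — not clinical performance.

## The pinned benchmark

The scaled-down study (`vitalembed.benchmark`) uses two hospitals of 300
stays (100–140 minutes each), three signals (SAO2, ETCO2, NIBPM),
16-dimensional embeddings, and hypoxemia as the outcome. The downstream
classifier sees labeled windows at stride 4 — the label-scarce regime in
which pretrained representations earn their keep — while the
self-supervised models train on the full stride-1 window stream and the
test split is scored densely (stride 1) for tight AP estimates. The
second hospital differs by gender ratio (57% → 38%), emergency fraction
(7.65% → 15.31%), blood-pressure/CO₂ baseline shifts, and a 1.5× higher
hypoxemic-event hazard (a sicker case mix); the signal dynamics and the
drift-precedes-event mechanism are shared, which is the premise that
makes cross-hospital transfer learnable. Each cohort seed is evaluated
with *both* hospitals as the target (models are trained once per
hospital and reused across directions; each hospital's split is fixed by
its own profile seed, so reuse leaks nothing), the two target scores are
averaged — the same aggregate-across-targets rule used for percent
improvements — and medians are taken across five fixed seeds. The
margins at this scale are honest but modest: the trained next-embedding
beats raw by a paired median of roughly one to two AP points, with
cohort-to-cohort variability of the same order, so individual cohorts
(and small seed sets, as in the acceptance script) can and do land on
either side; the transferred models retain most of the trained margin
on average; and the untrained random embedding hovers at raw's level
(its information loss and its compactness advantage roughly cancel on a
three-signal task). The decisive, scale-independent contrasts are the
fine-tuning convergence speed-up and the planted-relevance recovery;
the AP ordering is a real but small-sample-noisy effect at desk scale.
The fine-tuning comparison pairs warm-started and from-scratch runs of
the same architecture, config and seed, and compares epochs to the best
validation checkpoint under early stopping (patience 4).

## Known limitations

* The LSTM is single-layer with no regularization beyond early stopping;
  at desk scale this is adequate, at clinical scale it would not be the
  architecture of choice.
* The literal α = 5 EMA feature is numerically enormous (~10³⁵); harmless
  for trees, inappropriate as-is for linear or distance-based downstream
  models (use span mode there).
* Interventional Shapley cost grows with leaves × samples × references ×
  path features; it is exact, not approximate, so very deep ensembles on
  thousands of samples call for subsampling the background or the
  explained set.
* The bootstrap treats test windows as exchangeable; overlapping windows
  of one stay are correlated, so intervals are somewhat anti-conservative.
  Stay-level blocking would be the refinement.
* `aggregate_targets` reproduces the stated mean-of-SEs pooling rule; it
  is not a variance-correct pooled standard error.
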