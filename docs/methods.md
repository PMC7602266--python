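# Methods

This note records the models, conventions and design choices behind
`emgsign`, in the order the pipeline applies them.

## Signal model and feature extraction

Input trials are raw multi-channel sEMG sample matrices (default 600 samples
= 3 s at 200 Hz, 8 channels, arbitrary units; no calibration or filtering is
applied). Features are computed per channel on half-open sliding windows
`[start, start + window)` with window 600 and stride window/4 by default, so
a default-length trial yields exactly one window.

Time-domain statistics use the population convention throughout: STD is
`sqrt(mean((x - mean)^2))`, which makes `rms² = std² + mean²` an exact
identity (asserted in tests to 1e-10 relative). The log detector is the
geometric mean of `|x|` with magnitudes floored at `log_floor = 1e-12`
because idle EMG contains exact zeros where the logarithm is undefined; the
floor is the only deviation from the pure formula and is configurable.

Frequency-domain statistics operate on a Welch PSD: 128-sample Hann segments,
50% overlap, mean averaging, density scaling, no detrending. At 200 Hz this
gives ~1.56 Hz resolution over a 0–100 Hz span, appropriate for 600-sample
windows; integrated density is Parseval-consistent with the signal variance
(checked to 10% on white noise). Conventions that needed a decision:

* **MDF** is the smallest bin frequency at which cumulative power reaches
  half the total, with no interpolation — the discrete definition is
  bin-wise and interpolation would invent precision.
* **MNP** is implemented as the frequency-weighted form `Σ f·P / Σ f`. This
  deviates from the common mean power `Σ P / N`; the conventional form is
  exposed separately as `mean_power_conventional` so users can compare. The
  weighted form scales with amplitude squared, like a power, but emphasizes
  high-frequency bins.
* **PSR** uses the global peak frequency f₀, a half-band ε = 10 Hz and an
  analysis band defaulting to (0, Nyquist), all configurable; the peak
  interval is clipped to the band. ε and the band have no canonical values,
  so the defaults are documented choices.
* **PKF** ties break toward the lowest frequency, for determinism.

An all-zero window returns 0 for the ratio-type spectral features rather
than erroring, since idle segments are legitimate data; the underlying
functions do raise on all-zero spectra when called directly.

## Stacked bilinear user × motion model

One scalar observation is `y_{c,n}^{u,m} = z_uᵀ W_c x_n^m` with user factor
`z_u ∈ R^I`, motion factor `x_n^m ∈ R^J` and per-channel interaction matrix
`W_c ∈ R^{I×J}`. Data are stacked as `Y ∈ R^{CU×MN}`: **one vertical block
per channel**, rows within a block indexed by user, columns motion-major and
repetition-minor. A single function (`bilinear.stack_layout`) owns this
mapping. This channel-major row order is forced by the algebra: it is the
unique layout under which both compositions `Y = [W^ST Z]^ST X` and
`Y^ST = [W X]^ST Z` hold exactly (verified to 1e-10 on random factor
triples), where the stacked transpose (ST) transposes each of the C blocks
independently.

**Fitting.** X is initialized as the first J rows of Vᵀ from the SVD of Y.
Each full iteration updates Z as the first I rows of Vᵀ of `[Y Xᵀ]^ST` and X
as the first J rows of Vᵀ of `[Y^ST Zᵀ]^ST`; both updates are optimal
subspace fits given the other factor, so with the least-squares interaction
matrices `W_c = Z Y_c Xᵀ` (valid because the SVD rows are orthonormal) the
objective `E = Σ ||y - zᵀW_c x||²` is non-increasing. Row signs of every Vᵀ
are canonicalized (largest-magnitude entry positive) to make the fit
deterministic. Iteration stops when the relative change of E drops below
`tol` (default 1e-6) or the fit is numerically exact; `max_iter` defaults to
50 but noise-free instances in the model class converge in 1–2 iterations.
When J exceeds the rank of the update matrix, the extra rows of Vᵀ come from
the deterministic orthonormal completion; they span no additional signal and
do not affect the objective. Constraints: `I ≤ U` and `J ≤ MN` (the updates
take rows of U×U and MN×MN orthonormal matrices).

Z and X are identifiable only up to an invertible transform absorbed by W,
so all tests compare reconstructions and subspaces, never raw factor
entries.

**New-user adaptation.** Given calibration data `Y_new` (C blocks × N_cal
columns) for one designated motion m, three pseudo-inverse steps run in
closed form: `z_new` is the least-squares solution of
`Y_new^ST = [W X_m]^ST z`; the adapted interaction matrix is
`W_new = [Y_new^ST z_new⁺]^ST X_m⁺`; the calibration motion factors are
`X_new_m = ([W_new^ST z_new]^ST)⁺ Y_new`. Pseudo-inverses apply to the whole
stacked matrix with a relative singular-value cutoff of 1e-10·σ_max, and the
condition number of every step is surfaced in the result (small calibration
sets are rank-hungry; a flag marks conditioning above 1e8).

One consequence matters for deployment: `W_new` is a product through the
calibration data, so its rank is at most N_cal. The projector built from it
confines every projected factor to a min(C, N_cal)-dimensional slice of the
J-dimensional motion space, while the classifier's training factors (columns
of X) span all J dimensions. Unlabeled-data projection therefore defaults to
the **training** interaction matrix W combined with the adapted `z_new`; on
exactly bilinear data this recovers the model's own motion factors to
machine precision, whereas the W_new-projector loses most of the factor
energy. The fully adapted projector remains available
(`project_motions(..., use_adapted_w=True)`) and is the one that exactly
reproduces `X_new_m` on the calibration data.

## Feature selection

Permutation importance uses an 80/20 stratified within-subject split: a
classifier is trained once, then each feature in turn is shuffled across the
held-out trials (the whole per-trial block of that feature, jointly over
channels and windows, preserving temporal structure) and accuracy
re-measured, averaged over `n_repeats = 10` draws. Importance is exactly
`baseline − permuted`. Top-k selection sorts by importance with ties broken
by the fixed feature-name order. The pipeline default feature subset is
{RMS, LOG, AAC, PSR, MNP, MDF}.

## Classifiers

The LSTM is a single layer with 64 hidden units, final-step softmax readout,
forget-gate bias +1, trained full-batch with Adam at learning rate 1e-4 for
500 epochs by default (the operating point at which validation loss levels
off on this task family). It is implemented directly in numpy with manual
backpropagation through time, which keeps training bit-deterministic under a
fixed seed — same seed, same weights. Non-finite inputs are rejected at
construction and a non-finite loss aborts with a diagnostic.

The deterministic fallback is a nearest-class-centroid classifier on
time-averaged sequences. It is training-free and is what the fast tests and
the cross-user ordering checks use, so those results do not depend on
neural-network training variance.

## Evaluation protocols

*Within-subject*: stratified 80/20 split per motion, confusion matrix and
per-motion/per-subject/overall accuracies.

*Cross-user (LOSO)*: one fold per subject; train on all others, test on the
held-out subject. In bilinear mode the fold fits (Z, W, X) on the training
subjects' stacked features — latent dimensions clamped to the fold-feasible
ranges I ≤ U_train, J ≤ M·N_eff — adapts to the held-out subject from
calibration trials of a designated motion (default: the first half of that
motion's trials; a single trial would make the closed-form adaptation
rank-1), projects the remaining trials, and classifies the factors. The
classifier trains on the shared motion-factor columns of X. Calibration
trials are excluded from testing in **both** arms so the with/without
comparison shares folds, features, seeds and test sets and isolates the
factorization. Default (I, J) = (6, 120) before clamping.

Feature scaling: before any stacking, each feature is divided by a single
scalar — its standard deviation over the training subjects of the fold.
This makes amplitude features (a.u.) and spectral features (Hz)
commensurable without flattening the per-user channel structure that the
bilinear user factor is supposed to absorb, and uses no held-out data.

## Synthetic data

`generate_bilinear_instance` draws standard-normal factors, composes Y in
the stacked layout and optionally adds i.i.d. Gaussian noise — the
verification workload for the algebra (noise-free fits recover Y to
E/‖Y‖² ≤ 1e-8; with noise σ the per-entry residual approaches σ², which the
tests check to 20% over 10 seeds at dimensions where the model's degrees of
freedom are a small fraction of the data).

`generate_emg_cohort` synthesizes raw trials: per channel, Gaussian noise
band-passed to a per-motion, per-channel sub-band of 20–95 Hz (within the
100 Hz Nyquist), amplitude-modulated by a piecewise-linear envelope of 2–4
segments that models sequential sub-gestures; motions differ in envelopes,
active-channel subsets and bands (archetypes must be distinct). Trials
jitter the envelope timing (10%) and amplitude (15%). Each subject applies a
fixed confound to all of their trials: per-channel lognormal gains
(σ = 0.4), cross-channel mixing (strength 0.35 toward a random row-stochastic
mixture), and a circular electrode-rotation shift of up to 2 channel
positions, plus a small sensor noise floor (0.02). These strengths were
fixed a priori as "strong" inter-subject variation; the confound families
are deliberately the user-linear kind of structure a bilinear user factor
can absorb, which is what makes the with/without-factorization comparison a
fair test of the mechanism. The generator emulates burst texture and
inter-subject variation only — it is not a motor-unit simulation, it has no
crosstalk dynamics, fatigue, or force variation, and passing on it shows the
pipeline's mechanics work under the stated confound model, not that the
real-data accuracies of any particular cohort would be reproduced.

## Problem sizes

The test suite and the acceptance script run at desk scale by design:
reference-dimension fits at (I, J, C, U, M, N) = (6, 120, 8, 19, 20, 10)
(a 152×200 stacked matrix), cross-user cohorts of 5 subjects × 6 motions ×
10 trials over 5 generator seeds with the centroid fallback, and 10-seed
noise-calibration runs at (3, 10, 6, 15, 8, 10). These sizes exercise every
code path while keeping the full suite in the minutes range.

## Known limitations

* The frequency-weighted MNP is non-standard (see above); users wanting the
  literature's mean power should read `mean_power_conventional`.
* Closed-form adaptation estimates `z_new` inside the I-dimensional span of
  the training users' factors; a new user whose confound is far outside that
  span adapts poorly (visible as fold S02 in the worked example). More
  training subjects widen the span.
* The LSTM is CPU-only and full-batch; it is adequate for the trial counts
  here, not for large corpora.
* Only balanced cohorts (equal trials per subject × motion, equal windows
  per trial) can be stacked for the bilinear fit; unbalanced designs raise a
  validation error rather than silently subsetting.
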