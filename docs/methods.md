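# Methods

## The model

`KCSFCnet` decodes two-class motor-imagery EEG from raw epoched trials
`X ∈ R^{Nc×Nt}` (Nc channels, Nt samples).  Its premise is that class
information lives in the *pairwise spectral dependence* between channels
rather than in any single channel's waveform.  For a stationary kernel,
the kernel evaluation of two signals is an integral of their cross-spectral
density over the kernel's effective bandwidth, so a Gaussian kernel applied
to *band-filtered* channel signals estimates their cross-spectral
distribution inside the filter's passband.  The network makes both halves
learnable:

1. **Temporal filtering.**  Nf bias-free 1-D convolution filters
   `w_f ∈ R^{Δt}` (valid mode, stride 1) are applied per channel, giving
   features `z_{f,c} ∈ R^{Nt−Δt+1}`.  Each learned filter selects a
   frequency band; `KCSFCnet.aggregate_frequency_response` exposes
   `Σ_f |FFT(w_f)|²` so the tuned bands can be inspected.  One caveat for
   interpretation: batch normalisation renormalises every filter map, so
   the network is scale-invariant to filter amplitude and *untuned*
   filters keep whatever spectral peaks their (small) weights happen to
   have.  When looking for a recovered band, inspect the per-filter
   spectra `|FFT(w_f)|²` individually — on planted-coupling data at least
   one filter peaks inside the planted band, while the plain sum can be
   dominated by an idle filter's incidental peak.
2. **Kernel connectivity.**  For every channel pair c < c′ and filter f,
   `κ_G(z_{f,c}, z_{f,c′}) = exp(−‖z_{f,c} − z_{f,c′}‖² / 2σ²)` with one
   global learnable scale σ.  Averaging over the Nf filters yields the
   trial's connectivity vector `p ∈ [0,1]^{Nc(Nc−1)/2}` (the vectorised
   strict upper triangle of a symmetric matrix with unit diagonal).
3. **Readout.**  Batch normalisation, ELU, dropout, then an affine softmax
   layer `v ∈ R^{M×2}, b ∈ R²` on the M = Nc(Nc−1)/2 pairs.

Batch-normalisation stages sit after the convolution (per filter map,
2·Nf parameters) and after the filter average (one map, 2 parameters);
moving statistics are not trainable.  The trainable total is
`Nf·Δt + 2Nf + 2 + M·Ny + Ny + 1` — 4301 for the 64-channel, Nf=4, Δt=64
configuration, an order of magnitude below typical deep EEG decoders.

### Training

Full-batch Adam (learning rate 1e-3, 500 epochs, no callbacks or
schedules) minimises mean categorical cross-entropy over
Θ = {w_f, σ, batch-norm scale/shift, v, b}.  σ is stored as ρ = log σ, so
positivity needs no constraint.  After every update the max-norm
constraints are re-projected: each conv filter onto ‖w_f‖ ≤ 2.0, each
readout column onto ‖v_{:,y}‖ ≤ 0.5.  Forward and backward passes
(including the whitening backward pass of both batch normalisations and
the kernel's gradients with respect to the features and ρ) are implemented
directly on numpy arrays; the test suite pins every analytic gradient
against central finite differences at 1e-4 relative tolerance in float64.
Training runs in float32 by default (`dtype` switches precision).

σ is initialised by the median heuristic — σ² set to half the median
squared feature distance over all trials, filters and pairs of the
training batch at the initial weights — so the initial kernel values are
well spread in (0,1); an all-zero batch falls back to σ = 1 with a
warning.  Filters start as small Gaussian noise (std 1/√Δt), the readout
as Glorot-uniform, and one seeded generator drives initialisation and
dropout masks, making `fit` bit-reproducible for a fixed `random_state`.

### Degenerate inputs and numerical choices

Predicted labels use argmax with the lowest index on exact ties.  A NaN
loss aborts training with a diagnostic rather than silently continuing.
Inference uses the running batch-norm statistics (momentum 0.1) and no
dropout, so repeated calls are identical.  Connectivity values are exact
kernel outputs and therefore always within [0,1]; channels with identical
signals give connectivity 1 by construction.

## Preprocessing

Raw trials are (i) downsampled to 128 Hz by Fourier-domain truncation,
(ii) bandpassed 4–40 Hz with a fifth-order Butterworth, (iii) clipped to
the motor-imagery window 0.5–2.5 s after the cue (half-open in samples,
giving exactly 256 samples at 128 Hz), in that fixed order.  Filtering is
zero-phase (forward–backward, effective order 10) by default: the epoch of
interest is short, and group delay would shift it against the cue;
`zero_phase=False` restores a causal single pass.  An optional amplitude
threshold can drop high-voltage trials; it is off by default because the
synthetic data contain no artifacts.

## Evaluation protocol

Per subject: five *stratified* shuffled 80/20 splits, a fresh model per
split, and held-out accuracy, Cohen's kappa and ROC-AUC (sklearn
implementations; the tests check them against brute-force pair counting
and the contingency closed form).  Stratification matters: in a balanced
dataset a plain shuffle makes the training-side class imbalance
anti-correlate with the held-out side, and a model that leans toward its
training majority then scores systematically *below* chance on no-signal
data, corrupting the negative control.  Stratified splits keep both sides
at the dataset ratio and restore chance-level behaviour under the null.

The filter count Nf is grid-searched over {2,3,4} on the same five splits
per candidate (shared splits reduce selection variance; ties break toward
the smaller model).  Reporting the winner's own CV folds carries a mild
optimism bias — the selection and the report use the same resamples — and
is done deliberately to mirror the original protocol.

The score matrix condenses each subject into six [0,1] columns: mean
accuracy, mean normalised kappa ((κ+1)/2, applied per fold *before*
aggregation so the spread is also bounded), mean AUC, and the complements
1 − std of each (population std over folds).  Higher is uniformly better.

## Group analysis and interpretation

Subjects are clustered on their score-matrix rows by k-means (k = 3,
10 restarts, seeded) and the clusters renamed G I/G II/G III by decreasing
centroid mean accuracy.  A PCA first component (sign-aligned with the
accuracy column) orders subjects best-to-worst; `transfer_labels` assigns
new subjects to the fitted centroids without refitting (ties to the best
group).  t-SNE (perplexity 10, seeded) lays out the score rows in 2-D.

For interpretation, each channel pair's trial-wise connectivity values are
contrasted between classes with a two-sample Kolmogorov–Smirnov test
(exact null distribution up to pooled size 25, asymptotic beyond); pairs
with raw p ≤ 0.05 are retained.  **No multiple-testing correction is
applied** — deliberately, so the retained set has per-connection, not
family-wise, error level; the type-I simulation in the tests confirms the
per-pair false-positive rate sits at the nominal α.

The pruned pattern is summarised by a quadratic Rényi entropy.  The
reference for this quantity gives no formula for pruned connectivity
matrices, so it is operationalised here over the significance-weight
distribution: w_i = 1 − p_i for significant pairs, q = w/Σw,
H₂ = −log₂ Σ q_i² (0 when at most one pair survives, log₂ m for m equally
weighted pairs).  This makes the intended monotone link — more, and more
evenly spread, discriminative connections ⇒ higher entropy — exact and
testable.  A spectral variant (same functional on the normalised singular
values of the masked weight matrix) is available via
`renyi_entropy(..., variant="spectral")` for comparison.

Channel relevance maps come either from the pruning (summing 1 − p over a
channel's significant pairs) or from the readout weights (summing
class-averaged |v| over a channel's pairs — per-class maps can be obtained
by slicing `readout_weights_` directly); both are max-normalised.  Edge
lists keep pairs at or above the 99th percentile of connectivity strengths
min-max normalised *jointly across the supplied subjects*, matching a
cross-subject comparison; scalp coordinates for topographic export come
from the standard 10-05 montage via mne.

## Synthetic data

The generator emulates the statistical skeleton the method targets:
independent 1/f (pink) background noise per channel (unit variance, so
`snr` is interpretable as coupled-source variance per affected channel),
and per coupling one band-limited white source added identically
(zero-lag) to both channels of a pair on trials of one class.  The default
subject — 80 balanced trials, 16 channels, 2 s at 128 Hz, an 8–13 Hz
coupling on channels (0,1) for class 1 and an 18–24 Hz coupling on (2,3)
for class 0, snr 2 — is the fixture used throughout the tests and the
acceptance script; snr=0 is an exact negative control.

A statistical subtlety of that control: within one fixture, all five CV
folds re-score the *same* random label assignment with a model that
memorises its training noise, so the held-out predictions are strongly
correlated and the fixture's CV accuracy scatters around 0.5 with a
standard deviation near 0.1 — several times the binomial spread of 80
independent predictions.  The chance-level test therefore averages the
CV accuracy over three null fixtures (independent label assignments),
which brings the binomial 95% band to roughly 2.4σ coverage of the true
null distribution; a single-fixture check against that band would fail
for about one seed in four without any defect being present.

What the generator does **not** emulate: volume conduction (every real EEG
channel mixes every source), ocular/muscular artifacts, nonstationary
drifts, and per-subject spectral idiosyncrasies.  Passing tests therefore
demonstrate that the pipeline recovers planted cross-channel spectral
dependence at realistic noise levels and stays at chance without it — not
that it attains any particular accuracy on recorded EEG.

## Problem sizes

The default test and acceptance runs use the fixture above (80 trials, 16
channels) for the cross-validated checks, a compact 40-trial, 8-channel
variant for unit-level behaviour, and 200 replications of a 40-trial,
15-pair null for the type-I simulation — sizes chosen so the whole suite
runs comfortably on a single CPU while leaving the statistical checks
well-powered.  The pipeline's default synthetic cohort (six subjects with
snr from 0.2 to 3) uses 40 trials of 8 channels and 150 training epochs
per fit for the same reason; all of these are configuration values, and
the study-scale settings (500 epochs, Nf grid {2,3,4}, 5 folds) remain the
defaults of the estimator and protocol objects.

## Known limitations

* Binary classification only; the readout is two-class by construction.
* One global σ is shared across filters; per-filter scales are a possible
  extension but depart from the single-σ parameter set.
* The average pooling over filters realises the expectation over the
  filter bank; alternative poolings (max, learned weights) are not
  implemented.
* Grid-search optimism (see above) is inherited from the mirrored
  protocol.
* On recorded data the optional EDF/matrix loaders are deliberately thin;
  anything beyond the documented container format must be converted first.
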