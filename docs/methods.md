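# Methods

This note records the models and procedures implemented in `mdwhiten`, the
assumptions behind them, the choices made where the design was genuinely
open, and what the synthetic experiments can and cannot show.

## 1. Radar signal model and micro-Doppler simulation

**Model.** An FMCW radar transmits linear chirps (carrier `fc`, bandwidth
`B`, duration `Tc`, chirp rate `alpha = B/Tc`). A human body is modelled as
a small set of point scatterers, each with a slow-time range trajectory
`r_i(t)` and reflectivity `A_i`. After I/Q demodulation the complex
baseband return of the scene is the superposition

    s(t) = sum_i A_i exp(j 2 pi ((fD_i - alpha tau_i) t - fc tau_i)),

with two-way delay `tau_i = 2 r_i / c` and Doppler
`fD_i = -2 fc (dr_i/dt) / c`. The simulator evaluates `tau_i` and `fD_i`
once per chirp and holds them constant within the chirp (stop-and-hop),
which is the standard FMCW simulation convention; Doppler trajectories are
obtained numerically (`np.gradient`) from the sampled range.

**Processing chain.** The sampled matrix `s(n1, n2)` (fast time x slow
time) is DFT'd along fast time with a `1/N1` normalization to give the
range map `R(p, n2)`; the range bins spanning the subject (plus one guard
bin each side) are summed into a slow-time signal `v(n2)`; its spectrogram
(squared-magnitude STFT; Hann window 256, hop 2, 2048-point DFT,
DFT-shifted so zero Doppler is centered) is the micro-Doppler signature.
The signature is mapped to dB (clipped 40 dB below the peak), cropped to
+/-200 Hz Doppler, flipped so positive Doppler points up, bilinearly
resized to 75x75, and linearly stretched to integer pixel values 0..255.

**Sign conventions.** Implementing the baseband phase literally against the
forward-DFT kernel puts a target at the aliased beat bin
`N1 - 2 B r / c (mod N1)`; `RadarParams.beat_bin` encapsulates this and all
range-gating uses it consistently.

**Range gating vs Doppler fidelity.** Summing a *narrow* window of range
bins leaves a residual beat-leakage phase in `v(n2)` that biases the
apparent Doppler of a moving target by about `B vr / c` (~2 Hz at 1.5 m/s
with 400 MHz). This is a property of partial Dirichlet-kernel sums, not a
bug; it is invisible at the exported image scale (~5.3 Hz per pixel). When
the chain's Doppler fidelity is measured against the analytic
`fD = 2 fc vr / c` at the zero-padded bin resolution (0.49 Hz), the test
sums *all* range bins, for which `v(n2) = s(0, n2) = exp(-j 2 pi fc tau)`
holds exactly by the DFT sum identity and the ridge is unbiased. Both
configurations are valid instances of "the range bins of interest"; the
single-target fidelity scene has no clutter to exclude.

**Radar defaults** (configurable): `fc = 5.8 GHz`, `B = 400 MHz`,
`Tc = 1 ms` (1 kHz chirp rate), 128 fast-time samples per chirp, 2.4 s
dwell (2400 chirps). These match a common 5.8 GHz healthcare-sensing radar
configuration and give +/-500 Hz unambiguous Doppler.

## 2. The synthetic activity population

**What it emulates.** Six activity classes with the canonical micro-Doppler
morphologies: walking (periodic torso + limb sinusoids with a bulk
approach velocity), sitting down / standing up (short monophasic torso
transients of opposite sign), bending (biphasic out-and-back transient),
drinking (small, slow arm transient), and falling (large, fast transient —
the "waterfall" excursion). Each simulated subject carries kinematic
perturbations drawn once per subject (gait/transient speed 0.7-1.3x, limb
amplitude 0.4-1.6x, standoff range 1.5-4 m, activity onset 0.2-1.4 s) and
shared across that subject's recordings; each repetition adds further
jitter (onset, phases, per-scatterer reflectivity, displacement and
duration scales) plus a fresh complex-noise realization at -5 dB baseband
SNR (the processing chain contributes ~45 dB of integration gain, so
signatures remain visible but textured). The population geometry matches
the downstream experiments: 95 signatures per class from 33 subjects
repeating each activity 2-3 times (29 subjects x 3 + 4 x 2), 570 images
total.

**Difficulty calibration.** The variability and noise defaults were set so
that the base CNN's 50/50 accuracy lands in the high-80s/low-90s — the
operating regime in which normalization choices matter and which measured
activity datasets of this kind occupy — rather than at a saturated ceiling
where all classifiers tie at ~100%. A nearest-centroid classifier on raw
pixels reaches ~60-65% on the default population (chance is 16.7%).

**What it does not emulate.** Electromagnetic scattering (RCS aspect
dependence, multipath, occlusion between body parts), true articulated
biomechanics, non-normal incidence aspect angles, clutter from other
movers, and the exact (unpublished) crop/scaling used to produce measured
75x75 datasets. Conclusions from the synthetic experiments are therefore
qualitative (orderings, decorrelation behavior), not quantitative
predictions of accuracy on measured data.

## 3. Normalization layers

All layers operate on the unrolled conv activation batch `X in R^{d x m}`
(`d` = channels, `m` = batch size x spatial positions), the convention
under which a conv channel is one feature.

**Batch normalization.** Centering and per-feature scaling with the biased
(1/m) variance, `eps = 1e-5` diagonal loading, followed by a learnable
per-channel affine. Running means/variances for inference are exponential
moving averages with momentum 0.1.

**IterNorm batch whitening.** The whitening matrix `W ~ Sigma^{-1/2}` of
the trace-normalized covariance is computed with Newton's recursion
(`P_k = (3 P_{k-1} - P_{k-1}^3 Sigma_N)/2`, K iterations,
`W = P_K / sqrt(tr Sigma)`). Numerically the recursion is evaluated in its
coupled, self-correcting form (`T = (3I - Z)/2; P <- P T; Z <- T Z T`,
`Z_0 = Sigma_N`), which yields the same iterates in exact arithmetic (all
factors are commuting polynomials in `Sigma_N`) but is stable long past
convergence, where the one-matrix form amplifies roundoff once
`cond(Sigma_N)` exceeds ~2.4. The training default is `K = 5`; `K = 20`
reproduces the eigen-decomposition `Sigma^{-1/2}` to ~1e-14 on
well-conditioned batches. Gradients propagate through the batch mean, the
covariance and every Newton iterate via the package's reverse-mode engine.
Running inference statistics: EMAs of the batch mean and of `W` (momentum
0.1). A learnable per-channel affine follows, for the same
representation-restoration reason as in BN; removing it measurably hurts
accuracy even though a linear layer follows (optimization, not
expressivity).

**Whitening + rotation.** Any orthogonal `Q` gives another valid whitening
matrix `Q^T W`. The rotation module aligns latent axis `i` (label-sort
order; the first `Nc` of `d` axes) with class `i` by ascending

    J(Q) = sum_i (1/m_i) q_i^T XW_{c_i} 1,

the summed mean activation of each class along its axis, under
`Q^T Q = I`. The ascent primitive is a Cayley retraction: with Euclidean
gradient `G` (class means in the first `Nc` columns) and skew-symmetric
relative gradient `A = Q G^T - G Q^T`,
`Q <- (I + eta/2 A)^{-1} (I - eta/2 A) Q`, which preserves orthogonality
to machine precision (polar-factor re-orthogonalization is triggered if
drift ever exceeds 1e-6). Because the Cayley map preserves `det Q`, a
single ascent explores one component of O(d); `optimize_rotation` runs
both components (identity and one reflection seed) and returns the better
endpoint, which is what a brute-force comparison over all 2-D orthogonal
matrices requires.

Inside the network the rotation layer takes one Cayley step per training
batch, with two stabilizations that per-batch updates need at batch size
10 (fewer than two samples per class per batch):

* the gradient uses an exponential moving average (momentum 0.1) of the
  per-class mean whitened activations instead of the raw batch means,
  which are pure noise at this batch size;
* each step is treated as a re-parameterization: rotating the latent axes
  changes the layer output by a known linear map, and the next layer's
  input channels are counter-mixed by its inverse, so the network function
  is preserved (verified to float precision) while the axes align. Without
  this, inserting or updating the rotation mid-training costs 15-25
  accuracy points, because a few fine-tuning epochs cannot re-adapt the
  downstream weights to a moving basis.

Classes absent from a batch contribute nothing to the moving average that
batch. The layer order is whiten -> rotate -> affine; the diagonal affine
rescales the aligned axes (it cannot re-mix them), and the output
covariance stays diagonal, preserving the decorrelation property.

## 4. Classifier and training protocol

Three blocks of `3x3 same-padded conv -> ReLU -> 3x3/stride-3 max-pool ->
normalization` with 32/64/128 filters (spatial pyramid 75 -> 25 -> 8 -> 2),
dropout 0.15, and a fully-connected 6-way softmax head; 96,198 trainable
parameters. Conv weights use He fan-in initialization (seeded); the output
layer is zero-initialized so the untrained softmax is exactly uniform
(initial cross-entropy `ln 6`). Pixel values are divided by 255.

Training: cross-entropy, SGD with momentum 0.9, batch size 10, up to 30
epochs, learning rate decayed 10x every 7 epochs; last short batch kept
unless of size 1 (whitening undefined), which is dropped. Initial rates
per variant: 0.01 (base), 0.01 (model 1), 0.001 (model 2 fine-tuning) —
configurable, and results are sensitive to them. Model 2 is warm-started
from a trained model 1 (convolutions, head, whitening running statistics
and affine are copied; `Q = I`) and fine-tuned for 5 epochs with per-batch
rotation updates. Final-epoch weights are evaluated; no validation set or
early stopping. Everything is reproducible bit-exactly from a master seed;
per-trial seeds derive from it by a fixed counter scheme
(`SeedSequence([master, trial])`).

All tensor arithmetic, including the CNN, runs on the package's own
reverse-mode autodiff over numpy (`mdwhiten.autodiff`): convolution and
pooling are im2col matrix products with hand-derived, finite-difference-
verified backward rules; all other gradients compose from graph
primitives. Training uses float32; oracle computations use float64.

## 5. Experiments and diagnostics

* **Repeated stratified splits**: for each split (20/80, 50/50, 80/20) and
  trial, a class-stratified disjoint train/test partition; mean/std
  accuracy and trial-averaged row-normalized confusion matrices per
  variant.
* **Single-layer replacement**: the base model with exactly one BN layer
  swapped for a whitening layer (trained from scratch under the same
  protocol; the rotation variant updates its one `Q` per batch).
* **Subject-wise holdout**: 27 training / 6 test subjects, disjoint in
  person identity.
* **Correlation maps**: absolute Pearson correlation of every channel pair
  at each normalization output over a test set, all spatial positions as
  samples; zero-variance channels are flagged and assigned correlation 0.
* **Top-activated signatures**: a sample's activation on an axis is the
  spatial mean of that channel (spatial max available); per class axis the
  argmax test sample is reported with its true label.
* **Empirical receptive fields**: 32x32 masking patches at stride 5 (81
  positions on a 75x75 image), filled with seeded uniform noise over the
  image's intensity range (zero-fill available); the reduction in axis
  activation per position forms the map, highlighted at the top decile.

## 6. Problem sizes used by the test suite and acceptance script

Whitening oracles run 200 batches with `d in {2,4,8,16}`, `m = 64 d`
(standard-normal entries with random mean offsets; correlated batches are
exercised in the unit tests). The gradient check uses `d=3, m=8, K=5`.
Rotation optimality runs 20 random 2-D problems against a 1e-4-resolution
angle grid, and 1000 consecutive updates for orthogonality drift. The
end-to-end experiment uses the default 570-signature population, the
50/50 split, 5 trials, 30 epochs (5 for the model-2 fine-tune), batch 10.

## 7. What the synthetic experiments show — and what they do not

The decorrelation claim reproduces sharply: across trained models the mean
off-diagonal |correlation| at whitening-layer outputs is ~0.07-0.10 versus
~0.29-0.51 at the BN outputs of the base model, at every layer (the
acceptance script recomputes these). The *accuracy* advantage of the
whitening-aided variants reported on measured radar data does not emerge
on this synthetic population: with per-variant tuned learning rates the BN
base model averages ~92% at the 50/50 split against ~90% for the whitening
variants, and the gap widens at 20/80. A plausible mechanism: in the third
block the unrolled batch has 40 columns against 128 channels, so the
batch covariance is rank-deficient and the trace-normalized Newton
recursion amplifies its noise-only nullspace directions — a cost BN does
not pay — while the synthetic signatures are otherwise well-conditioned
enough for BN-based optimization to succeed. Whether whitening helps
accuracy is therefore data-dependent; the package reproduces the
mechanism and the decorrelation, and reports the accuracy comparison as
measured.

## 8. Known limitations

* The rotation layer's function-preserving compensation is exact for the
  orthogonal part and the affine scale; the shift term leaves a
  second-order residual at padded convolution borders (zero at
  initialization, negligible for the small per-batch rotations used).
* Whitening assumes the unrolled batch covariance is informative;
  at `d = 128` with 40 columns per sample it relies on the spatial
  positions as samples.
* The synthetic population is a controlled emulation; orderings observed
  on it support the implementation's correctness and the qualitative
  behavior of the layers, not field performance claims.
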