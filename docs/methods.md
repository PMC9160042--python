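# Methods

This note records the models implemented by `aggrgan`, the defaults and why
they were chosen, the numerical decisions taken where the procedure was
genuinely open, and what the synthetic test conditions do and do not show.

## Pipeline overview

One run consists of: (1) train three base generative models on a set of
reference slices; (2) draw one sample per model per reference; (3) rank the
three samples by SSIM or PSNR against the reference, fuse the best two with
edge-priority weights; (4) refine each base sample and each fused image by
style transfer toward the reference; (5) score all eight method variants
(3 base, 3 base+style, 2 aggregates) with the four-metric suite and report
per-image scores plus mean and max statistics. Every stage draws all of its
randomness from the run seed, so two runs with the same configuration are
bit-identical.

## Image-quality metrics

All metrics operate on 8-bit images with peak intensity 255.

* **SSIM** is computed *globally*: one mean, one variance and one covariance
  per image, population (1/N) estimators, stabilizers c₁ = (0.01·255)²,
  c₂ = (0.03·255)². This is the written form of the index, not the sliding-
  window estimator common in imaging toolkits; a windowed variant
  (`compute_ssim_windowed`) exists behind a flag for comparison.
  Comparability caveat: published SSIM tables rarely state window policy or
  constants, so absolute values are comparable only within one convention.
* **PSNR** = 20·log₁₀(255/√MSE); identical images return `math.inf`, a
  sentinel that sorts above every finite score so degenerate cases cannot
  crash table generation.
* **Histogram KL**: KL(P‖Q) over the 256 intensity bins in nats. Real
  images guarantee empty bins, where the divergence is undefined, so both
  histograms receive additive smoothing ε = 1e-10 per bin and are
  renormalized. Gibbs' inequality (KL ≥ 0) survives this scheme; the
  property is tested on 1000 random histogram pairs.
* **Sharpness difference** SD = 10·log₁₀(255²/∇), where
  Δf(i,j) = 2f(i,j) − f(i−1,j) − f(i,j−1) and ∇ is the mean absolute
  difference of the two gradient maps. The first row and column reference
  out-of-grid pixels; replicate-border extension defines Δ on the full grid
  so the 1/(mn) normalization is exact. Gradient-identical images (e.g. two
  constants) return the infinite sentinel.

Every metric is validated against an independently coded double-loop
implementation at 1e-9 on random images up to 8×8.

## Aggregation

Candidates are ranked by the chosen metric; ties break toward the lower
candidate index for determinism. Sobel magnitudes (standard 3×3 kernels,
reflect borders) are smoothed with a truncated Gaussian (default σ = 1.0,
radius round(3σ)); the blend weight of candidate 1 at a pixel is
g₁m₁/(g₁m₁ + g₂m₂), falling back to m₁/(m₁+m₂) where both smoothed edge
values are zero. The fused pixel is the convex combination rounded
half-to-even.

Two decisions here are this package's own formalizations and are flagged
as such:

* The multiplicative g·m weight rule. "Edge priority scaled by metric
  score" fixes what must drive the weights — the per-pixel smoothed edge
  value and the image-level metric — but not a closed form. The implemented
  rule is the simplest form that reduces correctly in every degenerate
  limit (equal edges and scores → 0.5 everywhere; one candidate edgeless →
  the other dominates; edge-free pixels → metric-proportional split).
* Sentinel and sign handling of the scores: an infinite PSNR among the
  selected pair is rank-transformed (2 : 1) so weights stay finite, and
  negative SSIM clamps to zero with an equal split if both clamp.

Note the radius-3σ truncation bounds how exactly the Gaussian semigroup
identity (twice at σ vs once at σ√2) can hold: the agreement is ~1e-4 on an
impulse, which is what the property test asserts against.

## Base generative models

Architectural template (widths config-exposed via `base_channels`, default
16): generators project the 100-dimensional standard-normal latent to a
(4·c, S/8, S/8) tensor and double the resolution three times; all filters
are 4×4; Tanh output in [−1, 1]. DCGAN-1 upsamples by nearest-neighbour
followed by a stride-1 convolution; DCGAN-2 uses stride-2 transposed
convolutions — the two paths deliberately differ only in the upsampling
mechanism (and parameter count). The shared discriminator is three stride-2
4×4 convolutions with LeakyReLU(0.2), batch normalization after the first
block, dropout 0.25 after every layer except the final fully connected
sigmoid layer. The Wasserstein-divergence model is fully connected in both
generator (100→128→256→S²) and critic (S²→256→128→1, no terminal squashing,
no batch norm).

Losses: the DCGANs use the non-saturating generator loss (maximize the
probability of the discriminator being wrong); the saturating two-player
value is exposed as `minimax_value` for completeness. The critic objective
adds k·E[‖∇f(x̃)‖^p] at per-pair uniform convex combinations x̃ of real and
fake samples; k = 2, p = 6 (the standard divergence settings; the objective
itself requires only p > 0) and the penalty is differentiated through the
critic parameters
exactly — the in-repo autograd supports double backprop for the dense and
elementwise operations the critic is built from (convolution backward is
first-order only, which the DCGAN losses need and nothing more).

Optimizers are Adam with β₁ = 0.5, β₂ = 0.999 — the DCGAN convention,
which fixes the betas that the optimizer choice alone leaves open. Batch
normalization always uses current-batch statistics. Training alternates
one discriminator step
and one generator step per batch; any non-finite loss aborts with a
diagnostic.

Named profiles: `paper` carries the full-scale settings
(batch/lr/epochs = 64/2e-4/1000 for DCGAN-1, 128/2e-4/650 for DCGAN-2,
32/1e-3/1000 for the WGAN); `desk` is the CPU-scale profile used
throughout the test suite — image size 32, 50 epochs, 64 training phantoms.
Desk-scale runs are smoke tests of the training mechanics, not attempts at
sample quality.

## Style transfer

The optimization variable is initialized at the content image (this makes
the zero-iteration contract exact; noise initialization is the obvious
alternative and is not used). Optimization runs in unit-domain floats;
output is clamped to [0, 1] and converted to uint8. The objective weights
are w_cont = 5, w_sty = 100, w_tv = 0.001; style layers 1_1…5_1 each carry
weight 1/5 and the content layer is 4_2, with features taken
post-activation (pre-activation is the undocumented alternative). The
optimizer is scipy's L-BFGS-B (history 10, strong-Wolfe line search) with
analytic gradients; full-scale refinement uses 2000 iterations, the desk
profile 100. L-BFGS-B only accepts decreasing steps, so the final loss
never exceeds the initial one — the descent property the tests assert.

The extractor contract (`layer_names` + `features()`) decouples the losses
from any particular network. The default `RandomConvExtractor` is a
five-block stack of paired 3×3 He-initialized random convolutions with ReLU
and 2×2 average pooling between blocks, deterministic per seed and never
trained. Random multi-scale projections preserve enough structure for the
Gram losses to be meaningful optimization targets, and they make the whole
pipeline runnable with no pretrained weights; a VGG-19-style pretrained
extractor can be plugged through the same contract when fidelity to
published perceptual losses matters.

## Phantoms

`make_phantom` renders an elliptical head (axes 0.42/0.36 of the image) of
tissue level 110 on background 0, band-limited Gaussian-smoothed texture
(sd 12 intensity levels) inside the head, a bright tumor disc (level 230,
radius 0.10, fully inside the head by construction) and additive pixel
noise (sd 6). Defaults were chosen so that every metric and edge path is
exercised non-degenerately: three distinct plateaus, strong head and tumor
edges, non-trivial histograms, tumor mean > tissue mean > background mean.
`make_dataset` jitters tumor geometry and texture by ±10 % per image.

What passing tests on phantoms show: the training loops, fusion algebra,
optimization and metrics behave exactly as specified on images with
MRI-like statistical structure. What they do not show: sample quality or
metric values on real MRI data — phantoms have no anatomy, no modality
contrast (T1/T2/FLAIR), and no scanner noise model, so published
full-scale table values are out of reach by design at desk scale.

## Numerical choices and degenerate inputs

* float64 throughout the autograd engine; seeded `numpy.random.Generator`
  everywhere (no global RNG state).
* Blend rounding is half-to-even (`numpy.rint`); blended pixels are
  provably inside [min, max] of the two inputs.
* Min-max slice rescaling maps a constant NIfTI slice to all zeros
  (documented degenerate case).
* Intensity-domain conversions are affine through [0, 1]; the
  uint8→signed→uint8 round trip is exact for all 256 levels (≤ 1 level is
  the contract; exactness is what the exhaustive test observes).
* Probabilities are clamped by 1e-7 before logs in the adversarial losses.

## Known limitations

* Convolution operations support first derivatives only; a convolutional
  critic with a gradient penalty would need the dense fallback.
* Batch statistics (not running averages) are used at sampling time, so
  generator output depends on the sampled batch composition; sampling is
  deterministic per seed and batch.
* The aggregation weight formula is a documented reconstruction (see
  above), and SSIM values are convention-dependent; both caveats matter
  when comparing numbers across implementations.
* The pipeline pairs generated image i with reference i; no matching or
  assignment step is attempted.
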