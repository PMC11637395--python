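# Methods

## The generative model

The core of the package is an invertible multi-scale coupling flow between
images `x` (treated as `w·h`-dimensional vectors) and latents `z` of the
same dimension. Each of `n_levels` levels begins with a squeeze (2×2
spatial-to-channel reshape), applies `n_steps` flow steps — actnorm
(per-channel affine with data-dependent initialization to zero mean / unit
variance on the first training batch), an invertible 1×1 convolution, and an
affine coupling layer — and, at every level except the last, factors half of
its channels out into the latent code; the last level contributes all of its
channels. The latent layout (per-level chunk shapes and concatenation order,
level 1 first, each chunk in channel-major raster order) is recorded on the
model so flatten/unflatten round-trips exactly.

The exact log-likelihood is the change-of-variables formula: the standard
Gaussian log-density of `z` plus the sum of per-layer log-Jacobian
determinants (actnorm: `H·W·Σ log s_c`; 1×1 convolution: `H·W·log|det W|`;
coupling: `Σ log s` over the transformed half). The prior is deliberately
**fixed** to N(0, I) rather than learned, so the latent metric is isotropic
and Euclidean / L∞ distances are meaningful for the enhancement step.

The model, its analytic reverse-mode gradients and an Adam optimizer are
written directly in NumPy (float64). Convolutions use an im2col/matmul
formulation. Gradient correctness is pinned by finite-difference tests, and
the forward log-determinant is verified against the log-determinant of a
numerically differentiated full Jacobian on 8×8 inputs (relative 10⁻³ in the
tests; observed agreement is ~10⁻¹²).

### Invertibility maintenance

During training a 1×1 weight can drift toward singularity, destroying
invertibility. At the end of every epoch each weight `W = UΣVᵀ` is
re-composed as `U·crop(Σ; 10⁻³, 10³)·Vᵀ`, bounding its condition number by
10⁶. The crop is idempotent and leaves in-range matrices unchanged (up to
SVD round-off); it runs after the optimizer step of the epoch's final batch.

### Training input transform

Display intensities in `[0, 255]` are mapped to the flow's working range by
`x/256 − 0.5`. Uniform dequantization noise `U(0, 1/256)` is added during
training only; enhancement and likelihood evaluation use the deterministic
transform, keeping the whole enhancement pipeline reproducible bit-for-bit.

### Coupling parameterization

The coupling net is `n_coupling_convs` same-padded convolutions (ReLU
between, hidden width `hidden_width`) whose final layer is zero-initialized,
so every coupling step — and hence the whole flow — starts as an identity
map on top of its channel permutations. The affine scale is
`s = exp(tanh(raw))`, bounded inside `[1/e, e]`: bounded away from zero for
a stable inverse, and exactly 1 at initialization.

## The normal hyperplane and enhancement

The latents of the N normal training images span an (at most N-dimensional)
linear subspace S containing the origin. Its orthonormal basis `Q` is
computed by column-pivoted thin QR of the `(d × N)` latent matrix; pivots
whose R-diagonal falls below `rank_tol` (default 10⁻¹⁰) times the largest
are dropped, so rank-deficient inputs reduce to their numerical rank. The
factorization is in-memory, which caps N at desk scale; this replaces any
out-of-core scheme and is the package's declared limitation for very large
training sets. The basis archive stores a SHA-256 of the generating model so
a mismatched model/basis pair is rejected at enhancement time.

Projection `z₀ = Q(Qᵀz)` is the unique Euclidean-nearest point of S.
Enhancement then either extrapolates along the straight line
(`euclidean` mode, `γ > 1`), or applies the three-step L∞ scheme
(default): element-wise clamp of `z` into `[z₀ⱼ − Γ, z₀ⱼ + Γ]`,
`Γ = γ‖z − z₀‖∞`, followed by `z* = βz + (1−β)z_interp`. Ties at exactly
`Γ` count as unchanged (closed interval), and untouched elements are
propagated bit-exactly through the final extrapolation, so the set of
altered latent elements is exactly the set with `|zⱼ − z₀ⱼ| > Γ`. The γ = 0
and γ = 1 endpoints return `z₀` and `z` exactly (special-cased so floating
round-off in `z₀ ± Γ` cannot break the identities).

Defaults γ = 0.2 and β = 1.2 are adopted as given; they originate from a
subjective grid search and are not re-derived here. A warning is emitted for
β > 2, where large local or global deformation is expected. Enhanced images
are clipped back to the declared display range before writing.

## Preprocessing

Raw intensities are windowed linearly onto `[0, 255]` (DICOM window
center/width tags (0028,1050)/(0028,1051) when present; explicit or
full-range min/max otherwise, with a logged warning for tag-less DICOM).
Geometry: rescale to canvas width preserving aspect ratio; taller images are
symmetrically truncated and shorter ones symmetrically zero-padded (the
padding rule is a declared extension — truncation alone cannot square a wide
image); the canvas is anti-aliased down to the model resolution. Windowing
precedes resizing; both are intensity-linear so the order affects only
interpolation rounding. Post-enhancement up-sampling to display size is
bicubic. The full-scale geometry (canvas 1024 → model 512 → display 1024)
ships in the `paper512` preset; the desk preset uses 64/32/64.

## Synthetic phantoms

The phantom generator emulates the gross radiographic structure needed to
exercise every pipeline stage: bright thorax ellipse on a dark frame, two
darker lung ellipses, a bright mediastinal column, sinusoidal rib-like bands
(4 per image by default, contrast 14), per-image geometric jitter (3%
multiplicative on ellipse parameters and a random rib phase) and Gaussian
noise (SD 4). Nodules are Gaussian blobs, FWHM = diameter (desk default
4–8 px, i.e. 12–25% of the 32-px frame, peak contrast 20–45) with the
half-maximum disc as ROI; evaluation sets draw 1–3 nodules per case
(probabilities 0.70/0.27/0.03, mean 1.33). All generation is bit-exactly
reproducible from the spec seed.

What the phantoms do **not** emulate: soft-tissue texture, scatter,
projection physics, pathology other than blob-like nodules, patient
positioning variation, detector response. Passing the phantom study shows
the pipeline is mechanically and statistically sound — that the flow learns
the phantom population, that projection onto the normal span removes
nodules preferentially, and that extrapolation re-amplifies them — not that
clinical conspicuity gains transfer to real radiographs.

## Desk-scale study conditions

The default configuration is chosen so the complete study runs in about a
minute on one CPU: 32×32 single-channel images, 2 levels × 4 steps, hidden
width 64, 3 coupling convolutions with 3×3 kernels, batch 16, 4 epochs,
Adam with learning rate 10⁻³ (adequate convergence within the short epoch
budget; the loss-decrease test is the acceptance bar for any optimizer
choice), 400 normal training phantoms (latent span of rank 400 in the
1024-dimensional latent space) and a 50-case evaluation set. The full-scale
preset (512×512, 7 levels, 32 steps, 22 epochs, batch 4) is provided for
real-data work and is only ever load-tested.

## Numerical choices and degenerate inputs

- float64 throughout; observed flow round-trip error ~10⁻¹³ against a 10⁻⁴
  test tolerance.
- Basis construction requires N < latent dimension; N ≥ d raises a
  degeneracy error rather than silently producing an identity projection.
- Zero lung-field variance, empty masks, non-finite inputs, singular 1×1
  weights, and model/basis hash mismatches raise typed errors naming the
  failing stage.
- Lung-field CNR statistics exclude all nodule ROIs of the case (recorded in
  the report), so injected lesions do not inflate the noise term.
- ΔCNR histogram bins are width 0.1 aligned on zero.

## Known limitations

- In-memory QR caps the training-set size (thousands of latents at desk
  scale); no incremental or distributed factorization.
- The NumPy implementation is single-node and CPU-bound; the full-scale
  preset is configuration only.
- No lung-field segmenter is bundled: for real images the lung mask is an
  input.
- Enhancement operates at model resolution; fine detail beyond the
  down-sampled grid cannot be recovered by the bicubic up-sample.
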