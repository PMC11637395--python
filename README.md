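# eggpale

Abnormal-lesion emphasis for chest radiographs, built from an invertible
(flow-based) generative model trained **only on normal images**, plus an
L∞-distance-based latent-space extrapolation that amplifies whatever a
normal-anatomy model cannot explain — without requiring any lesion labels.

The package is aimed at researchers in medical image analysis who want an
unsupervised, label-free enhancement step for nodule-like findings, together
with a fully synthetic phantom pipeline for controlled experiments and a
contrast-to-noise-ratio (CNR) evaluation of the result.

## Method

A multi-scale coupling flow (actnorm → invertible 1×1 convolution → affine
coupling per step, with squeeze/split between levels) realizes an invertible
map `z = f_θ(x)` with exact log-likelihood

```
log p_θ(x) = log N(z; 0, I) + Σᵢ log |det (∂hᵢ/∂hᵢ₋₁)|
```

trained by maximum likelihood on normal images only. The prior is fixed to
the standard Gaussian so Euclidean and L∞ distances in latent space are
meaningful, and at the end of every epoch each 1×1 weight `W = UΣVᵀ` is
re-composed with its singular values cropped into `[10⁻³, 10³]`, which keeps
`f_θ` numerically invertible throughout training.

The latent codes of the N training images (N < latent dimension) span the
**normal hyperplane** `S`. Enhancement of an unseen image `x`:

1. `z = f_θ(x)`; perpendicular projection `z₀ = Q Qᵀ z` onto `S`
   (thin pivoted-QR basis `Q`) — the "virtually normalized" latent;
2. L∞ interpolation: clamp each element of `z` into `[z₀ⱼ − Γ, z₀ⱼ + Γ]`
   with `Γ = γ‖z − z₀‖∞` (the L1-nearest point of the hypercube
   `‖z' − z₀‖∞ ≤ γ‖z − z₀‖∞`); elements within `Γ` of `z₀` are untouched;
3. final Euclidean extrapolation `z* = β z + (1−β) z_interp`, which moves
   only the few clamped elements — the lesion-specific ones — away from
   normal; defaults `γ = 0.2`, `β = 1.2`;
4. `x* = f_θ⁻¹(z*)`, clipped back to the display range.

Enhancement quality is scored per nodule by
`CNR = (μ_nodule − μ_lungfield)/σ_lungfield` on the original (CNR₋) and
enhanced (CNR₊) image; `ΔCNR = CNR₊ − CNR₋`.

The flow, its manual reverse-mode gradients and the Adam optimizer are
implemented in NumPy (float64); no deep-learning framework is required.

## Worked example

The desk-scale study (32×32 synthetic chest phantoms, 2 levels × 4 steps,
400 normal training phantoms, 50-case nodule evaluation set) runs in about
a minute on one CPU:

```python
from eggpale.pipeline import run_desk_pipeline

summary = run_desk_pipeline(n_train=400, n_eval=50, seed=1)
print(f"nodules evaluated:     {summary['n_nodules']}")
print(f"fraction CNR improved: {summary['fraction_improved']:.3f}")
print(f"mean delta CNR:        {summary['mean_delta']:.3f}")
print(f"change nodule / lung:  {summary['mean_abs_change_nodule']:.2f} / "
      f"{summary['mean_abs_change_lung']:.2f}")
```

prints

```
nodules evaluated:     66
fraction CNR improved: 0.652
mean delta CNR:        0.060
change nodule / lung:  3.09 / 1.49
```

i.e. enhancement with γ = 0.2, β = 1.2 raised the CNR of about two thirds of
the injected nodules, and the mean absolute pixel change inside nodule ROIs
was roughly twice that over the rest of the lung field — the enhancement is
lesion-localized rather than a global contrast change.

The same pipeline is available from the shell:

```
eggpale make-phantoms --out data/train --n 400 --size 32 --seed 7
eggpale train         --data data/train --out model.npz --seed 7
eggpale build-basis   --model model.npz --data data/train --out basis.npz
eggpale enhance       --model model.npz --basis basis.npz \
                      --in data/train/case_0000.png --out enhanced.png --save-diff
eggpale evaluate      --model model.npz --basis basis.npz \
                      --cases data/eval --out report/
```

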