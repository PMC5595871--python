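# msinc — spectral-inconsistency scoring of multispectral retinal images

Multispectral fundus imaging (MSI) records a sequence of en-face retinal
images under narrow-band illumination at ~11 wavelengths between 550 and
850 nm.  Healthy tissue looks *spectrally consistent*: what a pixel looks
like in one band predicts what it looks like in the others.  Early
degenerative changes (RPE disruption, microaneurysms, hemorrhages,
exudates) break that coupling — a pixel appears structured in the red and
infrared slices but normal at shorter wavelengths.  Ophthalmologists
diagnose by eye-balling exactly this cross-band (in)consistency, which is
hard with more than ten slices and only RGB perception.

`msinc` measures spectral inconsistency per pixel, without supervision,
and turns the resulting score map into lesion segmentations.  It is aimed
at researchers working on MSI-based ocular diagnostics who need a
quantitative, reproducible counterpart to visual cross-band comparison.

## Model

Each pixel *i* contributes one feature vector per spectral slice *j*:
gradient orientations (cos θ, sin θ) concatenated over a 7 × 7 window, so
**x**_ij ∈ ℝ^98.  Spectral consistency is defined as the existence of a
single latent vector **z**_i ∈ ℝ^l reconstructing every slice through
slice-specific projections **P**_j:

    x_ij ~ N(P_j z_i, I/σ).

Inconsistent pixels need several latent vectors.  Which views share which
vector is governed by a per-pixel Dirichlet-process mixture
(stick-breaking weights, concentration γ), with conjugate priors
σ ~ Gamma(α, β) and z ~ N(0, I/(σr)).  The latents, weights and σ
marginalize analytically; inference is collapsed stochastic EM — a Gibbs
sweep over the view-to-latent assignments s_ij (E-step) alternated with a
MAP update of the projections P_j (M-step).  The inconsistency score of
pixel *i* is

    ψ_i = (1/T) Σ_t  1[M_i(t) > 1]   ∈ [0, 1],

the fraction of sampler iterations in which pixel *i* required more than
one latent vector — a probability-like degeneration score.  Thresholding
ψ yields a segmentation; the package reports empirical ROC/AUC,
best-threshold accuracy and Dice against reference masks.

Defaults follow the reference experiment: γ = 1.2, α = β = 1, T = 400
iterations (the CLI demo profile uses T = 100; `--paper-defaults`
restores 400), latent dimension selectable by validation
(`msinc select-l`).

## Worked example

No clinical MSI data ship with the package; the synthetic module builds a
ground-truthed phantom — a band-coherent background with three elliptical
lesions whose texture decouples in the longer-wavelength bands:

```sh
msinc synth --out phantom --height 64 --width 64 --bands 5 --lesions 3 --seed 1
msinc score --input phantom/stack.tif --out scored --seed 1 \
            --window 7 --iters 50 --latent-dim 2
msinc eval  --psi scored/psi.tif --mask phantom/mask.png
```

which prints

```
phantom written to phantom (339 lesion pixels)
psi map written to scored (mean psi 0.1594)
{
  "auc": 0.9749498085383195,
  "best_tau": 0.9800000190734863,
  "best_accuracy": 0.9541015625,
  "dice": 0.7798594847775175
}
```

Reading: 339 of 4096 pixels are truly lesional; the mean ψ of 0.16
reflects a mostly-consistent image.  Ranking pixels by ψ separates lesion
from background with AUC 0.97; thresholding at the accuracy-optimal
τ = 0.98 (lesion pixels sit at ψ ≈ 1) classifies 95.4% of pixels
correctly and overlaps the true mask with Dice 0.78.  `scored/psi.tif`
is the 32-bit score map, `scored/psi.csv` the same as (row, col, psi)
rows.

The same pipeline is available as a library:

```python
from msinc import (generate_msi_stack, build_feature_matrix,
                   Hyperparams, run_sem, inconsistency_scores)
stack, mask = generate_msi_stack(H=64, W=64, s=5, n_lesions=3, seed=1)
X = build_feature_matrix(stack, window=7)
state, trace = run_sem(X, Hyperparams(l=2, T=50, seed=1))
psi = inconsistency_scores(trace, grid_shape=X.grid_shape,
                           pixel_index=X.pixel_index).to_grid()
```

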