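# Methods

## The generative model

An aligned MSI sequence yields, per pixel *i* and spectral slice *j*, a
feature vector **x**_ij ∈ ℝ^{d_j}.  The model treats the slices as views
of a common low-dimensional state:

* each pixel owns a set of latent vectors Z_i = {z_im}, z_im ∈ ℝ^l, with
  z_im ~ N(0, I/(σr));
* each view is assigned to one latent vector, s_ij = m, with per-pixel
  mixture weights W_i drawn from a stick-breaking Dirichlet process with
  concentration γ;
* observations are linear projections under isotropic noise,
  x_ij | s_ij = m  ~  N(P_j z_im, I/σ), with the projection P_j ∈
  ℝ^{d_j×l} shared by all pixels of view j;
* a single global precision σ ~ Gamma(α, β) scales both the latent prior
  and the noise.

A pixel whose views all share one latent vector (M_i = 1) is spectrally
consistent; needing M_i > 1 latent vectors is the model's definition of
spectral inconsistency.  The mixture weights are per-pixel: cluster
statistics never pool across pixels — only P_j, and the scalars A and B
below, are global.

## Collapsed inference

Conjugacy lets z, W and σ integrate out exactly.  Writing, per pixel
cluster (i, m),

    C_im^{-1} = Σ_{j: s_ij=m} P_j'P_j + rI,
    μ_im      = C_im Σ_{j: s_ij=m} P_j' x_ij,

and globally

    A = α + n (Σ_j d_j)/2,
    B = β + ½ (Σ_ij x_ij'x_ij − Σ_im μ_im' C_im^{-1} μ_im),

the marginal data likelihood given assignments and projections is
proportional to Γ(A) B^{-A} Π_im r^{l/2} |C_im|^{1/2}.  The sampler never
instantiates any z, w or σ.

**E-step.**  One Gibbs sweep over all (i, j) in fixed row-major order.
For each observation the statistics are downdated (the "−ij" quantities),
and the assignment is drawn among the pixel's live clusters and a fresh
one with probabilities proportional to

    existing m :  N_{im,−j}/(s−1+γ) · B_{−ij}^{A_{−ij}}/B_{s_ij=m}^{A}
                  · Γ(A)/Γ(A_{−ij}) · |C_{im,+}|^{1/2}/|C_{im,−ij}|^{1/2}
    new        :  r^{l/2} γ/(s−1+γ) · (same B, Γ factors) · |C_new|^{1/2}.

The CRP normalizer uses the number of views s (the per-pixel restaurant
seats one customer per view).  Empty clusters are deleted immediately and
labels compacted, so labels are always 0..M_i−1.  Tests verify these
conditionals against brute-force numerical marginalization of the
un-collapsed model (quadrature over σ and every z) at l = 1 and l = 2,
and the incremental downdate/update bookkeeping against from-scratch
recomputation after every sweep.

**M-step.**  Maximizing the expected complete-data log joint over P_j at
fixed assignments gives

    P_j = (A/B) (Σ_i x_ij μ_{i,s_ij}') (Σ_i C_{i,s_ij} + (A/B) Σ_i μ_{i,s_ij} μ_{i,s_ij}')^{-1},

where (μ_{i,s_ij}, C_{i,s_ij}) is the posterior of the cluster currently
owning observation (i, j): the expectation E[σ z z'] = (A/B) μμ' + C of
the owning cluster is what enters the normal equations, so the covariance
sum runs over owning clusters only (for fully consistent assignments,
M_i = 1, this coincides with summing over all clusters).  All collapsed
statistics are rebuilt after the update since they depend on P.  A
finite-difference test confirms that the update's fixed point is a
stationary point of the (quadrature-evaluated) log joint.

**Score.**  After every iteration (one sweep + one projection update) the
indicator 1[M_i > 1] is recorded; ψ_i is its average over all T
iterations.  ψ is therefore a multiple of 1/T, bounded in [0, 1].  A
`burn_in` parameter can discard initial iterations but defaults to 0.

## Initialization and warm start

All views of every pixel start in a single cluster — the prior belief
that most pixels are normal — and P_j is filled with N(0, 1/l) entries.
Random projections carry no information, so Gibbs sweeps run directly
against them split pixels essentially at random, and on some seeds the
sampler is absorbed into an everything-split state that later M-steps
entrench (observed as score maps with ψ ≈ 1 everywhere).  `run_sem`
therefore warm-starts the projections by iterating the M-step on the
all-consistent initial assignment (at most 30 iterations, relative
tolerance 1e-6) before the first sweep — the mixture-model analogue of
one-component initialization.  This removed the degenerate runs entirely
and leaves well-behaved runs unchanged.

## Hyperparameters

| name | meaning | default | rationale |
|------|---------|---------|-----------|
| γ | DP concentration; new-cluster propensity γ/(s−1+γ) | 1.2 | reference experimental setting |
| α, β | Gamma prior on σ | 1, 1 | reference experimental setting |
| r | latent prior precision scale | 1 | unitless; no published value, neutral choice |
| l | latent dimension | 2 | smallest non-degenerate subspace; select with `select_latent_dim` per dataset |
| T | SEM iterations | 400 (library), 100 (CLI demo) | reference run length; ψ resolution is 1/T |
| window | orientation window w (features are 2w² per band) | 7 | typical local-descriptor scale |
| burn_in | iterations dropped from ψ | 0 | score averages all iterations |

## Features

Per band, gradients are central differences with reflective padding;
orientation is encoded as the unit vector (cos θ, sin θ), which avoids
the 2π wrap-around a raw angle would put into a linear model, and makes
features invariant to positive rescaling of the band (band-specific
illumination gain drops out).  Pixels with gradient magnitude below
1e-12 have no orientation and are encoded (0, 0).  The w × w window's
pairs are concatenated in row-major order (reflective padding at
borders), giving d_j = 2w² per band.  Each feature row is mean-centered
across pixels: the latent prior is zero-mean with no intercept term, so
centering is required for x_ij = P_j z_i to be attainable.  Intensities
are rescaled to [0, 1] by dtype maximum on load, so 16-bit DICOM and
8-bit PNG land on one scale.  A region-of-interest mask may restrict
which pixels become model columns.

## Synthetic generators

`generate_views` inverts the model exactly: standard-normal projections,
z ~ N(0, I/(σr)), noise N(0, I/σ); a chosen fraction of pixels draws a
second independent latent vector and splits its views uniformly between
the two (re-drawing until both are used).  Two latent vectors are the
minimal structure satisfying the definition of inconsistency and keep
ground truth unambiguous.  Because the generator matches the model, runs
on its output probe inference quality, not model misspecification.

`generate_msi_stack` is an image-level phantom: one smooth Gaussian
random field shared by all bands with band-specific gain (orientation
identical across bands — consistent tissue), plus elliptical lesions
whose texture is re-drawn independently per band from a mid-index
"contrast flip" band upward, mimicking structures visible only in
red/infrared slices.  Mild per-band sensor noise (σ = 0.004 in [0,1]
units) keeps bands non-identical.  The phantom has no vessels, optic
disc, or wavelength physics (melanin/hemoglobin absorption), and real
lesions' spectral statistics are uncharacterized; passing tests on it
demonstrates that the pipeline detects cross-band structural decoupling,
not clinical performance.

## Evaluation

Segmentation is the strict threshold rule ψ > τ.  ROC curves are
empirical with one vertex per distinct score and trapezoidal AUC — a
deliberate, assumption-free replacement for legacy binormal ROC fitting.
`best_accuracy` scans every distinct score as τ plus one sub-minimum
value (so both trivial classifiers are in the scan) and breaks ties
toward the smallest τ.  Dice of two empty masks is defined as 1.

## Numerical choices

* All mixture arithmetic in the log domain; B^A ratios are computed as
  A_{−ij} log B_{−ij} − A log B_m because A ≈ nd/2 is enormous for
  images (≈ 10^6 for a 64 × 64 five-band stack).
* The l × l cluster precisions are factored by a hand-rolled Cholesky in
  the jit-compiled sweep kernel (l ≤ 4 in practice); positive-definiteness
  is guaranteed by r > 0 and asserted.
* The sweep is a pure function of the state and a matrix of pre-drawn
  uniforms, one per (pixel, view); all randomness flows from a single
  seeded generator, so runs are bitwise reproducible on a platform.
* Non-finite assignment log-probabilities abort the run naming the
  offending (pixel, view); B ≤ 0 aborts as corrupted state.
* The empty-cluster posterior is exactly (0, I/r); its log-determinant
  supplies the r^{l/2} prefactor of the new-cluster case.

## Problem sizes

The test and reproduction runs use desk-scale conditions chosen as the
smallest sizes at which the studied effects are unambiguous: multi-view
experiments at n = 500 pixels, s = 5 views, d_j = 4, l = 2, σ = 50,
T = 200, five replicate seeds; image phantoms at 64 × 64 × 5 bands with
three lesions, 7 × 7 windows, T = 50.  Oracle comparisons run at n ≤ 3,
s ≤ 3, d_j = 1, l ∈ {1, 2}, where nested quadrature is exact to ~1e-10.

## Known limitations

* With γ = 1.2 and s = 5 views the per-pixel CRP gives every view a
  ~23% prior chance of opening a new cluster, so even fully consistent
  pixels flicker: baseline ψ on normal synthetic pixels sits near 0.5–0.6
  rather than 0.  Detection rests on the contrast with anomalous pixels
  (ψ ≈ 0.9), not on a near-zero baseline.  At the feature-matrix
  conditions above, ψ's AUC against planted anomalies averages ≈ 0.87–0.90
  across seeds: anomalies whose two latent vectors happen to lie close
  (prior scale 1/√(σr) ≈ 0.14) are intrinsically inseparable.  The image
  phantom, whose lesions decouple strongly, scores AUC ≈ 0.97.
* Inputs must be pre-aligned; no inter-band registration is performed.
* One global σ for all bands; no per-spectrum noise levels.
* SEM is a stochastic ascent, not a full posterior: ψ is a trajectory
  average whose resolution is 1/T.
* The symbol D in the CRP normalizer and two update-equation subscripts
  in the published description are ambiguous; this implementation uses
  the per-view restaurant (D = s) and the readings that make the
  recursions well-defined and the M-step stationary.
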