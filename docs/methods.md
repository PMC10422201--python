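# Methods

## Model

`zsdecode` fits a linear-Gaussian latent-variable model linking three
observed views — brain activity (f), visual image features (v) and semantic
category features (s) — through one shared latent variable:

    x_n^(k) = W^(k) z_n + e_n^(k),   e_n^(k) ~ N(0, beta_k^-1 I),
    z_n ~ N(0, I_Dz),
    W_ij^(k) ~ N(0, 1/alpha_ij^(k)),  alpha_ij^(k) ~ Gamma(mean 1, shape 0),
    p(beta_k) ∝ 1/beta_k.

The element-wise Gamma hyperpriors implement automatic relevance
determination (ARD): precisions of loadings that the data do not support
grow without bound and the corresponding entries shrink to zero, which is
the model's built-in feature selection for high-dimensional voxel data.

Two sample blocks enter the likelihood. The *paired* block (N samples)
observes all three views. The *additional* block (M samples) observes only
visual and semantic features; its brain columns are treated as missing
values `X_miss` with a standard-normal prior and are imputed as posterior
means during inference. This is the semi-supervised mechanism: feature-only
samples from target categories pull the latent space and the feature
loadings toward the target region even though their brain activity was
never recorded.

### Assumptions

- Each view is a *linear* map of the latent plus isotropic noise; a single
  scalar noise precision per view.
- The loading posterior is factorized element-wise (no row covariance), as
  is the mean-field family `q(X_miss) q(Z) q(W) q(alpha) q(beta)`.
- Missing brain columns are exchangeable with observed ones given the
  latent; the additional block is assumed to come from the same generative
  process as the paired block, only with a different category composition.

## Inference

Coordinate ascent cycles the closed-form updates in the fixed order
W → Z → X_miss → alpha → beta for `n_iterations` full cycles (default 10).
A fixed iteration count, rather than a convergence test, is the default
protocol; an optional relative-change stop (`rel_tol`) exists but is off.

Numerical choices, all in `ModelConfig`:

- **Latent update aggregation.** The latent precision uses
  `sigma_z = sum_k beta_k (Wbar_k^T Wbar_k + V_k) + I` with `V_k` the
  diagonal of *column-summed element-wise loading variances*
  `V_k[j] = sum_i 1/sigma_ij^(k)`. This is the unique aggregation for which
  the W, Z and beta updates form a self-consistent expectation of the
  quadratic form under the factorized posterior; the same `V_k` appears in
  the noise update and in test-time latent inference.
- **Missing-column residuals.** The noise update evaluates residuals of the
  additional block at the imputed means. Because the X_miss update sets
  those means to `Wbar_f zbar_n` exactly, additional-block brain residuals
  vanish and the brain noise variance is estimated from the paired block
  diluted over N+M columns; the alternative of adding `D_f / beta_f` per
  missing sample to the residual would undo that dilution but is not the
  default (kept faithful to the update as specified).
- **ARD clipping.** Precision means `alpha` are clipped at
  `alpha_cap = 1e8`. Pruned entries diverge, and the clip only keeps
  arithmetic finite; in a 10-iteration run `alpha` grows additively by
  roughly `beta_k (N+M) [sigma_z^-1]_jj` per cycle and typically reaches
  1e3–1e4, so the cap is an overflow guard, not an operating point.
- **Noise floor.** The posterior-mean noise variance `1/beta_k` is floored
  at `beta_var_floor = 1e-12` so a perfect reconstruction cannot produce an
  infinite precision.
- **Initialization and determinism.** One integer seed drives a single
  generator; the draw order (latent means, missing means, then loadings per
  view in brain/visual/semantic order) is part of the determinism contract.
  Latent and missing means start standard normal, loadings from their prior,
  `beta = 1`, precisions at identity scale.
- **Degenerate inputs.** Zero-variance features are z-scored to 0 and
  flagged, not rejected (real voxel data contains dead channels); constant
  vectors in a Pearson correlation return 0 with a warning rather than
  aborting an evaluation; exact score ties credit 0.5 in pairwise
  identification and count against the truth in ranks.

### What ARD pruning looks like here

The latent basis of this model is identified only up to rotation, and the
ARD prior is element-wise. When the data need fewer latent directions than
the model provides, coordinate ascent from a dense random start suppresses
the surplus *direction* — the smallest singular value of the loading means
collapses (typically a factor ~10 below the next one after 10 iterations) —
but no individual *column* of `Wbar` needs to shrink, because a rotated
basis spreads the suppression across columns. The package therefore reports
pruning two ways: `VIResults.effective_latent_rank()` detects the retained
rank as the largest logarithmic gap in the singular-value spectrum of the
loading means (rotation-invariant), while the per-column diagnostic
(`n_pruned`, alpha at the clip) only fires in rotation-free situations such
as a view with no shared signal at all, where the columns themselves
collapse below 1e-3 within the default 10 iterations.

### Diagnostics

Each iteration logs, per view, the expected mean squared reconstruction
error under the current factors (the residual of the means plus the
loading- and latent-covariance corrections, divided by the number of matrix
elements — identical to the quantity whose inverse is the noise-precision
update). This proxy is what the noise update minimizes and in practice
decreases monotonically across cycles on model-generated data; it is *not*
the variational lower bound itself, and isolated increases of order 1e-3
can occur on unfavourable draws. The bound is defined but not computed in
closed form here.

## Prediction and decoding

Test-time latent inference drops the visual/semantic terms of the latent
update (only brain activity is observed at test time):
`sigma_z,test = beta_f (Wbar_f^T Wbar_f + V_f) + I`,
`zbar_test = beta_f sigma_z,test^-1 Wbar_f^T x_test`. Feature predictions
plug the loading means into the likelihood and integrate over this
Gaussian; the predictive covariance `Wbar_i sigma_z,test^-1 Wbar_i^T +
I/beta_i` is independent of the test input.

- **Scale.** Inputs are z-scored per feature with statistics fitted on the
  paired block only (no information flows from additional or test data into
  the preprocessing). Predictions are mapped back to the original feature
  scale before they are correlated with candidate vectors: correlating a
  per-feature-rescaled prediction against raw candidates would compare
  incompatible scales, and Pearson correlation is not invariant to
  per-coordinate rescaling.
- **Ensembling.** `fit_ensemble(x, T)` trains T models that differ only in
  their random initialization (seeds `base+1 … base+T`; no data resampling)
  and averages the predictive means per view. The reduction is ordered by
  seed index, so results do not depend on execution order. T defaults to
  100 in the ensemble-of-restarts protocol; the desk-scale tests use small
  T because single fits are already stable at these problem sizes.
- **Trade-off weight.** The blended score `eta*r_v + (1-eta)*r_s` is
  evaluated over the grid {0, 0.1, …, 1}. Selecting the best eta on the
  evaluation data itself is oracle selection; the grid utilities return all
  eleven records so that dependence stays visible, and the CLI reports the
  full grid.

## Synthetic data generator

`sample_ground_truth` / `sample_dataset` draw studies from the model's own
generative process with category structure:

- Latents are category-clustered: `z = mu_c + tau * eps` with one prototype
  `mu_c` per category and within-category spread `tau` (default 0.5, about
  half the between-category spread — repeated viewings of one category are
  similar but not identical).
- Views are `W z` plus isotropic noise. Noise precisions are set from a
  per-view signal-to-noise ratio; the default preset uses snr 2 for brain
  and 10 for the feature views, reflecting that fMRI is far noisier than
  deep-network or word-embedding features.
- The zero-shot split: 20 source categories form the paired block (8 paired
  samples each, matching a typical per-category viewing count), 8 target
  categories contribute only visual/semantic samples (25 each) plus test
  brain activity, and 12 further categories exist only as candidate
  distractors. Candidates are noiseless per-category prototypes
  `W^(i) mu_c`.
- **Bias emulation.** Source prototypes are shifted 2.0 latent units along
  a random direction *and* compressed to 25% spread along the last half of
  the latent axes. The compression is what creates projection domain shift
  at desk scale: a pure mean shift is removed by per-feature
  standardization, and source latents would otherwise cover every latent
  direction with full variance, leaving a well-specified linear model
  nothing to be biased about. Under-represented directions in the source
  block are exactly what additional target-category features rectify.
- All randomness flows from one seed via `SeedSequence` spawning three
  streams (truth, training data, test data), so ground truth and data can
  be varied independently.

What the generator does **not** emulate: spatial voxel correlation,
hemodynamic temporal structure, non-linear feature extraction,
heavy-tailed noise, or category similarity structure beyond Gaussian
prototypes. Passing the recovery and benchmark tests therefore shows that
the inference and decoding machinery is correct and that the
semi-supervised mechanism behaves as designed *under the model's own
assumptions* — it does not certify accuracy on real fMRI data, whose
headline numbers depend on a specific public dataset and pretrained
feature extractors and are out of scope here.

## Problem sizes used in the test suite

Recovery checks use 60/40/20 features, 5 latent components (one inactive),
N = 300 paired and M = 104 additional samples at snr 10, ten seeds; the
zero-shot benchmark uses the default preset above, ten seeds, comparing
M = 0 against M = 200. Chance-level checks simulate 2,000 trials over
10,000 candidates. These sizes make every fit take well under a second
while keeping N comfortably above the feature dimensions, the regime the
asymptotic recovery claims refer to.

## Known limitations

- The variational lower bound is not computed; convergence is monitored
  through the reconstruction proxy only.
- Element-wise ARD cannot report pruning per latent column under rotation
  ambiguity (see above); use the spectral rank.
- The brain noise precision is biased upward when M > 0 (missing-column
  residuals vanish by construction); this is inherent to evaluating the
  specified update at the imputed means.
- Identification metrics assume the candidate set contains the true
  category; `TestSet.check_against` enforces this.
- Ensemble members are refits of the same data; the ensemble averages away
  initialization variance but cannot reduce bias.
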