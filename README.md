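# zsdecode

Semi-supervised multi-view embedding for **zero-shot neural decoding**:
identify which image category a person was viewing from fMRI activity, for
categories that were never part of the paired training data.

## Who this is for

Neural-decoding studies pair brain activity with stimulus features: visual
features of the viewed image and a semantic word vector of its category.
Collecting fMRI is expensive, so the paired training set covers few
categories, and a mapping fitted on those *source* categories misplaces the
embeddings of unrelated *target* categories — the projection domain shift
problem of zero-shot learning. This package implements a generative
multi-view model that rectifies the shift by additionally ingesting visual
and semantic features of target-related images **without any brain
activity**, treating the unrecorded brain responses as missing values.

## The model

Three views — brain activity `x⁽ᶠ⁾ ∈ R^{D_f}`, visual features
`x⁽ᵛ⁾ ∈ R^{D_v}`, semantic features `x⁽ˢ⁾ ∈ R^{D_s}` — are generated from a
shared latent `z ∈ R^{D_z}`:

    x_n⁽ᵏ⁾ = W⁽ᵏ⁾ z_n + ε_n⁽ᵏ⁾,    ε_n⁽ᵏ⁾ ~ N(0, β_k⁻¹ I),    k ∈ {f, v, s}

with `z_n ~ N(0, I)`, element-wise Gaussian priors
`W_ij⁽ᵏ⁾ ~ N(0, α_ij⁽ᵏ⁾⁻¹)` whose precisions carry Gamma hyperpriors
(automatic relevance determination), and uninformative priors on the noise
precisions `β_k`. N paired samples observe all three views; M additional
samples observe only the visual and semantic views, and their brain columns
`X_miss⁽ᶠ⁾` are imputed as posterior means. Inference is mean-field
coordinate ascent over `q(X_miss) q(Z) q(W) q(α) q(β)` in the fixed order
W → Z → X_miss → α → β for 10 iterations.

At test time, the latent posterior is approximated from brain activity
alone, `σ_z,test = β_f (W̄⁽ᶠ⁾ᵀW̄⁽ᶠ⁾ + V⁽ᶠ⁾) + I`, and each feature view is
predicted as `x̄⁽ⁱ⁾ = β_f W̄⁽ⁱ⁾ σ_z,test⁻¹ W̄⁽ᶠ⁾ᵀ x_test⁽ᶠ⁾`, optionally
averaged over T random-restart fits. Decoding correlates the predictions
with every candidate category's reference vectors and blends the two
spaces, `r = η·r⁽ᵛ⁾ + (1−η)·r⁽ˢ⁾`; the arg-max candidate is the decoded
category. Evaluation uses pairwise (two-alternative) identification
accuracy (chance 50%) and rank-n accuracy over C candidates (chance n/C).

Special cases: two included views give Bayesian CCA against a single
feature space (BCCA-V / BCCA-S); M = 0 gives the purely supervised
multi-view model.

## Worked example

```python
from zsdecode import (MultiViewEmbedding, eta_grid, sample_dataset,
                      sample_ground_truth)

# synthetic zero-shot study drawn from the model's own generative process:
# 20 source categories with paired data, 8 target categories with
# feature-only data, one inactive latent component
truth = sample_ground_truth(seed=0, zero_latent_columns=(4,),
                            snr={"brain": 2.0, "visual": 10.0, "semantic": 10.0})
bundle = sample_dataset(truth, n_per_source_category=8,
                        m_add_per_target_category=25,
                        n_test_per_target_category=5, seed=0)

model = MultiViewEmbedding(bundle.dataset, latent_dim=5, seed=1)
res = model.fit()
print(res.summary())

pred_v = res.predict(bundle.test.brain_test, view="visual").mean
pred_s = res.predict(bundle.test.brain_test, view="semantic").mean
records = eta_grid(pred_v, pred_s, bundle.candidates, bundle.test.true_labels)
best = max(records, key=lambda r: r["pairwise_accuracy"])
print(f"best eta = {best['eta']:.1f}")
print(f"pairwise identification accuracy = {best['pairwise_accuracy']:.3f}")
```

prints

```
Semi-supervised multi-view embedding — variational fit
==========================================================
views: brain, visual, semantic   latent dim: 5
paired samples N: 160   additional samples M: 200
iterations: 10   seed: 1
pruned latent components: 0 / 5

view         D_k     beta_mean     recon MSE
brain         60         4.341        0.2304
visual        40         5.071        0.1972
semantic      20         4.646        0.2152

total recon MSE per iteration: 2.952, 1.532, 0.8851, ..., 0.646, 0.6428

best eta = 0.4
pairwise identification accuracy = 0.962
```

The fit summary shows the per-view posterior noise precisions and the
descent of the expected reconstruction error over the 10 coordinate-ascent
cycles. A pairwise accuracy of 0.962 means the true category out-scores
96.2% of the competing candidates; chance is 0.5.

The same pipeline runs from the shell:

```bash
zsdecode simulate --seed 0 -o runs/sim
zsdecode fit --data runs/sim/dataset/manifest.json --latent-dim 5 -o runs/ckpt
zsdecode predict --checkpoint runs/ckpt --test runs/sim/test/manifest.json -o runs/pred
zsdecode evaluate --predictions runs/pred \
    --candidates runs/sim/candidates/manifest.json --rank 1 -o runs/eval
```

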