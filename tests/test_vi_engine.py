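import numpy as np
import pytest

from zsdecode import (ConfigError, ModelConfig, MultiViewDataset,
                      MultiViewEmbedding, NumericalError)
from zsdecode.model import (VariationalState, fit_state, init_state, update_alpha,
                            update_beta, update_missing, update_w, update_z)


def make_state(*, views=("brain",), data=None, W_mean, W_prec, alpha_mean,
               beta_mean, Z_mean, sigma_z_inv, n_paired, n_additional=0,
               X_miss_mean=None):
    """Hand-built state for checking single updates in isolation."""
    dz = np.asarray(Z_mean).shape[0]
    df = np.asarray(W_mean["brain"]).shape[0]
    return VariationalState(
        views=tuple(views), n_paired=n_paired, n_additional=n_additional,
        latent_dim=dz,
        W_mean={k: np.asarray(v, dtype=float) for k, v in W_mean.items()},
        W_prec={k: np.asarray(v, dtype=float) for k, v in W_prec.items()},
        alpha_mean={k: np.asarray(v, dtype=float) for k, v in alpha_mean.items()},
        alpha_shape=0.5,
        beta_mean=dict(beta_mean),
        beta_shape={k: 1.0 for k in views},
        Z_mean=np.asarray(Z_mean, dtype=float),
        sigma_z=np.linalg.inv(np.asarray(sigma_z_inv) + 1e-300 * np.eye(dz))
        if np.any(np.asarray(sigma_z_inv)) else np.eye(dz) * 1e300,
        sigma_z_inv=np.asarray(sigma_z_inv, dtype=float),
        X_miss_mean=np.zeros((df, n_additional)) if X_miss_mean is None
        else np.asarray(X_miss_mean, dtype=float),
    )


def brain_only_dataset(brain):
    brain = np.asarray(brain, dtype=float)
    n = brain.shape[1]
    filler = np.linspace(-1, 1, 2 * n).reshape(2, n)
    return MultiViewDataset(brain=brain, visual=filler, semantic=filler)


class TestInit:
    def test_same_seed_bit_identical(self, tiny_dataset):
        cfg = ModelConfig(latent_dim=2, seed=5)
        a = init_state(tiny_dataset, cfg)
        b = init_state(tiny_dataset, cfg)
        np.testing.assert_array_equal(a.Z_mean, b.Z_mean)
        for k in a.views:
            np.testing.assert_array_equal(a.W_mean[k], b.W_mean[k])

    def test_prior_defaults(self, tiny_dataset):
        state = init_state(tiny_dataset, ModelConfig(latent_dim=2))
        for k in state.views:
            assert np.all(state.alpha_mean[k] == 1.0)
            assert state.beta_mean[k] == 1.0
        assert state.alpha_shape == 0.5

    def test_latent_init_centered(self):
        rng = np.random.default_rng(0)
        ds = MultiViewDataset(brain=rng.standard_normal((25, 500)),
                              visual=rng.standard_normal((25, 500)),
                              semantic=rng.standard_normal((25, 500)))
        state = init_state(ds, ModelConfig(seed=12))
        assert state.Z_mean.size >= 10_000
        assert abs(state.Z_mean.mean()) < 0.03

    def test_latent_dim_exceeding_views_rejected(self, tiny_dataset):
        with pytest.raises(ConfigError):
            MultiViewEmbedding(tiny_dataset, latent_dim=10)

    def test_auto_latent_dim_is_smallest_view(self, tiny_dataset):
        model = MultiViewEmbedding(tiny_dataset)  # semantic has 3 features
        assert model.latent_dim == 3


class TestUpdateW:
    def test_scalar_hand_substitution(self):
        # Df=Dz=1, N=2, zbar=[1,1], x=[2,2], beta=1, alpha=1, [sz^-1]=0.5
        state = make_state(W_mean={"brain": [[0.0]]}, W_prec={"brain": [[1.0]]},
                           alpha_mean={"brain": [[1.0]]}, beta_mean={"brain": 1.0},
                           Z_mean=[[1.0, 1.0]], sigma_z_inv=[[0.5]], n_paired=2)
        update_w(state, brain_only_dataset([[2.0, 2.0]]), "brain")
        assert state.W_prec["brain"][0, 0] == pytest.approx(4.0)
        assert state.W_mean["brain"][0, 0] == pytest.approx(1.0)

    def test_zero_cross_moment_gives_zero_mean(self):
        state = make_state(W_mean={"brain": [[1.0]]}, W_prec={"brain": [[1.0]]},
                           alpha_mean={"brain": [[1.0]]}, beta_mean={"brain": 1.0},
                           Z_mean=[[1.0, -1.0]], sigma_z_inv=[[0.0]], n_paired=2)
        update_w(state, brain_only_dataset([[3.0, 3.0]]), "brain")
        assert state.W_mean["brain"][0, 0] == 0.0

    def test_precision_bounded_below_by_alpha(self, tiny_dataset):
        cfg = ModelConfig(latent_dim=2, seed=1)
        state = init_state(tiny_dataset, cfg)
        for k in state.views:
            update_w(state, tiny_dataset, k)
            assert np.all(state.W_prec[k] >= state.alpha_mean[k])


class TestUpdateZ:
    def test_scalar_hand_substitution(self):
        # one view, Wbar=2, beta=1, vanishing loading variance -> sz=5, z=0.4x
        state = make_state(W_mean={"brain": [[2.0]]}, W_prec={"brain": [[1e18]]},
                           alpha_mean={"brain": [[1.0]]}, beta_mean={"brain": 1.0},
                           Z_mean=[[0.0, 0.0]], sigma_z_inv=[[0.0]], n_paired=2)
        update_z(state, brain_only_dataset([[1.0, -2.0]]))
        assert state.sigma_z[0, 0] == pytest.approx(5.0)
        np.testing.assert_allclose(state.Z_mean, [[0.4, -0.8]])

    def test_zero_data_gives_zero_latents(self, tiny_dataset):
        zero = MultiViewDataset(brain=np.zeros((6, 12)), visual=np.zeros((4, 12)),
                                semantic=np.zeros((3, 12)))
        state = init_state(zero, ModelConfig(latent_dim=2, seed=0))
        update_z(state, zero)
        np.testing.assert_allclose(state.Z_mean, 0.0)

    def test_ridge_limit_recovers_observations(self):
        # W = I, variances ~ 0, beta large: z_n -> x_n
        rng = np.random.default_rng(3)
        x = rng.standard_normal((3, 5))
        ds = MultiViewDataset(brain=x, visual=np.ones((2, 5)), semantic=np.ones((2, 5)))
        state = make_state(W_mean={"brain": np.eye(3)},
                           W_prec={"brain": np.full((3, 3), 1e18)},
                           alpha_mean={"brain": np.ones((3, 3))},
                           beta_mean={"brain": 1e9},
                           Z_mean=np.zeros((3, 5)), sigma_z_inv=np.zeros((3, 3)),
                           n_paired=5)
        update_z(state, ds)
        np.testing.assert_allclose(state.Z_mean, x, atol=1e-6)


class TestUpdateMissing:
    def _state(self, w, z_add, m):
        return make_state(W_mean={"brain": w}, W_prec={"brain": np.ones_like(w)},
                          alpha_mean={"brain": np.ones_like(w)},
                          beta_mean={"brain": 4.0},
                          Z_mean=z_add, sigma_z_inv=np.zeros((np.asarray(z_add).shape[0],) * 2),
                          n_paired=np.asarray(z_add).shape[1] - m, n_additional=m)

    def test_scalar_product(self):
        state = self._state([[3.0]], [[0.5, 2.0]], m=1)
        update_missing(state)
        assert state.X_miss_mean[0, 0] == pytest.approx(6.0)
        assert state.X_miss_var == pytest.approx(0.25)

    def test_identity_loading_passes_latent_through(self):
        w = np.eye(2)
        state = make_state(W_mean={"brain": w}, W_prec={"brain": np.ones((2, 2))},
                           alpha_mean={"brain": np.ones((2, 2))}, beta_mean={"brain": 1.0},
                           Z_mean=np.array([[0.0, 1.5], [0.0, -2.5]]),
                           sigma_z_inv=np.zeros((2, 2)), n_paired=1, n_additional=1)
        update_missing(state)
        np.testing.assert_allclose(state.X_miss_mean[:, 0], [1.5, -2.5])

    def test_no_additional_is_noop(self, tiny_dataset):
        state = init_state(tiny_dataset, ModelConfig(latent_dim=2, seed=0))
        before = state.X_miss_mean.copy()
        update_missing(state)
        np.testing.assert_array_equal(state.X_miss_mean, before)


class TestUpdateAlpha:
    def test_default_hand_substitution(self):
        state = make_state(W_mean={"brain": [[1.0]]}, W_prec={"brain": [[1.0]]},
                           alpha_mean={"brain": [[1.0]]}, beta_mean={"brain": 1.0},
                           Z_mean=[[0.0]], sigma_z_inv=[[0.0]], n_paired=1)
        update_alpha(state, ModelConfig())
        # with defaults alpha = 1 / (Wbar^2 + sigma^-1) = 1/2
        assert state.alpha_mean["brain"][0, 0] == pytest.approx(0.5)
        assert state.alpha_shape == 0.5

    def test_pruned_component_clipped_at_cap(self):
        state = make_state(W_mean={"brain": [[0.0]]}, W_prec={"brain": [[1e30]]},
                           alpha_mean={"brain": [[1.0]]}, beta_mean={"brain": 1.0},
                           Z_mean=[[0.0]], sigma_z_inv=[[0.0]], n_paired=1)
        cfg = ModelConfig(alpha_cap=1e8)
        update_alpha(state, cfg)
        assert state.alpha_mean["brain"][0, 0] == cfg.alpha_cap


class TestUpdateBeta:
    def test_shape_parameter(self):
        rng = np.random.default_rng(0)
        ds = MultiViewDataset(brain=rng.standard_normal((10, 20)),
                              visual=rng.standard_normal((4, 20)),
                              semantic=rng.standard_normal((4, 20)))
        state = init_state(ds, ModelConfig(latent_dim=2, seed=0,
                                           included_views=("brain",)))
        update_beta(state, ds, "brain", ModelConfig())
        assert state.beta_shape["brain"] == pytest.approx(100.0)  # Dk(N+M)/2

    def test_scalar_residual_case(self):
        # residuals [1,1], no variance terms, Dk=1, N+M=2 -> 1/beta = 1
        state = make_state(W_mean={"brain": [[0.0]]}, W_prec={"brain": [[1e30]]},
                           alpha_mean={"brain": [[1.0]]}, beta_mean={"brain": 1.0},
                           Z_mean=[[0.0, 0.0]], sigma_z_inv=[[0.0]], n_paired=2)
        update_beta(state, brain_only_dataset([[1.0, 1.0]]), "brain", ModelConfig())
        assert state.beta_mean["brain"] == pytest.approx(1.0)

    def test_perfect_fit_hits_variance_floor(self):
        state = make_state(W_mean={"brain": [[1.0]]}, W_prec={"brain": [[1e30]]},
                           alpha_mean={"brain": [[1.0]]}, beta_mean={"brain": 1.0},
                           Z_mean=[[1.0, 2.0]], sigma_z_inv=[[0.0]], n_paired=2)
        cfg = ModelConfig(beta_var_floor=1e-12)
        update_beta(state, brain_only_dataset([[1.0, 2.0]]), "brain", cfg)
        assert state.beta_mean["brain"] == pytest.approx(1e12)


class TestConjugacyOracle:
    def test_qw_matches_grid_posterior(self):
        """For the scalar one-view model with z treated as known, the q(W)
        update must equal the exact Bayesian posterior of scalar
        linear-Gaussian regression, here computed by numerical integration."""
        rng = np.random.default_rng(8)
        z = rng.standard_normal(6)
        beta, alpha = 2.3, 0.7
        w_true = 1.4
        x = w_true * z + rng.normal(scale=beta ** -0.5, size=6)
        state = make_state(W_mean={"brain": [[0.0]]}, W_prec={"brain": [[1.0]]},
                           alpha_mean={"brain": [[alpha]]}, beta_mean={"brain": beta},
                           Z_mean=z[None, :], sigma_z_inv=[[0.0]], n_paired=6)
        update_w(state, brain_only_dataset(x[None, :]), "brain")
        vi_mean = state.W_mean["brain"][0, 0]
        vi_var = 1.0 / state.W_prec["brain"][0, 0]
        # brute-force normalization of the unnormalized posterior on a grid
        grid = np.linspace(-10, 10, 400_001)
        log_post = (-0.5 * beta * ((x[None, :] - grid[:, None] * z[None, :]) ** 2).sum(axis=1)
                    - 0.5 * alpha * grid ** 2)
        post = np.exp(log_post - log_post.max())
        post /= np.trapezoid(post, grid)
        grid_mean = np.trapezoid(grid * post, grid)
        grid_var = np.trapezoid((grid - grid_mean) ** 2 * post, grid)
        assert vi_mean == pytest.approx(grid_mean, abs=1e-6)
        assert vi_var == pytest.approx(grid_var, abs=1e-6)


def _reference_two_view_fit(data, view2, dz, n_iter, seed, alpha_cap=1e8,
                            var_floor=1e-12):
    """Independent plain-numpy coordinate ascent for the two-view special
    case (brain + one feature view, no additional samples)."""
    mats = {"brain": data.brain, view2: data.view(view2)}
    dims = {k: v.shape[0] for k, v in mats.items()}
    n = data.n_paired
    rng = np.random.default_rng(seed)
    z = rng.standard_normal((dz, n))
    rng.standard_normal((dims["brain"], 0))  # mirrors the (empty) missing draw
    w = {k: rng.standard_normal((dims[k], dz)) for k in mats}
    prec = {k: np.ones((dims[k], dz)) for k in mats}
    alpha = {k: np.ones((dims[k], dz)) for k in mats}
    beta = {k: 1.0 for k in mats}
    sz_inv = np.eye(dz)
    for _ in range(n_iter):
        for k in mats:
            zz = (z ** 2).sum(axis=1) + n * np.diag(sz_inv)
            prec[k] = beta[k] * zz[None, :] + alpha[k]
            w[k] = (beta[k] / prec[k]) * (mats[k] @ z.T)
        sz = np.eye(dz)
        rhs = np.zeros((dz, n))
        for k in mats:
            v = (1.0 / prec[k]).sum(axis=0)
            sz = sz + beta[k] * (w[k].T @ w[k] + np.diag(v))
            rhs = rhs + beta[k] * (w[k].T @ mats[k])
        sz = 0.5 * (sz + sz.T)
        sz_inv = np.linalg.inv(sz)
        z = np.linalg.solve(sz, rhs)
        for k in mats:
            alpha[k] = np.minimum(1.0 / (w[k] ** 2 + 1.0 / prec[k]), alpha_cap)
        for k in mats:
            v = (1.0 / prec[k]).sum(axis=0)
            zz = (z ** 2).sum(axis=1) + n * np.diag(sz_inv)
            bracket = (((mats[k] - w[k] @ z) ** 2).sum() + (v * zz).sum()
                       + n * np.sum(sz_inv * (w[k].T @ w[k])))
            beta[k] = 1.0 / max(bracket / (dims[k] * n), var_floor)
    return w, z, beta


class TestFit:
    def test_runs_ten_iterations_by_default(self, tiny_dataset):
        res = MultiViewEmbedding(tiny_dataset, latent_dim=2, seed=0).fit()
        assert len(res.diagnostics) == 10

    def test_positivity_and_spd_after_fit(self, recovery_fit):
        state = recovery_fit.state
        for k in state.views:
            assert np.all(state.W_prec[k] > 0)
            assert np.all(state.alpha_mean[k] > 0)
            assert state.beta_mean[k] > 0
        np.linalg.cholesky(state.sigma_z)  # raises if not SPD

    def test_reconstruction_error_non_increasing(self, recovery_fit):
        for k in recovery_fit.state.views:
            trace = [d["reconstruction_error"][k] for d in recovery_fit.diagnostics]
            assert np.all(np.diff(trace) <= 1e-6)

    @pytest.mark.parametrize("view2", ["visual", "semantic"])
    def test_two_view_reduction_ignores_excluded_view(self, tiny_dataset, view2):
        """BCCA against one feature space: the excluded view must not touch
        the trajectory at all (bit-identical states)."""
        excluded = "semantic" if view2 == "visual" else "visual"
        scrambled = MultiViewDataset(
            brain=tiny_dataset.brain, visual=tiny_dataset.visual.copy(),
            semantic=tiny_dataset.semantic.copy(),
            paired_labels=tiny_dataset.paired_labels)
        getattr(scrambled, excluded)[:] = 99.0 + getattr(scrambled, excluded)
        kw = dict(latent_dim=2, seed=3, included_views=("brain", view2),
                  standardize=False)
        a = MultiViewEmbedding(tiny_dataset, **kw).fit()
        b = MultiViewEmbedding(scrambled, **kw).fit()
        np.testing.assert_array_equal(a.state.Z_mean, b.state.Z_mean)
        for k in a.state.views:
            np.testing.assert_array_equal(a.state.W_mean[k], b.state.W_mean[k])
        assert a.state.beta_mean == b.state.beta_mean

    @pytest.mark.parametrize("view2", ["visual", "semantic"])
    def test_two_view_reduction_matches_reference(self, tiny_dataset, view2):
        res = MultiViewEmbedding(tiny_dataset, latent_dim=2, seed=3,
                                 included_views=("brain", view2),
                                 standardize=False).fit()
        w, z, beta = _reference_two_view_fit(tiny_dataset, view2, dz=2,
                                             n_iter=10, seed=3)
        np.testing.assert_allclose(res.state.Z_mean, z, atol=1e-8)
        for k in res.state.views:
            np.testing.assert_allclose(res.state.W_mean[k], w[k], atol=1e-8)
            assert res.state.beta_mean[k] == pytest.approx(beta[k], rel=1e-8)

    def test_pure_noise_loadings_collapse(self):
        """With no shared signal, ARD drives the loading columns to zero and
        the precision means far above their prior within the default 10
        iterations (the precisions keep growing additively and reach the
        overflow cap only in the infinite-iteration limit)."""
        rng = np.random.default_rng(3)
        ds = MultiViewDataset(brain=rng.standard_normal((20, 200)),
                              visual=rng.standard_normal((5, 200)),
                              semantic=rng.standard_normal((5, 200)))
        res = MultiViewEmbedding(ds, latent_dim=2, seed=9,
                                 included_views=("brain",), standardize=False).fit()
        norms = np.linalg.norm(res.state.W_mean["brain"], axis=0)
        assert np.all(norms < 1e-3)
        assert np.all(res.state.alpha_mean["brain"] > 1e3)

    def test_numerical_error_reports_view_and_iteration(self):
        state = make_state(W_mean={"brain": [[1.0]]}, W_prec={"brain": [[1.0]]},
                           alpha_mean={"brain": [[1.0]]},
                           beta_mean={"brain": float("inf")},
                           Z_mean=[[1.0]], sigma_z_inv=[[0.0]], n_paired=1)
        with pytest.raises(NumericalError, match=r"brain.*iteration 4"):
            update_w(state, brain_only_dataset([[2.0]]), "brain", iteration=4)


class TestRecovery:
    def test_loading_subspace_recovered(self, recovery_truth, recovery_bundle,
                                        recovery_fit):
        from scipy.linalg import subspace_angles
        model = recovery_fit.model
        for k in recovery_fit.state.views:
            true_active = recovery_truth.W[k][:, :4] / model.stats[k].std[:, None]
            ang = np.degrees(subspace_angles(recovery_fit.state.W_mean[k], true_active))
            assert ang.max() < 15.0

    def test_missing_brain_columns_recovered(self, recovery_bundle, recovery_fit):
        from zsdecode import standardize_apply
        truth = standardize_apply(recovery_bundle.withheld["add_brain_true"],
                                  recovery_fit.model.stats["brain"])
        r = np.corrcoef(recovery_fit.imputed_brain.ravel(), truth.ravel())[0, 1]
        assert r > 0.8

    def test_inactive_latent_direction_suppressed(self, recovery_fit):
        # one of the 5 latent columns carries no signal in any view; the
        # fitted loadings must retain only 4 directions
        for k in recovery_fit.state.views:
            assert recovery_fit.effective_latent_rank(k) == 4


class TestCheckpoint:
    def test_save_load_prediction_roundtrip(self, recovery_bundle, recovery_fit,
                                            tmp_path):
        from zsdecode.model import VIResults
        recovery_fit.save(tmp_path / "ckpt")
        loaded = VIResults.load(tmp_path / "ckpt")
        x = recovery_bundle.test.brain_test[:, :3]
        for view in ("visual", "semantic"):
            a = recovery_fit.predict(x, view=view).mean
            b = loaded.predict(x, view=view).mean
            np.testing.assert_allclose(a, b, atol=1e-9)

    def test_summary_mentions_views_and_iterations(self, recovery_fit):
        text = recovery_fit.summary()
        assert "brain" in text and "visual" in text and "semantic" in text
        assert "iterations: 10" in text
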