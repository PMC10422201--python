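"""Semi-supervised multi-view generative model and its variational fit.

The model assumes each observed view k (brain activity f, visual features v,
semantic features s) is a linear map of a shared latent variable z_n with
isotropic Gaussian noise::

    x_n^(k) = W^(k) z_n + e_n,   e_n ~ N(0, beta_k^{-1} I)

with element-wise Gaussian priors on the loadings W^(k) whose precisions
alpha_ij^(k) carry Gamma hyperpriors (automatic relevance determination), a
standard-normal prior on z_n, and an uninformative prior on the noise
precisions beta_k.  Additional samples that have visual and semantic
features but no recorded brain activity enter the model with their brain
columns treated as missing values; the missing columns are imputed as
posterior means while the model is fitted.

Inference is mean-field coordinate ascent with the factorization
q(X_miss) q(Z) q(W) q(alpha) q(beta), cycling the closed-form updates in the
fixed order  W -> Z -> X_miss -> alpha -> beta  for a fixed number of
iterations (10 by default).

The public surface follows the statsmodels convention: build a
:class:`MultiViewEmbedding` from a dataset, call :meth:`~MultiViewEmbedding.fit`
(or :meth:`~MultiViewEmbedding.fit_ensemble`), and read estimates,
diagnostics and predictions off the returned results object.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import linalg

from .data import VIEWS, MultiViewDataset, StandardizationStats, standardize_apply, standardize_fit
from .exceptions import ConfigError, DataError, NumericalError

__all__ = [
    "ModelConfig",
    "VariationalState",
    "MultiViewEmbedding",
    "VIResults",
    "PredictiveResult",
    "EnsemblePrediction",
    "init_state",
    "update_w",
    "update_z",
    "update_missing",
    "update_alpha",
    "update_beta",
    "compute_diagnostics",
    "infer_test_latent",
    "predict_view",
    "ensemble_predict",
]


# ---------------------------------------------------------------------------
# configuration


@dataclass(frozen=True)
class ModelConfig:
    """Hyperparameters and run controls for the variational fit.

    Parameters
    ----------
    latent_dim : int or "auto"
        Dimension of the shared latent variable.  "auto" uses the smallest
        feature dimension among the included views.
    n_iterations : int
        Number of full coordinate-ascent cycles (default 10).
    ard_prior_mean, ard_prior_shape, ard_prior_scale :
        Gamma hyperprior on the loading precisions: prior mean
        ``ard_prior_mean`` (default 1), prior shape (default 0, i.e. the
        broad ARD limit) and the prior scale term that multiplies the shape
        in the posterior-mean update (default 0).
    seed : int
        Seed for the random initialization; every fit is deterministic
        given the seed.
    alpha_cap : float
        Upper clip for the ARD precision means; pruning drives them to
        infinity, clipping keeps arithmetic finite.
    beta_var_floor : float
        Lower floor on the posterior mean noise variance ``1/beta``.
    included_views : tuple of str
        Views entering the likelihood; must contain "brain".  The two-view
        special cases {brain, visual} and {brain, semantic} reproduce
        Bayesian CCA against a single feature space.
    rel_tol : float or None
        Optional early stop on the relative change of the reconstruction
        diagnostic; disabled (None) by default to keep the printed protocol
        of a fixed iteration count.
    """

    latent_dim: int | str = "auto"
    n_iterations: int = 10
    ard_prior_mean: float = 1.0
    ard_prior_shape: float = 0.0
    ard_prior_scale: float = 0.0
    seed: int = 0
    alpha_cap: float = 1e8
    beta_var_floor: float = 1e-12
    included_views: tuple[str, ...] = VIEWS
    rel_tol: float | None = None

    def __post_init__(self) -> None:
        views = tuple(self.included_views)
        object.__setattr__(self, "included_views", views)
        if "brain" not in views:
            raise ConfigError("included_views must contain 'brain'")
        unknown = set(views) - set(VIEWS)
        if unknown:
            raise ConfigError(f"unknown views: {sorted(unknown)}")
        if self.n_iterations < 1:
            raise ConfigError("n_iterations must be >= 1")
        if self.latent_dim != "auto" and (not isinstance(self.latent_dim, (int, np.integer))
                                          or self.latent_dim < 1):
            raise ConfigError("latent_dim must be a positive integer or 'auto'")
        if self.ard_prior_mean <= 0:
            raise ConfigError("ard_prior_mean must be positive")
        if self.ard_prior_shape < 0 or self.ard_prior_scale < 0:
            raise ConfigError("ARD shape/scale terms must be non-negative")
        if self.alpha_cap <= self.ard_prior_mean:
            raise ConfigError("alpha_cap must exceed ard_prior_mean")

    def resolve_latent_dim(self, dims: dict[str, int]) -> int:
        included = {k: dims[k] for k in self.included_views}
        if self.latent_dim == "auto":
            return min(included.values())
        dz = int(self.latent_dim)
        if dz > min(included.values()):
            raise ConfigError(
                f"latent_dim={dz} exceeds the smallest included view dimension "
                f"({min(included.values())})"
            )
        return dz

    def to_dict(self) -> dict:
        return {
            "latent_dim": self.latent_dim,
            "n_iterations": self.n_iterations,
            "ard_prior_mean": self.ard_prior_mean,
            "ard_prior_shape": self.ard_prior_shape,
            "ard_prior_scale": self.ard_prior_scale,
            "seed": self.seed,
            "alpha_cap": self.alpha_cap,
            "beta_var_floor": self.beta_var_floor,
            "included_views": list(self.included_views),
            "rel_tol": self.rel_tol,
        }


# ---------------------------------------------------------------------------
# variational state


@dataclass
class VariationalState:
    """All factor-distribution parameters of the mean-field posterior.

    Per included view k: loading means ``W_mean[k]`` (D_k x Dz), element-wise
    loading precisions ``W_prec[k]``, ARD precision means ``alpha_mean[k]``
    and common shape ``alpha_shape``, noise precision mean ``beta_mean[k]``
    and shape ``beta_shape[k]``.  Shared: latent means ``Z_mean``
    (Dz x (N+M)), latent precision ``sigma_z`` (one SPD matrix for all
    samples) and its inverse, imputed missing brain means ``X_miss_mean``
    (Df x M) with scalar per-coordinate variance ``X_miss_var``.
    """

    views: tuple[str, ...]
    n_paired: int
    n_additional: int
    latent_dim: int
    W_mean: dict[str, np.ndarray]
    W_prec: dict[str, np.ndarray]
    alpha_mean: dict[str, np.ndarray]
    alpha_shape: float
    beta_mean: dict[str, float]
    beta_shape: dict[str, float]
    Z_mean: np.ndarray
    sigma_z: np.ndarray
    sigma_z_inv: np.ndarray
    X_miss_mean: np.ndarray
    X_miss_var: float = 1.0
    diagnostics: list[dict] = field(default_factory=list)

    @property
    def n_total(self) -> int:
        return self.n_paired + self.n_additional

    def loading_var_diag(self, view: str) -> np.ndarray:
        """Column sums of element-wise loading variances, the diagonal
        aggregation entering the latent and noise updates."""
        return (1.0 / self.W_prec[view]).sum(axis=0)

    def view_data(self, data: MultiViewDataset, view: str) -> np.ndarray:
        """Observed columns of one view, with imputed means standing in for
        the missing brain columns of the additional block."""
        if self.n_additional == 0:
            return data.view(view)
        if view == "brain":
            return np.concatenate([data.brain, self.X_miss_mean], axis=1)
        return np.concatenate([data.view(view), data.additional(view)], axis=1)

    def n_pruned(self, cap: float) -> int:
        """Latent columns whose ARD precisions sit at the clip in every view."""
        pruned = np.ones(self.latent_dim, dtype=bool)
        for k in self.views:
            pruned &= np.all(self.alpha_mean[k] >= cap * (1 - 1e-9), axis=0)
        return int(pruned.sum())


def _check_finite(x: np.ndarray, what: str, iteration: int | None = None) -> None:
    if not np.all(np.isfinite(x)):
        where = f" at iteration {iteration}" if iteration is not None else ""
        raise NumericalError(f"non-finite values in {what}{where}")


def init_state(data: MultiViewDataset, config: ModelConfig) -> VariationalState:
    """Draw the initial state from the prior with the config seed.

    Latent means and missing brain columns are i.i.d. standard normal;
    loading means are drawn from their ARD prior given the prior precision
    mean; ARD means start at the prior mean with posterior shape
    ``1/2 + gamma_0``; noise precision means start at 1; the latent
    precision and loading precisions start at identity scale.
    """
    dims = data.dims
    dz = config.resolve_latent_dim(dims)
    n, m = data.n_paired, data.n_additional
    rng = np.random.default_rng(config.seed)
    # draw order is part of the determinism contract: Z, X_miss, then W per
    # view in canonical view order
    z = rng.standard_normal((dz, n + m))
    x_miss = rng.standard_normal((dims["brain"], m))
    w_mean, w_prec, a_mean, b_mean, b_shape = {}, {}, {}, {}, {}
    for k in VIEWS:
        if k not in config.included_views:
            continue
        dk = dims[k]
        w_mean[k] = rng.standard_normal((dk, dz)) / np.sqrt(config.ard_prior_mean)
        w_prec[k] = np.ones((dk, dz))
        a_mean[k] = np.full((dk, dz), config.ard_prior_mean)
        b_mean[k] = 1.0
        b_shape[k] = 0.5 * dk * (n + m)
    return VariationalState(
        views=tuple(k for k in VIEWS if k in config.included_views),
        n_paired=n, n_additional=m, latent_dim=dz,
        W_mean=w_mean, W_prec=w_prec,
        alpha_mean=a_mean, alpha_shape=0.5 + config.ard_prior_shape,
        beta_mean=b_mean, beta_shape=b_shape,
        Z_mean=z, sigma_z=np.eye(dz), sigma_z_inv=np.eye(dz),
        X_miss_mean=x_miss,
    )


# ---------------------------------------------------------------------------
# coordinate-ascent updates


def update_w(state: VariationalState, data: MultiViewDataset, view: str,
             *, iteration: int | None = None) -> VariationalState:
    """Update q(W^(k)): element-wise Gaussian with precision

    ``sigma_ij = beta_k (sum_n zbar_nj^2 + (N+M) [sigma_z^{-1}]_jj) + alpha_ij``

    and mean ``Wbar_ij = beta_k sigma_ij^{-1} sum_n x_ni zbar_nj``.
    """
    x = state.view_data(data, view)
    z = state.Z_mean
    beta = state.beta_mean[view]
    zz = (z ** 2).sum(axis=1) + state.n_total * np.diag(state.sigma_z_inv)
    with np.errstate(invalid="ignore"):  # non-finite inputs are caught below
        prec = beta * zz[None, :] + state.alpha_mean[view]
        mean = (beta / prec) * (x @ z.T)
    _check_finite(prec, f"q(W[{view}]) precision", iteration)
    _check_finite(mean, f"q(W[{view}]) mean", iteration)
    if np.any(prec <= 0):
        raise NumericalError(f"non-positive loading precision in view {view}")
    state.W_prec[view] = prec
    state.W_mean[view] = mean
    return state

def update_z(state: VariationalState, data: MultiViewDataset,
             *, iteration: int | None = None) -> VariationalState:
    """Update q(Z): shared precision

    ``sigma_z = sum_k beta_k (Wbar_k^T Wbar_k + V_k) + I``

    with V_k the diagonal of column-summed loading variances, and means
    ``zbar_n = sigma_z^{-1} sum_k beta_k Wbar_k^T x_n^(k)`` where the brain
    term of additional samples uses the current imputed means.
    """
    dz = state.latent_dim
    sz = np.eye(dz)
    rhs = np.zeros((dz, state.n_total))
    for k in state.views:
        w = state.W_mean[k]
        sz += state.beta_mean[k] * (w.T @ w + np.diag(state.loading_var_diag(k)))
        rhs += state.beta_mean[k] * (w.T @ state.view_data(data, k))
    sz = 0.5 * (sz + sz.T)
    try:
        cho = linalg.cho_factor(sz, lower=True)
    except linalg.LinAlgError as e:  # pragma: no cover - defensive
        raise NumericalError(f"latent precision not SPD at iteration {iteration}") from e
    state.sigma_z = sz
    state.sigma_z_inv = linalg.cho_solve(cho, np.eye(dz))
    state.Z_mean = linalg.cho_solve(cho, rhs)
    _check_finite(state.Z_mean, "q(Z) means", iteration)
    return state


def update_missing(state: VariationalState, *, iteration: int | None = None) -> VariationalState:
    """Update q(X_miss): means ``Wbar_f zbar_n`` for the additional columns,
    per-coordinate variance the current brain noise variance.  No-op when
    there are no additional samples."""
    if state.n_additional == 0:
        return state
    z_add = state.Z_mean[:, state.n_paired:]
    state.X_miss_mean = state.W_mean["brain"] @ z_add
    state.X_miss_var = 1.0 / state.beta_mean["brain"]
    _check_finite(state.X_miss_mean, "q(X_miss) means", iteration)
    return state


def update_alpha(state: VariationalState, config: ModelConfig,
                 *, iteration: int | None = None) -> VariationalState:
    """Update q(alpha^(k)): Gamma with shape ``1/2 + gamma_0`` and mean

    ``alphabar_ij = shape / (Wbar_ij^2/2 + sigma_ij^{-1}/2 + gamma_0 * scale)``

    clipped at ``alpha_cap`` (ARD drives pruned precisions to infinity).
    """
    shape = 0.5 + config.ard_prior_shape
    extra = config.ard_prior_shape * config.ard_prior_scale
    for k in state.views:
        denom = 0.5 * state.W_mean[k] ** 2 + 0.5 / state.W_prec[k] + extra
        with np.errstate(divide="ignore", over="ignore"):
            alpha = shape / denom
        alpha = np.minimum(alpha, config.alpha_cap)
        _check_finite(alpha, f"q(alpha[{k}]) mean", iteration)
        state.alpha_mean[k] = alpha
    state.alpha_shape = shape
    return state


def _expected_residual(state: VariationalState, data: MultiViewDataset, view: str) -> float:
    """Eq-20 bracket: expected total squared reconstruction error of one view
    under the current factors (residual of the means plus the loading- and
    latent-covariance corrections)."""
    x = state.view_data(data, view)
    w = state.W_mean[view]
    z = state.Z_mean
    resid = x - w @ z
    rss = float((resid ** 2).sum())
    v = state.loading_var_diag(view)
    zz = (z ** 2).sum(axis=1) + state.n_total * np.diag(state.sigma_z_inv)
    tr_v = float((v * zz).sum())
    tr_w = state.n_total * float(np.sum(state.sigma_z_inv * (w.T @ w)))
    return rss + tr_v + tr_w


def update_beta(state: VariationalState, data: MultiViewDataset, view: str,
                config: ModelConfig, *, iteration: int | None = None) -> VariationalState:
    """Update q(beta_k): Gamma with shape ``D_k (N+M) / 2`` and mean the
    inverse of the per-element expected squared reconstruction error, with
    the variance floored to keep the precision finite."""
    dk = state.W_mean[view].shape[0]
    denom = dk * state.n_total
    if denom == 0:
        raise ConfigError(f"view {view} is empty")
    inv_beta = _expected_residual(state, data, view) / denom
    inv_beta = max(inv_beta, config.beta_var_floor)
    state.beta_mean[view] = 1.0 / inv_beta
    state.beta_shape[view] = 0.5 * denom
    _check_finite(np.array(state.beta_mean[view]), f"q(beta[{view}]) mean", iteration)
    return state


def compute_diagnostics(state: VariationalState, data: MultiViewDataset,
                        config: ModelConfig) -> dict:
    """Per-view expected mean squared reconstruction error (per matrix
    element), current noise precision means, and the count of ARD-pruned
    latent components."""
    rec = {}
    for k in state.views:
        dk = state.W_mean[k].shape[0]
        rec[k] = _expected_residual(state, data, k) / (dk * state.n_total)
    return {
        "reconstruction_error": rec,
        "beta_mean": dict(state.beta_mean),
        "n_pruned": state.n_pruned(config.alpha_cap),
    }


def fit_state(data: MultiViewDataset, config: ModelConfig) -> VariationalState:
    """Run the full coordinate-ascent schedule and return the final state."""
    state = init_state(data, config)
    prev = None
    for it in range(config.n_iterations):
        for k in state.views:
            update_w(state, data, k, iteration=it)
        update_z(state, data, iteration=it)
        update_missing(state, iteration=it)
        update_alpha(state, config, iteration=it)
        for k in state.views:
            update_beta(state, data, k, config, iteration=it)
        diag = compute_diagnostics(state, data, config)
        diag["iteration"] = it
        state.diagnostics.append(diag)
        total = sum(diag["reconstruction_error"].values())
        if config.rel_tol is not None and prev is not None:
            if abs(prev - total) <= config.rel_tol * max(abs(prev), 1e-12):
                break
        prev = total
    return state


# ---------------------------------------------------------------------------
# test-time prediction


@dataclass
class PredictiveResult:
    """Predictive Gaussian for one view given test brain activity.

    ``mean`` has one column per test sample; the covariance does not depend
    on the test input, so a single D_i x D_i matrix serves all samples.
    """

    view: str
    mean: np.ndarray
    covariance: np.ndarray
    latent_mean: np.ndarray
    latent_precision: np.ndarray


@dataclass
class EnsemblePrediction:
    """Arithmetic mean of member predictive means over T independent fits."""

    means: dict[str, np.ndarray]
    T: int
    member_seeds: list[int]


def _as_test_matrix(state: VariationalState, x: np.ndarray) -> tuple[np.ndarray, bool]:
    x = np.asarray(x, dtype=float)
    one_d = x.ndim == 1
    if one_d:
        x = x[:, None]
    if x.ndim != 2 or x.shape[0] != state.W_mean["brain"].shape[0]:
        raise DataError(
            f"test brain activity must have {state.W_mean['brain'].shape[0]} features"
        )
    if not np.all(np.isfinite(x)):
        raise DataError("test brain activity contains non-finite entries")
    return x, one_d


def infer_test_latent(state: VariationalState, x_test_brain: np.ndarray
                      ) -> tuple[np.ndarray, np.ndarray]:
    """Approximate posterior of the test latent from brain activity alone:
    precision ``beta_f (W_f^T W_f + V_f) + I`` and mean
    ``beta_f sigma^{-1} W_f^T x``.  Returns (mean, precision)."""
    x, one_d = _as_test_matrix(state, x_test_brain)
    w = state.W_mean["brain"]
    beta = state.beta_mean["brain"]
    prec = beta * (w.T @ w + np.diag(state.loading_var_diag("brain"))) + np.eye(state.latent_dim)
    prec = 0.5 * (prec + prec.T)
    mean = beta * linalg.cho_solve(linalg.cho_factor(prec, lower=True), w.T @ x)
    return (mean[:, 0] if one_d else mean), prec


def predict_view(state: VariationalState, x_test_brain: np.ndarray, view: str
                 ) -> PredictiveResult:
    """Predict one feature view from test brain activity: plug the loading
    means into the likelihood and integrate over the approximate test-latent
    posterior."""
    if view not in state.views or view == "brain":
        raise ConfigError(f"view {view!r} was not fitted as a prediction target")
    x, one_d = _as_test_matrix(state, x_test_brain)
    z_mean, z_prec = infer_test_latent(state, x)
    w_i = state.W_mean[view]
    cho = linalg.cho_factor(z_prec, lower=True)
    z_cov = linalg.cho_solve(cho, np.eye(state.latent_dim))
    mean = w_i @ z_mean
    cov = w_i @ z_cov @ w_i.T + (1.0 / state.beta_mean[view]) * np.eye(w_i.shape[0])
    return PredictiveResult(
        view=view,
        mean=mean[:, 0] if one_d else mean,
        covariance=0.5 * (cov + cov.T),
        latent_mean=z_mean,
        latent_precision=z_prec,
    )


def ensemble_predict(data: MultiViewDataset, config: ModelConfig,
                     x_test_brain: np.ndarray, T: int = 100) -> EnsemblePrediction:
    """Train T models that differ only in their random initialization
    (seeds ``config.seed + 1 ... config.seed + T``), predict with each, and
    average the predictive means per view."""
    if T < 1:
        raise ConfigError("T must be >= 1")
    sums: dict[str, np.ndarray] = {}
    seeds = [config.seed + t for t in range(1, T + 1)]
    for s in seeds:
        member_cfg = replace(config, seed=s)
        try:
            state = fit_state(data, member_cfg)
            for k in state.views:
                if k == "brain":
                    continue
                pred = predict_view(state, x_test_brain, k)
                sums[k] = sums.get(k, 0.0) + pred.mean
        except Exception as e:
            raise NumericalError(f"ensemble member with seed {s} failed: {e}") from e
    return EnsemblePrediction(
        means={k: v / T for k, v in sums.items()}, T=T, member_seeds=seeds,
    )


# ---------------------------------------------------------------------------
# statsmodels-style model / results


class MultiViewEmbedding:
    """Semi-supervised multi-view embedding model.

    Parameters
    ----------
    dataset : MultiViewDataset
        Paired three-view training block, optionally with an additional
        unpaired (visual, semantic) block for target categories.
    standardize : bool
        Fit per-feature z-scoring statistics on the paired block and apply
        them to all blocks before inference (default True, matching the
        preprocessing used with real feature matrices).
    **config_kwargs :
        Forwarded to :class:`ModelConfig`.

    Examples
    --------
    >>> model = MultiViewEmbedding(dataset, latent_dim=5, seed=0)
    >>> res = model.fit()
    >>> pred = res.predict(x_test_brain, view="visual")
    """

    def __init__(self, dataset: MultiViewDataset, *, standardize: bool = True,
                 config: ModelConfig | None = None, **config_kwargs):
        if config is not None and config_kwargs:
            raise ConfigError("pass either a ModelConfig or keyword overrides, not both")
        self.config = config if config is not None else ModelConfig(**config_kwargs)
        self.raw_dataset = dataset
        self.standardize = standardize
        self.stats: dict[str, StandardizationStats] = {}
        if standardize:
            self.stats = {k: standardize_fit(dataset.view(k)) for k in VIEWS}
            add_v = add_s = None
            if dataset.n_additional:
                add_v = standardize_apply(dataset.add_visual, self.stats["visual"])
                add_s = standardize_apply(dataset.add_semantic, self.stats["semantic"])
            self.dataset = MultiViewDataset(
                brain=standardize_apply(dataset.brain, self.stats["brain"]),
                visual=standardize_apply(dataset.visual, self.stats["visual"]),
                semantic=standardize_apply(dataset.semantic, self.stats["semantic"]),
                add_visual=add_v, add_semantic=add_s,
                paired_labels=dataset.paired_labels, add_labels=dataset.add_labels,
                zero_shot=dataset.zero_shot,
            )
        else:
            self.dataset = dataset
        # resolve now so config errors surface before fitting
        self.latent_dim = self.config.resolve_latent_dim(dataset.dims)

    @classmethod
    def from_manifest(cls, manifest_path: str | Path, **kwargs) -> "MultiViewEmbedding":
        from .data import load_dataset
        ds = load_dataset(manifest_path)
        if not isinstance(ds, MultiViewDataset):
            raise DataError("manifest does not describe a multi-view training dataset")
        return cls(ds, **kwargs)

    def fit(self, seed: int | None = None) -> "VIResults":
        """Run the variational schedule; ``seed`` overrides the config seed."""
        cfg = self.config if seed is None else replace(self.config, seed=seed)
        state = fit_state(self.dataset, cfg)
        return VIResults(self, state, cfg)

    def fit_ensemble(self, x_test_brain: np.ndarray, T: int = 100,
                     *, standardized: bool = False) -> EnsemblePrediction:
        """Ensemble-average predictions over T random-restart fits.

        ``x_test_brain`` is standardized with the training statistics unless
        ``standardized`` is set.
        """
        x = np.asarray(x_test_brain, dtype=float)
        one_d = x.ndim == 1
        if one_d:
            x = x[:, None]
        if self.standardize and not standardized:
            x = standardize_apply(x, self.stats["brain"])
        ens = ensemble_predict(self.dataset, self.config, x, T=T)
        if self.standardize:
            # back to the original feature scale, like VIResults.predict
            means = {}
            for k, v in ens.means.items():
                stats = self.stats[k]
                sd = np.where(stats.zero_variance, 0.0, stats.std)
                means[k] = v * sd[:, None] + stats.mean[:, None]
            ens = EnsemblePrediction(means=means, T=ens.T, member_seeds=ens.member_seeds)
        if one_d:
            ens = EnsemblePrediction(
                means={k: v[:, 0] for k, v in ens.means.items()},
                T=ens.T, member_seeds=ens.member_seeds)
        return ens


class VIResults:
    """Results of one variational fit: the full factor state, per-iteration
    diagnostics, and predictive methods for test brain activity."""

    def __init__(self, model: MultiViewEmbedding, state: VariationalState,
                 config: ModelConfig):
        self.model = model
        self.state = state
        self.config = config

    # -- estimates ---------------------------------------------------------

    @property
    def loadings(self) -> dict[str, np.ndarray]:
        return self.state.W_mean

    @property
    def noise_precisions(self) -> dict[str, float]:
        return self.state.beta_mean

    @property
    def latent_means(self) -> np.ndarray:
        return self.state.Z_mean

    @property
    def imputed_brain(self) -> np.ndarray:
        """Imputed missing brain columns, on the standardized scale."""
        return self.state.X_miss_mean

    @property
    def diagnostics(self) -> list[dict]:
        return self.state.diagnostics

    def n_pruned(self) -> int:
        return self.state.n_pruned(self.config.alpha_cap)

    def effective_latent_rank(self, view: str | None = None) -> int:
        """Number of latent directions the fit actually retains.

        The latent basis is only identified up to rotation, so ARD pruning
        of an irrelevant latent direction shows up in the singular-value
        spectrum of the loading means rather than in any single column.
        The retained rank is detected as the position of the largest
        logarithmic gap in the spectrum of one view's loadings (or of all
        included views' loadings stacked).  Only meaningful when at least
        one direction has been suppressed; for a fully loaded spectrum the
        largest gap is arbitrary.
        """
        if view is None:
            w = np.vstack([self.state.W_mean[k] for k in self.state.views])
        else:
            w = self.state.W_mean[view]
        s = np.linalg.svd(w, compute_uv=False)
        if s.shape[0] < 2:
            return s.shape[0]
        with np.errstate(divide="ignore"):
            gaps = np.log(np.maximum(s[:-1], 1e-300)) - np.log(np.maximum(s[1:], 1e-300))
        return int(np.argmax(gaps)) + 1

    # -- prediction --------------------------------------------------------

    def _prepare_test(self, x: np.ndarray, standardized: bool) -> np.ndarray:
        x = np.asarray(x, dtype=float)
        if self.model.standardize and not standardized:
            mat = x[:, None] if x.ndim == 1 else x
            mat = standardize_apply(mat, self.model.stats["brain"])
            return mat[:, 0] if x.ndim == 1 else mat
        return x

    def infer_latent(self, x_test_brain: np.ndarray, *, standardized: bool = False):
        return infer_test_latent(self.state, self._prepare_test(x_test_brain, standardized))

    def predict(self, x_test_brain: np.ndarray, view: str = "visual",
                *, standardized: bool = False,
                original_scale: bool = True) -> PredictiveResult:
        """Predictive distribution of one feature view.

        Test brain activity is standardized with the training statistics
        (unless ``standardized``); by default the predicted mean and
        covariance are mapped back to the original feature scale so they
        are directly comparable with raw candidate vectors.
        """
        pred = predict_view(self.state, self._prepare_test(x_test_brain, standardized), view)
        if original_scale and self.model.standardize:
            stats = self.model.stats[view]
            sd = np.where(stats.zero_variance, 0.0, stats.std)
            mean = pred.mean * (sd[:, None] if pred.mean.ndim == 2 else sd)
            mean = mean + (stats.mean[:, None] if pred.mean.ndim == 2 else stats.mean)
            cov = pred.covariance * np.outer(sd, sd)
            pred = PredictiveResult(view=pred.view, mean=mean, covariance=cov,
                                    latent_mean=pred.latent_mean,
                                    latent_precision=pred.latent_precision)
        return pred

    # -- reporting ---------------------------------------------------------

    def summary(self) -> str:
        """Plain-text summary of the fit: dimensions, noise precisions,
        pruning, and the reconstruction-error trajectory."""
        st, lines = self.state, []
        lines.append("Semi-supervised multi-view embedding — variational fit")
        lines.append("=" * 58)
        lines.append(f"views: {', '.join(st.views)}   latent dim: {st.latent_dim}")
        lines.append(f"paired samples N: {st.n_paired}   additional samples M: {st.n_additional}")
        lines.append(f"iterations: {len(st.diagnostics)}   seed: {self.config.seed}")
        lines.append(f"pruned latent components: {self.n_pruned()} / {st.latent_dim}")
        lines.append("")
        lines.append(f"{'view':<10}{'D_k':>6}{'beta_mean':>14}{'recon MSE':>14}")
        last = st.diagnostics[-1] if st.diagnostics else None
        for k in st.views:
            rec = last["reconstruction_error"][k] if last else float("nan")
            lines.append(f"{k:<10}{st.W_mean[k].shape[0]:>6}"
                         f"{st.beta_mean[k]:>14.4g}{rec:>14.4g}")
        if st.diagnostics:
            trail = ", ".join(
                f"{sum(d['reconstruction_error'].values()):.4g}" for d in st.diagnostics)
            lines.append("")
            lines.append(f"total recon MSE per iteration: {trail}")
        return "\n".join(lines)

    # -- persistence -------------------------------------------------------

    def save(self, directory: str | Path) -> Path:
        """Checkpoint the fit as CSV matrices plus JSON scalars."""
        directory = Path(directory)
        directory.mkdir(parents=True, exist_ok=True)
        meta = {
            "config": self.config.to_dict(),
            "views": list(self.state.views),
            "n_paired": self.state.n_paired,
            "n_additional": self.state.n_additional,
            "latent_dim": self.state.latent_dim,
            "beta_mean": self.state.beta_mean,
            "beta_shape": self.state.beta_shape,
            "alpha_shape": self.state.alpha_shape,
            "X_miss_var": self.state.X_miss_var,
            "diagnostics": self.state.diagnostics,
            "standardize": self.model.standardize,
        }
        for k in self.state.views:
            pd.DataFrame(self.state.W_mean[k]).to_csv(directory / f"W_mean_{k}.csv", index=False)
            pd.DataFrame(self.state.W_prec[k]).to_csv(directory / f"W_prec_{k}.csv", index=False)
            pd.DataFrame(self.state.alpha_mean[k]).to_csv(
                directory / f"alpha_mean_{k}.csv", index=False)
        pd.DataFrame(self.state.Z_mean).to_csv(directory / "Z_mean.csv", index=False)
        pd.DataFrame(self.state.sigma_z).to_csv(directory / "sigma_z.csv", index=False)
        if self.state.n_additional:
            pd.DataFrame(self.state.X_miss_mean).to_csv(directory / "X_miss_mean.csv", index=False)
        if self.model.standardize:
            for k, s in self.model.stats.items():
                pd.DataFrame({"mean": s.mean, "std": s.std,
                              "zero_variance": s.zero_variance.astype(int)}
                             ).to_csv(directory / f"stats_{k}.csv", index=False)
        (directory / "meta.json").write_text(json.dumps(meta, indent=2))
        return directory

    @classmethod
    def load(cls, directory: str | Path) -> "VIResults":
        """Restore a checkpoint for prediction; the training data itself is
        not stored, so refitting from a loaded results object is not
        supported."""
        directory = Path(directory)
        meta = json.loads((directory / "meta.json").read_text())
        config = ModelConfig(**{**meta["config"],
                                "included_views": tuple(meta["config"]["included_views"])})
        views = tuple(meta["views"])
        read = lambda name: pd.read_csv(directory / name).to_numpy(dtype=float)
        w_mean = {k: read(f"W_mean_{k}.csv") for k in views}
        w_prec = {k: read(f"W_prec_{k}.csv") for k in views}
        a_mean = {k: read(f"alpha_mean_{k}.csv") for k in views}
        z = read("Z_mean.csv")
        sz = read("sigma_z.csv")
        m = meta["n_additional"]
        x_miss = (read("X_miss_mean.csv") if m else
                  np.zeros((w_mean["brain"].shape[0], 0)))
        state = VariationalState(
            views=views, n_paired=meta["n_paired"], n_additional=m,
            latent_dim=meta["latent_dim"], W_mean=w_mean, W_prec=w_prec,
            alpha_mean=a_mean, alpha_shape=meta["alpha_shape"],
            beta_mean={k: float(v) for k, v in meta["beta_mean"].items()},
            beta_shape={k: float(v) for k, v in meta["beta_shape"].items()},
            Z_mean=z, sigma_z=sz, sigma_z_inv=np.linalg.inv(sz),
            X_miss_mean=x_miss, X_miss_var=meta["X_miss_var"],
            diagnostics=meta["diagnostics"],
        )
        shell = cls.__new__(cls)
        shell.config = config
        shell.state = state

        class _LoadedModel:
            standardize = bool(meta.get("standardize", False))
            stats = {}
        lm = _LoadedModel()
        if lm.standardize:
            for k in VIEWS:
                p = directory / f"stats_{k}.csv"
                if p.exists():
                    df = pd.read_csv(p)
                    lm.stats[k] = StandardizationStats(
                        mean=df["mean"].to_numpy(),
                        std=df["std"].to_numpy(),
                        zero_variance=df["zero_variance"].to_numpy().astype(bool))
        shell.model = lm
        return shell
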