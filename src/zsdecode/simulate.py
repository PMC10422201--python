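"""Synthetic data from the model's own generative process.

The generator emulates the structure of a zero-shot neural decoding study:
category-clustered latents (one prototype per category, isotropic
within-category spread tau), three views produced by linear loadings plus
isotropic Gaussian noise, a paired source block with all three views, an
unpaired target block with visual and semantic features only (the withheld
true brain columns are kept as ground truth for imputation checks), a test
block of target-category brain activity, and per-category noiseless
prototype vectors as the candidate set.

Source-category prototypes are drawn from a biased region of latent space:
shifted away from the target categories along a random direction, and
compressed (low variance) along part of the latent axes, emulating a study
whose source categories only explore a narrow slice of the semantic space.
Mappings fitted on such source data misplace target embeddings — the
projection-domain-shift phenomenon — and additional target-category
feature data is what rectifies it.  Shift and compression magnitudes are
knobs.

All randomness flows from one integer seed through a documented
stream-splitting rule: ``SeedSequence(seed)`` spawns the truth stream (used
for loadings and prototypes), the data stream (training and additional
samples) and the test stream, in that order.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from pathlib import Path
from typing import NamedTuple

import numpy as np

from .data import (CandidateSet, MultiViewDataset, TestSet, VIEWS, write_dataset)
from .exceptions import ConfigError

__all__ = [
    "SyntheticGroundTruth",
    "SyntheticBundle",
    "DEFAULT_PRESET",
    "sample_ground_truth",
    "sample_dataset",
    "make_benchmark",
]

# desk-scale default: dimensions small enough for second-scale fits but with
# the qualitative features of the real problem (brain the widest view, many
# source categories, a handful of zero-shot targets)
DEFAULT_PRESET = {
    "dims": {"brain": 60, "visual": 40, "semantic": 20},
    "latent_dim": 5,
    "n_source_categories": 20,
    "n_target_categories": 8,
    "n_candidate_only_categories": 12,
    "zero_latent_columns": (),
    "snr": {"brain": 2.0, "visual": 10.0, "semantic": 10.0},
    "tau": 0.5,
    "prototype_shift": 2.0,
    "source_compression": 0.25,
    "n_per_source_category": 8,
    "m_add_per_target_category": 25,
    "n_test_per_target_category": 5,
}


@dataclass
class SyntheticGroundTruth:
    """True generative parameters behind a synthetic study."""

    W: dict[str, np.ndarray]
    beta: dict[str, float]
    prototypes: np.ndarray  # Dz x n_categories
    category_names: list[str]
    source: list[str]
    target: list[str]
    candidate_only: list[str]
    tau: float
    zero_latent_columns: tuple[int, ...]
    seed: int

    @property
    def latent_dim(self) -> int:
        return self.prototypes.shape[0]

    def prototype(self, name: str) -> np.ndarray:
        return self.prototypes[:, self.category_names.index(name)]

    def view_prototype(self, view: str, name: str) -> np.ndarray:
        """Noiseless feature prototype W^(k) mu_c of one category."""
        return self.W[view] @ self.prototype(name)


class SyntheticBundle(NamedTuple):
    """A sampled study plus the withheld quantities needed for scoring."""

    dataset: MultiViewDataset
    test: TestSet
    candidates: CandidateSet
    withheld: dict


def sample_ground_truth(dims: dict[str, int] | None = None,
                        latent_dim: int = 5,
                        n_source_categories: int = 20,
                        n_target_categories: int = 8,
                        n_candidate_only_categories: int = 12,
                        zero_latent_columns: tuple[int, ...] = (),
                        snr: float | dict[str, float] = 10.0,
                        tau: float = 0.5,
                        prototype_shift: float = 2.0,
                        source_compression: float = 1.0,
                        seed: int = 0) -> SyntheticGroundTruth:
    """Draw true loadings, noise precisions and category prototypes.

    ``zero_latent_columns`` lists latent components whose loadings are
    exactly zero in every view — the sparsity pattern an ARD fit should
    prune.  ``snr`` sets each view's noise precision so that the average
    per-coordinate signal power divided by the noise variance equals the
    requested ratio.  Source prototypes are centered ``prototype_shift``
    away (along a random unit direction) from the target/candidate
    prototypes, which are centered at the origin, and their spread along
    the last ``Dz // 2`` latent axes is scaled by ``source_compression``
    (1 = no compression): with compression < 1 the source categories only
    weakly explore those axes while targets vary fully along them, which
    is what makes source-fitted mappings misplace target embeddings.
    """
    dims = dict(DEFAULT_PRESET["dims"]) if dims is None else dict(dims)
    if any(d < 1 for d in dims.values()) or latent_dim < 1:
        raise ConfigError("dimensions must be positive")
    if any(j < 0 or j >= latent_dim for j in zero_latent_columns):
        raise ConfigError("zero_latent_columns outside the latent dimension")
    snr_map = {k: float(snr) for k in VIEWS} if np.isscalar(snr) else dict(snr)
    if any(snr_map[k] <= 0 for k in VIEWS):
        raise ConfigError("snr must be positive")
    if n_target_categories < 1 or n_source_categories < 1:
        raise ConfigError("source and target category counts must be >= 1")

    rng = np.random.default_rng(np.random.SeedSequence(seed).spawn(3)[0])  # truth stream
    w = {}
    for k in VIEWS:
        wk = rng.standard_normal((dims[k], latent_dim))
        wk[:, list(zero_latent_columns)] = 0.0
        w[k] = wk

    names_source = [f"src{i:03d}" for i in range(n_source_categories)]
    names_target = [f"tgt{i:03d}" for i in range(n_target_categories)]
    names_cand = [f"cnd{i:03d}" for i in range(n_candidate_only_categories)]
    names = names_source + names_target + names_cand

    if not 0 < source_compression <= 1:
        raise ConfigError("source_compression must lie in (0, 1]")
    shift_dir = rng.standard_normal(latent_dim)
    shift_dir /= np.linalg.norm(shift_dir)
    protos = rng.standard_normal((latent_dim, len(names)))
    compressed = np.arange(latent_dim - latent_dim // 2, latent_dim)
    protos[np.ix_(compressed, np.arange(n_source_categories))] *= source_compression
    protos[:, :n_source_categories] += prototype_shift * shift_dir[:, None]

    # noise precision from the requested SNR: signal power per coordinate
    # averaged over features, with E[z_j^2] taken over prototypes plus the
    # within-category spread
    ez2 = (protos ** 2).mean(axis=1) + tau ** 2
    beta = {}
    for k in VIEWS:
        signal = float(((w[k] ** 2) * ez2[None, :]).sum(axis=1).mean())
        signal = max(signal, 1e-12)
        beta[k] = snr_map[k] / signal

    return SyntheticGroundTruth(
        W=w, beta=beta, prototypes=protos, category_names=names,
        source=names_source, target=names_target, candidate_only=names_cand,
        tau=tau, zero_latent_columns=tuple(zero_latent_columns), seed=seed,
    )


def _sample_block(truth: SyntheticGroundTruth, rng: np.random.Generator,
                  categories: list[str], n_per: int) -> tuple[dict, np.ndarray, list[str]]:
    """Sample ``n_per`` observations of every category: latents
    ``z = mu_c + tau * eps`` and all three views ``W z + beta^{-1/2} eps``."""
    labels = [c for c in categories for _ in range(n_per)]
    mus = np.stack([truth.prototype(c) for c in labels], axis=1)
    z = mus + truth.tau * rng.standard_normal(mus.shape)
    views = {}
    for k in VIEWS:
        noise_sd = truth.beta[k] ** -0.5
        views[k] = truth.W[k] @ z + noise_sd * rng.standard_normal(
            (truth.W[k].shape[0], z.shape[1]))
    return views, z, labels


def sample_dataset(truth: SyntheticGroundTruth,
                   n_per_source_category: int = 8,
                   m_add_per_target_category: int = 25,
                   n_test_per_target_category: int = 5,
                   seed: int = 0) -> SyntheticBundle:
    """Sample a full zero-shot study from the ground truth.

    The paired block covers source categories with all three views; the
    additional block covers target categories with visual and semantic
    features only (its true brain columns and latents are returned in
    ``withheld``); the test block is target-category brain activity; the
    candidate set holds noiseless per-category prototypes for every
    category, including candidate-only distractors.
    """
    if n_per_source_category < 1 or n_test_per_target_category < 1:
        raise ConfigError("sample counts must be >= 1")
    if m_add_per_target_category < 0:
        raise ConfigError("m_add_per_target_category must be >= 0")
    if not truth.target:
        raise ConfigError("ground truth has no target categories")
    streams = np.random.SeedSequence(seed).spawn(3)
    data_rng = np.random.default_rng(streams[1])   # data stream
    test_rng = np.random.default_rng(streams[2])   # test stream

    paired_views, paired_z, paired_labels = _sample_block(
        truth, data_rng, truth.source, n_per_source_category)

    if m_add_per_target_category > 0:
        add_views, add_z, add_labels = _sample_block(
            truth, data_rng, truth.target, m_add_per_target_category)
        add_visual, add_semantic = add_views["visual"], add_views["semantic"]
        add_brain_true = add_views["brain"]
    else:
        add_visual = add_semantic = add_brain_true = None
        add_z, add_labels = np.zeros((truth.latent_dim, 0)), []

    test_views, test_z, test_labels = _sample_block(
        truth, test_rng, truth.target, n_test_per_target_category)

    dataset = MultiViewDataset(
        brain=paired_views["brain"], visual=paired_views["visual"],
        semantic=paired_views["semantic"],
        add_visual=add_visual, add_semantic=add_semantic,
        paired_labels=paired_labels, add_labels=add_labels, zero_shot=True,
    )
    test = TestSet(brain_test=test_views["brain"], true_labels=test_labels)
    candidates = CandidateSet(
        names=list(truth.category_names),
        cand_visual=np.stack([truth.view_prototype("visual", c)
                              for c in truth.category_names], axis=1),
        cand_semantic=np.stack([truth.view_prototype("semantic", c)
                                for c in truth.category_names], axis=1),
    )
    withheld = {
        "add_brain_true": add_brain_true,
        "add_latents": add_z,
        "paired_latents": paired_z,
        "test_latents": test_z,
        "test_visual_true": test_views["visual"],
        "test_semantic_true": test_views["semantic"],
    }
    return SyntheticBundle(dataset=dataset, test=test, candidates=candidates,
                           withheld=withheld)


def make_benchmark(outdir: str | Path, config: dict | None = None,
                   seed: int = 0) -> dict:
    """Write a ready-to-run zero-shot benchmark bundle to disk.

    Produces manifests for the training dataset, the test set and the
    candidate set, plus a ground-truth JSON (loadings, noise precisions,
    prototypes, withheld brain columns) for scoring, and a config echo with
    the seed.  Returns the manifest paths.
    """
    cfg = dict(DEFAULT_PRESET)
    cfg.update(config or {})
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    truth = sample_ground_truth(
        dims=cfg["dims"], latent_dim=cfg["latent_dim"],
        n_source_categories=cfg["n_source_categories"],
        n_target_categories=cfg["n_target_categories"],
        n_candidate_only_categories=cfg["n_candidate_only_categories"],
        zero_latent_columns=tuple(cfg["zero_latent_columns"]),
        snr=cfg["snr"], tau=cfg["tau"],
        prototype_shift=cfg["prototype_shift"],
        source_compression=cfg["source_compression"], seed=seed,
    )
    bundle = sample_dataset(
        truth,
        n_per_source_category=cfg["n_per_source_category"],
        m_add_per_target_category=cfg["m_add_per_target_category"],
        n_test_per_target_category=cfg["n_test_per_target_category"],
        seed=seed,
    )
    paths = {
        "dataset": str(write_dataset(bundle.dataset, outdir / "dataset")),
        "test": str(write_dataset(bundle.test, outdir / "test")),
        "candidates": str(write_dataset(bundle.candidates, outdir / "candidates")),
    }
    gt = {
        "seed": seed,
        "config": {**cfg, "zero_latent_columns": list(cfg["zero_latent_columns"])},
        "beta": truth.beta,
        "tau": truth.tau,
        "source": truth.source,
        "target": truth.target,
        "candidate_only": truth.candidate_only,
        "W": {k: truth.W[k].tolist() for k in VIEWS},
        "prototypes": truth.prototypes.tolist(),
        "add_brain_true": (bundle.withheld["add_brain_true"].tolist()
                           if bundle.withheld["add_brain_true"] is not None else None),
        "test_visual_true": bundle.withheld["test_visual_true"].tolist(),
        "test_semantic_true": bundle.withheld["test_semantic_true"].tolist(),
    }
    gt_path = outdir / "ground_truth.json"
    gt_path.write_text(json.dumps(gt))
    paths["ground_truth"] = str(gt_path)
    (outdir / "benchmark.json").write_text(json.dumps(
        {"seed": seed, "config": gt["config"], "paths": paths}, indent=2))
    paths["benchmark"] = str(outdir / "benchmark.json")
    return paths
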