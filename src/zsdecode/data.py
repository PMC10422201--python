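"""Datasets, standardization and delimited-text I/O.

In memory every view is a dense ``features x samples`` matrix, matching the
orientation in which the model equations are written.  On disk matrices are
stored as CSV with one row per sample and a header of feature indices; the
loader transposes.  A small JSON manifest names the matrix files, their
orientation and the category labels, so a complete experiment (training
views, additional unpaired views, test brain activity, candidate vectors)
is a directory of plain-text files.

Standardization statistics are always fitted on the paired training block
and then applied to additional and test blocks, so no information flows
from test data into the preprocessing.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .exceptions import DataError

VIEWS = ("brain", "visual", "semantic")

__all__ = [
    "VIEWS",
    "StandardizationStats",
    "MultiViewDataset",
    "CandidateSet",
    "TestSet",
    "standardize_fit",
    "standardize_apply",
    "standardize_inverse",
    "load_dataset",
    "write_dataset",
    "write_results",
]


# ---------------------------------------------------------------------------
# standardization


@dataclass
class StandardizationStats:
    """Per-feature mean/SD of one view, with zero-variance features flagged."""

    mean: np.ndarray
    std: np.ndarray
    zero_variance: np.ndarray

    def __post_init__(self) -> None:
        self.mean = np.asarray(self.mean, dtype=float)
        self.std = np.asarray(self.std, dtype=float)
        self.zero_variance = np.asarray(self.zero_variance, dtype=bool)
        if not (self.mean.shape == self.std.shape == self.zero_variance.shape):
            raise DataError("standardization stats fields must share one shape")
        if np.any(self.std < 0):
            raise DataError("standard deviations must be non-negative")

    @property
    def n_features(self) -> int:
        return self.mean.shape[0]


def _check_matrix(x: np.ndarray, name: str) -> np.ndarray:
    x = np.asarray(x, dtype=float)
    if x.ndim != 2:
        raise DataError(f"{name} must be a 2-D matrix, got ndim={x.ndim}")
    if x.size == 0:
        raise DataError(f"{name} is empty")
    if not np.all(np.isfinite(x)):
        raise DataError(f"{name} contains non-finite entries")
    return x


def standardize_fit(matrix: np.ndarray) -> StandardizationStats:
    """Fit per-feature mean and SD across samples (columns).

    Features whose sample SD is exactly zero are flagged; ``standardize_apply``
    maps them to 0 instead of dividing by zero.
    """
    x = _check_matrix(matrix, "matrix")
    mean = x.mean(axis=1)
    std = x.std(axis=1)
    return StandardizationStats(mean=mean, std=std, zero_variance=std == 0.0)


def standardize_apply(matrix: np.ndarray, stats: StandardizationStats) -> np.ndarray:
    """z-score ``matrix`` (features x samples) with previously fitted stats."""
    x = _check_matrix(matrix, "matrix")
    if x.shape[0] != stats.n_features:
        raise DataError(
            f"feature dimension {x.shape[0]} does not match stats ({stats.n_features})"
        )
    safe_std = np.where(stats.zero_variance, 1.0, stats.std)
    z = (x - stats.mean[:, None]) / safe_std[:, None]
    z[stats.zero_variance, :] = 0.0
    return z


def standardize_inverse(matrix: np.ndarray, stats: StandardizationStats) -> np.ndarray:
    """Undo ``standardize_apply`` for unflagged features; flagged features
    are restored to their (constant) training mean."""
    x = _check_matrix(matrix, "matrix")
    if x.shape[0] != stats.n_features:
        raise DataError("feature dimension does not match stats")
    safe_std = np.where(stats.zero_variance, 0.0, stats.std)
    return x * safe_std[:, None] + stats.mean[:, None]


# ---------------------------------------------------------------------------
# dataset containers


@dataclass
class MultiViewDataset:
    """Paired three-view training block plus an optional unpaired block.

    ``brain``/``visual``/``semantic`` are ``D_k x N`` matrices observed for
    the same N samples.  ``add_visual``/``add_semantic`` are ``D_k x M``
    matrices for M additional samples whose brain activity was never
    recorded; during inference those brain columns are treated as missing
    values.  With ``zero_shot=True`` the additional (target) categories must
    be disjoint from the paired (source) categories.
    """

    brain: np.ndarray
    visual: np.ndarray
    semantic: np.ndarray
    add_visual: np.ndarray | None = None
    add_semantic: np.ndarray | None = None
    paired_labels: list[str] = field(default_factory=list)
    add_labels: list[str] = field(default_factory=list)
    zero_shot: bool = False

    def __post_init__(self) -> None:
        self.brain = _check_matrix(self.brain, "brain")
        self.visual = _check_matrix(self.visual, "visual")
        self.semantic = _check_matrix(self.semantic, "semantic")
        n = self.brain.shape[1]
        if self.visual.shape[1] != n or self.semantic.shape[1] != n:
            raise DataError(
                "paired views disagree on sample count: "
                f"brain {n}, visual {self.visual.shape[1]}, semantic {self.semantic.shape[1]}"
            )
        if (self.add_visual is None) != (self.add_semantic is None):
            raise DataError("additional visual and semantic blocks must come together")
        if self.add_visual is not None:
            self.add_visual = _check_matrix(self.add_visual, "add_visual")
            self.add_semantic = _check_matrix(self.add_semantic, "add_semantic")
            if self.add_visual.shape[0] != self.visual.shape[0]:
                raise DataError("add_visual feature dimension mismatch")
            if self.add_semantic.shape[0] != self.semantic.shape[0]:
                raise DataError("add_semantic feature dimension mismatch")
            if self.add_visual.shape[1] != self.add_semantic.shape[1]:
                raise DataError("additional blocks disagree on sample count")
        if self.paired_labels and len(self.paired_labels) != n:
            raise DataError("paired_labels length must equal N")
        if self.add_labels and len(self.add_labels) != self.n_additional:
            raise DataError("add_labels length must equal M")
        if self.zero_shot:
            shared = set(self.paired_labels) & set(self.add_labels)
            if shared:
                raise DataError(
                    f"zero-shot split shares categories between paired and "
                    f"additional blocks: {sorted(shared)}"
                )

    @property
    def n_paired(self) -> int:
        return self.brain.shape[1]

    @property
    def n_additional(self) -> int:
        return 0 if self.add_visual is None else self.add_visual.shape[1]

    @property
    def dims(self) -> dict[str, int]:
        return {
            "brain": self.brain.shape[0],
            "visual": self.visual.shape[0],
            "semantic": self.semantic.shape[0],
        }

    def view(self, name: str) -> np.ndarray:
        """Paired block of one view."""
        if name not in VIEWS:
            raise DataError(f"unknown view {name!r}")
        return getattr(self, name)

    def additional(self, name: str) -> np.ndarray | None:
        if name == "visual":
            return self.add_visual
        if name == "semantic":
            return self.add_semantic
        if name == "brain":
            return None  # missing by construction
        raise DataError(f"unknown view {name!r}")


@dataclass
class CandidateSet:
    """Per-category reference feature vectors used as decoding targets."""

    names: list[str]
    cand_visual: np.ndarray
    cand_semantic: np.ndarray

    def __post_init__(self) -> None:
        self.cand_visual = _check_matrix(self.cand_visual, "cand_visual")
        self.cand_semantic = _check_matrix(self.cand_semantic, "cand_semantic")
        c = len(self.names)
        if c < 2:
            raise DataError("a candidate set needs at least 2 categories")
        if len(set(self.names)) != c:
            raise DataError("candidate names must be unique")
        if self.cand_visual.shape[1] != c or self.cand_semantic.shape[1] != c:
            raise DataError("candidate matrices must have one column per name")

    @property
    def n_candidates(self) -> int:
        return len(self.names)

    def index_of(self, name: str) -> int:
        try:
            return self.names.index(name)
        except ValueError:
            raise DataError(f"category {name!r} not in candidate set") from None


@dataclass
class TestSet:
    """Held-out brain activity with ground-truth category labels."""

    __test__ = False  # not a pytest collection target

    brain_test: np.ndarray
    true_labels: list[str]

    def __post_init__(self) -> None:
        self.brain_test = _check_matrix(self.brain_test, "brain_test")
        if len(self.true_labels) != self.brain_test.shape[1]:
            raise DataError("true_labels length must equal the number of test samples")

    @property
    def n_test(self) -> int:
        return self.brain_test.shape[1]

    def check_against(self, candidates: CandidateSet) -> None:
        missing = [lb for lb in self.true_labels if lb not in candidates.names]
        if missing:
            raise DataError(f"test labels absent from candidate set: {sorted(set(missing))}")


# ---------------------------------------------------------------------------
# manifest I/O


def _write_matrix(x: np.ndarray, path: Path) -> None:
    # rows = samples, header = feature indices; full repr precision so the
    # roundtrip is bit-exact in decimal text
    df = pd.DataFrame(x.T, columns=[f"f{i}" for i in range(x.shape[0])])
    df.to_csv(path, index=False)


def _read_matrix(path: Path, orientation: str = "samples_by_features") -> np.ndarray:
    if not Path(path).exists():
        raise DataError(f"matrix file not found: {path}")
    df = pd.read_csv(path, float_precision="round_trip")
    x = df.to_numpy(dtype=float)
    if orientation == "samples_by_features":
        x = x.T
    elif orientation != "features_by_samples":
        raise DataError(f"unknown orientation {orientation!r}")
    if not np.all(np.isfinite(x)):
        raise DataError(f"matrix file {path} contains non-finite entries")
    return x


def write_dataset(obj: MultiViewDataset | TestSet | CandidateSet, directory: str | Path,
                  name: str = "manifest.json") -> Path:
    """Write a dataset object as CSV matrices plus a JSON manifest.

    Returns the manifest path, which ``load_dataset`` accepts.
    """
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    manifest: dict = {"orientation": "samples_by_features"}
    if isinstance(obj, MultiViewDataset):
        manifest["role"] = "multiview"
        manifest["zero_shot"] = obj.zero_shot
        mats = {"brain": obj.brain, "visual": obj.visual, "semantic": obj.semantic}
        if obj.n_additional:
            mats["add_visual"] = obj.add_visual
            mats["add_semantic"] = obj.add_semantic
        manifest["matrices"] = {}
        for key, mat in mats.items():
            fname = f"{key}.csv"
            _write_matrix(mat, directory / fname)
            manifest["matrices"][key] = fname
        manifest["labels"] = {"paired": obj.paired_labels, "add": obj.add_labels}
    elif isinstance(obj, TestSet):
        manifest["role"] = "test"
        _write_matrix(obj.brain_test, directory / "brain_test.csv")
        manifest["matrices"] = {"brain_test": "brain_test.csv"}
        manifest["labels"] = {"true": obj.true_labels}
    elif isinstance(obj, CandidateSet):
        manifest["role"] = "candidates"
        _write_matrix(obj.cand_visual, directory / "cand_visual.csv")
        _write_matrix(obj.cand_semantic, directory / "cand_semantic.csv")
        manifest["matrices"] = {"cand_visual": "cand_visual.csv",
                                "cand_semantic": "cand_semantic.csv"}
        manifest["labels"] = {"names": obj.names}
    else:
        raise DataError(f"cannot write object of type {type(obj).__name__}")
    path = directory / name
    path.write_text(json.dumps(manifest, indent=2))
    return path


def load_dataset(manifest_path: str | Path) -> MultiViewDataset | TestSet | CandidateSet:
    """Load and validate a dataset object from a JSON manifest."""
    manifest_path = Path(manifest_path)
    if not manifest_path.exists():
        raise DataError(f"manifest not found: {manifest_path}")
    manifest = json.loads(manifest_path.read_text())
    base = manifest_path.parent
    orientation = manifest.get("orientation", "samples_by_features")
    role = manifest.get("role")
    mats = {k: _read_matrix(base / v, orientation)
            for k, v in manifest.get("matrices", {}).items()}
    labels = manifest.get("labels", {})
    if role == "multiview":
        return MultiViewDataset(
            brain=mats["brain"], visual=mats["visual"], semantic=mats["semantic"],
            add_visual=mats.get("add_visual"), add_semantic=mats.get("add_semantic"),
            paired_labels=list(labels.get("paired", [])),
            add_labels=list(labels.get("add", [])),
            zero_shot=bool(manifest.get("zero_shot", False)),
        )
    if role == "test":
        return TestSet(brain_test=mats["brain_test"], true_labels=list(labels.get("true", [])))
    if role == "candidates":
        return CandidateSet(names=list(labels.get("names", [])),
                            cand_visual=mats["cand_visual"],
                            cand_semantic=mats["cand_semantic"])
    raise DataError(f"manifest role {role!r} not recognized")


def write_results(obj, path: str | Path, *, config: dict | None = None,
                  seed: int | None = None) -> Path:
    """Write predictions (matrix -> CSV) or a metrics record (dict -> JSON).

    Metrics JSON embeds the run configuration and seed so every printed
    number can be traced back to the run that produced it.
    """
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    if isinstance(obj, np.ndarray):
        x = np.asarray(obj, dtype=float)
        if not np.all(np.isfinite(x)):
            raise DataError("refusing to write non-finite prediction matrix")
        _write_matrix(x if x.ndim == 2 else x[:, None], path)
        return path
    if isinstance(obj, dict):
        payload = {"config": config or {}, "seed": seed, "results": obj}
        _assert_json_finite(payload)
        path.write_text(json.dumps(payload, indent=2, default=_json_default))
        return path
    raise DataError(f"cannot serialize object of type {type(obj).__name__}")


def _json_default(o):
    if isinstance(o, np.ndarray):
        return o.tolist()
    if isinstance(o, (np.integer,)):
        return int(o)
    if isinstance(o, (np.floating,)):
        return float(o)
    raise TypeError(f"not JSON serializable: {type(o).__name__}")


def _assert_json_finite(obj) -> None:
    if isinstance(obj, dict):
        for v in obj.values():
            _assert_json_finite(v)
    elif isinstance(obj, (list, tuple, np.ndarray)):
        for v in np.asarray(obj, dtype=object).ravel() if isinstance(obj, np.ndarray) else obj:
            _assert_json_finite(v)
    elif isinstance(obj, (float, np.floating)):
        if not np.isfinite(obj):
            raise DataError("refusing to write non-finite value in metrics record")
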