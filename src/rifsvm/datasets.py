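"""Synthetic imbalanced datasets, tabular loading, normalization, and stratified splits.

The two packaged synthetic presets emulate classic hard cases for
centroid-based fuzzy weighting:

* ``data1`` — three isotropic Gaussian clusters (a large majority cluster and
  two minority clusters of different sizes), producing a minority class with a
  small disjunct at 1:4 imbalance.
* ``data2`` — two concentric rings around the origin (minority inside), a
  manifold-structured geometry at 1:5 imbalance.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

__all__ = [
    "LabeledDataset",
    "ClusterSpec",
    "RingSpec",
    "SplitPlan",
    "generate_gaussian_clusters",
    "generate_ring_pair",
    "data1",
    "data2",
    "load_tabular",
    "load_manifest",
    "minmax_normalize",
    "minmax_params",
    "minmax_apply",
    "stratified_split",
    "stratified_kfold",
]


@dataclass(frozen=True)
class LabeledDataset:
    """A feature matrix with ±1 labels (+1 = minority/positive class)."""

    X: np.ndarray
    y: np.ndarray
    name: str = "dataset"

    def __post_init__(self) -> None:
        X = np.asarray(self.X, dtype=float)
        y = np.asarray(self.y, dtype=int)
        if X.ndim != 2:
            raise ValueError("features must be a 2-D matrix")
        if y.shape != (X.shape[0],):
            raise ValueError("labels must be a vector matching the number of rows")
        if not np.all(np.isfinite(X)):
            raise ValueError("all feature values must be finite")
        if not np.all(np.isin(y, (-1, 1))):
            raise ValueError("labels must take values in {+1, -1}")
        object.__setattr__(self, "X", X)
        object.__setattr__(self, "y", y)

    @property
    def n(self) -> int:
        return self.X.shape[0]

    @property
    def n_features(self) -> int:
        return self.X.shape[1]

    @property
    def n_pos(self) -> int:
        return int(np.sum(self.y == 1))

    @property
    def n_neg(self) -> int:
        return int(np.sum(self.y == -1))

    @property
    def imbalance_ratio(self) -> float:
        """Minority-to-majority count ratio IR = N+ / N-."""
        if self.n_neg == 0:
            raise ValueError("no majority instances")
        return self.n_pos / self.n_neg

    def subset(self, indices: np.ndarray, name: str | None = None) -> "LabeledDataset":
        indices = np.asarray(indices)
        return LabeledDataset(self.X[indices], self.y[indices], name or self.name)

    def require_trainable(self, min_per_class: int = 2) -> None:
        if self.n_pos < min_per_class or self.n_neg < min_per_class:
            raise ValueError(
                f"training requires at least {min_per_class} instances per class "
                f"(got N+={self.n_pos}, N-={self.n_neg})"
            )


@dataclass(frozen=True)
class ClusterSpec:
    """One isotropic Gaussian group: center, per-axis spread, count, label."""

    center: tuple[float, ...]
    spread: float
    count: int
    label: int

    def __post_init__(self) -> None:
        if self.count < 1:
            raise ValueError("cluster count must be >= 1")
        if self.spread <= 0:
            raise ValueError("cluster spread must be > 0")
        if self.label not in (-1, 1):
            raise ValueError("label must be +1 or -1")


@dataclass(frozen=True)
class RingSpec:
    """Two concentric annuli (one per class) sharing a 2-D center."""

    center: tuple[float, float] = (0.0, 0.0)
    width: float = 0.2
    inner_radius_pos: float = 0.3
    inner_radius_neg: float = 0.6
    count_pos: int = 100
    count_neg: int = 500

    def __post_init__(self) -> None:
        if self.width < 0 or not np.isfinite(self.width):
            raise ValueError("ring width must be finite and >= 0")
        if self.inner_radius_pos <= 0 or self.inner_radius_neg <= 0:
            raise ValueError("inner radii must be > 0")
        if self.count_pos < 1 or self.count_neg < 1:
            raise ValueError("counts must be >= 1")


@dataclass(frozen=True)
class SplitPlan:
    """A stratified partition of 0..n-1 into a train part and a test part."""

    train_indices: np.ndarray
    test_indices: np.ndarray
    seed: int

    def __post_init__(self) -> None:
        tr = np.asarray(self.train_indices)
        te = np.asarray(self.test_indices)
        if np.intersect1d(tr, te).size:
            raise ValueError("train and test indices overlap")
        object.__setattr__(self, "train_indices", tr)
        object.__setattr__(self, "test_indices", te)


def generate_gaussian_clusters(
    specs: list[ClusterSpec], seed: int, name: str = "gaussian-clusters"
) -> LabeledDataset:
    """Draw each group i.i.d. from an isotropic Gaussian at its center.

    Deterministic given ``seed``; groups are drawn in list order.
    """
    if not specs:
        raise ValueError("at least one cluster spec required")
    dims = {len(s.center) for s in specs}
    if len(dims) != 1:
        raise ValueError("all cluster centers must share a dimensionality")
    rng = np.random.default_rng(seed)
    blocks, labels = [], []
    for s in specs:
        blocks.append(rng.normal(loc=s.center, scale=s.spread, size=(s.count, len(s.center))))
        labels.append(np.full(s.count, s.label))
    return LabeledDataset(np.vstack(blocks), np.concatenate(labels), name)


DATA1_SPECS = (
    ClusterSpec(center=(0.4, 0.4), spread=0.1, count=800, label=-1),
    ClusterSpec(center=(0.15, 0.15), spread=0.1, count=50, label=+1),
    ClusterSpec(center=(0.7, 0.7), spread=0.1, count=150, label=+1),
)


def data1(seed: int) -> LabeledDataset:
    """Three-Gaussian preset: 800 negatives vs 50+150 positives (IR 1:4)."""
    return generate_gaussian_clusters(list(DATA1_SPECS), seed, name="data1")


def generate_ring_pair(spec: RingSpec, seed: int, name: str = "rings") -> LabeledDataset:
    """Sample each class uniformly in angle and uniformly in radius on its band."""
    rng = np.random.default_rng(seed)
    blocks, labels = [], []
    for label, inner, count in (
        (-1, spec.inner_radius_neg, spec.count_neg),
        (+1, spec.inner_radius_pos, spec.count_pos),
    ):
        theta = rng.uniform(0.0, 2.0 * np.pi, size=count)
        r = rng.uniform(inner, inner + spec.width, size=count)
        pts = np.column_stack([r * np.cos(theta), r * np.sin(theta)]) + np.asarray(spec.center)
        blocks.append(pts)
        labels.append(np.full(count, label))
    return LabeledDataset(np.vstack(blocks), np.concatenate(labels), name)


def data2(seed: int, count_pos: int = 100, count_neg: int = 500) -> LabeledDataset:
    """Concentric-rings preset: minority annulus [0.3, 0.5], majority [0.6, 0.8]."""
    spec = RingSpec(count_pos=count_pos, count_neg=count_neg)
    return generate_ring_pair(spec, seed, name="data2")


def load_tabular(
    path,
    label_column: str,
    positive_classes,
    negative_classes="rest",
    name: str | None = None,
) -> LabeledDataset:
    """Load a delimited text file and map raw class labels onto ±1.

    Rows whose label is in ``positive_classes`` become +1; rows in
    ``negative_classes`` (or, with ``"rest"``, all remaining rows) become −1;
    rows in neither set are dropped. The delimiter (comma or tab) is sniffed.
    """
    positive = {str(c) for c in positive_classes}
    if negative_classes == "rest":
        negative = None
    else:
        negative = {str(c) for c in negative_classes}
        if positive & negative:
            raise ValueError(
                f"positive and negative class sets overlap: {sorted(positive & negative)}"
            )
    df = pd.read_csv(path, sep=None, engine="python")
    if label_column not in df.columns:
        raise ValueError(f"label column {label_column!r} not found in {list(df.columns)}")
    raw = df[label_column].astype(str)
    y = np.where(raw.isin(positive), 1, -1)
    if negative is None:
        keep = np.ones(len(df), dtype=bool)
    else:
        keep = (raw.isin(positive) | raw.isin(negative)).to_numpy()
    features = df.drop(columns=[label_column]).loc[keep]
    try:
        X = features.astype(float).to_numpy()
    except (TypeError, ValueError) as exc:
        raise ValueError(f"non-numeric feature value: {exc}") from exc
    y = y[keep]
    if not np.any(y == 1):
        raise ValueError("positive class is empty after mapping")
    if not np.any(y == -1):
        raise ValueError("negative class is empty after mapping")
    return LabeledDataset(X, y, name or str(path))


def load_manifest(path) -> LabeledDataset:
    """Load a dataset described by a YAML/JSON manifest.

    Keys: ``path`` (CSV location, relative paths resolved against the
    manifest), ``label_column``, ``positive_classes`` (list), and optionally
    ``negative_classes`` (list, default ``"rest"``) and ``name``.
    """
    import json
    import pathlib

    import yaml

    manifest_path = pathlib.Path(path)
    text = manifest_path.read_text()
    spec = json.loads(text) if manifest_path.suffix == ".json" else yaml.safe_load(text)
    missing = {"path", "label_column", "positive_classes"} - set(spec)
    if missing:
        raise ValueError(f"manifest missing keys: {sorted(missing)}")
    csv_path = pathlib.Path(spec["path"])
    if not csv_path.is_absolute():
        csv_path = manifest_path.parent / csv_path
    return load_tabular(
        csv_path,
        spec["label_column"],
        spec["positive_classes"],
        spec.get("negative_classes", "rest"),
        name=spec.get("name"),
    )


def minmax_params(X: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Column-wise (min, range) with zero ranges replaced by 1 (constant -> 0)."""
    lo = X.min(axis=0)
    rng = X.max(axis=0) - lo
    rng = np.where(rng == 0, 1.0, rng)
    return lo, rng


def minmax_apply(X: np.ndarray, lo: np.ndarray, rng: np.ndarray) -> np.ndarray:
    return (X - lo) / rng


def minmax_normalize(dataset: LabeledDataset) -> LabeledDataset:
    """Affinely map every attribute onto [0, 1]; constant attributes map to 0."""
    lo, rng = minmax_params(dataset.X)
    return replace(dataset, X=minmax_apply(dataset.X, lo, rng))


def _per_class_shuffled(y: np.ndarray, rng: np.random.Generator) -> dict[int, np.ndarray]:
    out = {}
    for label in (1, -1):
        idx = np.flatnonzero(y == label)
        rng.shuffle(idx)
        out[label] = idx
    return out


def stratified_split(dataset: LabeledDataset, train_fraction: float, seed: int) -> SplitPlan:
    """Per-class random partition at ``train_fraction`` (rounded per class)."""
    if not 0.0 < train_fraction < 1.0:
        raise ValueError("train_fraction must lie strictly between 0 and 1")
    rng = np.random.default_rng(seed)
    train, test = [], []
    for label, idx in _per_class_shuffled(dataset.y, rng).items():
        n_train = int(round(train_fraction * idx.size))
        if n_train == 0 or n_train == idx.size:
            raise ValueError(
                f"class {label:+d} too small ({idx.size}) to appear in both parts "
                f"at fraction {train_fraction}"
            )
        train.append(idx[:n_train])
        test.append(idx[n_train:])
    return SplitPlan(np.sort(np.concatenate(train)), np.sort(np.concatenate(test)), seed)


def stratified_kfold(dataset: LabeledDataset, folds: int, seed: int) -> list[SplitPlan]:
    """Disjoint stratified folds by per-class round-robin after a seeded shuffle."""
    if folds < 2:
        raise ValueError("folds must be >= 2")
    if dataset.n_pos < folds or dataset.n_neg < folds:
        raise ValueError(
            f"each class must have at least {folds} instances "
            f"(got N+={dataset.n_pos}, N-={dataset.n_neg})"
        )
    rng = np.random.default_rng(seed)
    assignment = np.empty(dataset.n, dtype=int)
    for idx in _per_class_shuffled(dataset.y, rng).values():
        assignment[idx] = np.arange(idx.size) % folds
    plans = []
    for f in range(folds):
        test = np.flatnonzero(assignment == f)
        train = np.flatnonzero(assignment != f)
        plans.append(SplitPlan(train, test, seed))
    return plans
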