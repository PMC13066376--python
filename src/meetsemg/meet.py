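"""Mixture-of-experts Extra-Trees classifier (MEET) with Hadamard fusion.

The N gesture classes are split into consecutive ascending subsets of at
most ``a`` classes (default a=2).  One extremely-randomized-trees expert is
trained per subset on that subset's rows only; a gate of the same family is
trained on all rows.  For a sample, the experts' class-probability vectors
are stacked into a length-N vector Z aligned with the ascending class
order (each class is owned by exactly one expert), the gate emits its
length-N probability vector M, and the prediction is

    y = argmax( Z (Hadamard) M )

with ties broken toward the lowest class code.  The total classifier count
is ceil(N / a) + 1 (experts plus the gate).

Training of the experts is independent: each expert's random state is
derived from the master seed and its own class subset, so fitting an
expert is unaffected by the presence or absence of other classes' rows.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field
from pathlib import Path

import joblib
import numpy as np
from sklearn.ensemble import ExtraTreesClassifier

from .errors import ConfigurationError, InputError, SchemaError, TrainingError
from .features import FeatureMatrix

__all__ = [
    "DEFAULT_HYPERPARAMS",
    "ClassPartition",
    "MEETModel",
    "required_experts",
    "partition_classes",
    "fit",
    "fusion_vectors",
    "fuse_predict",
    "predict",
    "save_model",
    "load_model",
]

#: Extra-Trees settings shared by the experts and the gate.
DEFAULT_HYPERPARAMS = {
    "n_estimators": 100,
    "criterion": "gini",
    "min_samples_split": 2,
    "min_samples_leaf": 1,
    "max_features": "sqrt",
}


def required_experts(n_classes: int, a: int = 2) -> int:
    """Total classifier count: ceil(N/a) experts plus one gate."""
    if n_classes < 2 or a < 1:
        raise ConfigurationError(
            f"need n_classes >= 2 and a >= 1, got N={n_classes}, a={a}"
        )
    return math.ceil(n_classes / a) + 1


@dataclass(frozen=True)
class ClassPartition:
    """Disjoint, ascending class subsets, one per expert."""

    subsets: tuple[tuple[int, ...], ...]
    a: int
    class_order: tuple[int, ...]

    @property
    def n_experts(self) -> int:
        return len(self.subsets)

    def owner(self, cls: int) -> int:
        """Index of the expert owning a class code."""
        for i, subset in enumerate(self.subsets):
            if cls in subset:
                return i
        raise InputError(f"class {cls} not in partition")


def partition_classes(class_order, a: int = 2) -> ClassPartition:
    """Consecutive ascending chunks of size ``a`` (last possibly smaller)."""
    codes = [int(c) for c in class_order]
    if not codes:
        raise InputError("class_order is empty")
    if len(set(codes)) != len(codes):
        raise InputError(f"duplicate class codes in {codes}")
    if a < 1:
        raise ConfigurationError("a must be >= 1")
    codes = sorted(codes)
    subsets = tuple(tuple(codes[i : i + a]) for i in range(0, len(codes), a))
    return ClassPartition(subsets=subsets, a=a, class_order=tuple(codes))


def _seeded_tree_ensemble(hyperparams: dict, seed_words: list[int]) -> ExtraTreesClassifier:
    seed = int(np.random.SeedSequence(seed_words).generate_state(1)[0] % (2**31))
    return ExtraTreesClassifier(random_state=seed, n_jobs=1, **hyperparams)


@dataclass
class MEETModel:
    """Trained partitioned experts, gate, and fusion metadata."""

    experts: list[ExtraTreesClassifier] = field(repr=False)
    gate: ExtraTreesClassifier = field(repr=False)
    partition: ClassPartition
    feature_schema: list[str]
    train_seed: int
    hyperparams: dict
    #: "per_class" — normative length-N gate vector; "per_expert" — the gate's
    #: probability mass is pooled per expert before weighting its block of Z.
    fusion: str = "per_class"

    @property
    def class_order(self) -> tuple[int, ...]:
        return self.partition.class_order

    @property
    def n_classifiers(self) -> int:
        return len(self.experts) + 1

    def _check_schema(self, X: np.ndarray) -> np.ndarray:
        X = np.asarray(X, dtype=np.float64)
        if X.ndim == 1:
            X = X[None, :]
        if X.shape[1] != len(self.feature_schema):
            raise SchemaError(
                f"expected {len(self.feature_schema)} feature columns, got {X.shape[1]}"
            )
        return X

    def expert_probabilities(self, X: np.ndarray) -> np.ndarray:
        """Stacked expert output Z, shape (n_rows, N)."""
        X = self._check_schema(X)
        n_cls = len(self.class_order)
        pos = {c: i for i, c in enumerate(self.class_order)}
        z = np.zeros((X.shape[0], n_cls))
        for expert, subset in zip(self.experts, self.partition.subsets):
            probs = expert.predict_proba(X)
            for j, cls in enumerate(expert.classes_):
                z[:, pos[int(cls)]] = probs[:, j]
        return z

    def gate_probabilities(self, X: np.ndarray) -> np.ndarray:
        """Gate output M aligned to class_order, shape (n_rows, N)."""
        X = self._check_schema(X)
        n_cls = len(self.class_order)
        pos = {c: i for i, c in enumerate(self.class_order)}
        m = np.zeros((X.shape[0], n_cls))
        probs = self.gate.predict_proba(X)
        for j, cls in enumerate(self.gate.classes_):
            m[:, pos[int(cls)]] = probs[:, j]
        return m

    def fused_scores(self, X: np.ndarray) -> np.ndarray:
        z = self.expert_probabilities(X)
        m = self.gate_probabilities(X)
        if self.fusion == "per_expert":
            # pool the gate's mass over each expert's classes, then weight
            # that expert's whole block
            weights = np.zeros_like(m)
            pos = {c: i for i, c in enumerate(self.class_order)}
            for subset in self.partition.subsets:
                idx = [pos[c] for c in subset]
                weights[:, idx] = m[:, idx].sum(axis=1, keepdims=True)
            return z * weights
        return z * m


def fit(
    features: FeatureMatrix | np.ndarray,
    a: int = 2,
    hyperparams: dict | None = None,
    seed: int = 0,
    labels: np.ndarray | None = None,
    fusion: str = "per_class",
) -> MEETModel:
    """Train the partitioned experts and the gate.

    Accepts a :class:`FeatureMatrix` (labels and schema carried along) or a
    plain array plus ``labels``.  Every class present must have at least two
    rows.  The expert for subset i sees only rows whose label lies in
    subset i; the gate sees all rows.
    """
    if fusion not in ("per_class", "per_expert"):
        raise ConfigurationError(f"unknown fusion mode {fusion!r}")
    if isinstance(features, FeatureMatrix):
        X = features.values
        y = features.labels
        schema = list(features.feature_names)
    else:
        if labels is None:
            raise InputError("labels required when features is a plain array")
        X = np.asarray(features, dtype=np.float64)
        y = np.asarray(labels, dtype=np.int64)
        schema = [f"f{i}" for i in range(X.shape[1])]
    classes, counts = np.unique(y, return_counts=True)
    if len(classes) < 2:
        raise TrainingError("need at least two classes to train")
    thin = classes[counts < 2]
    if thin.size:
        raise TrainingError(f"class {int(thin[0])} has fewer than 2 training rows")

    hp = dict(DEFAULT_HYPERPARAMS, **(hyperparams or {}))
    part = partition_classes(classes, a)
    experts = []
    for subset in part.subsets:
        mask = np.isin(y, subset)
        clf = _seeded_tree_ensemble(hp, [seed, 1, *subset])
        clf.fit(X[mask], y[mask])
        experts.append(clf)
    gate = _seeded_tree_ensemble(hp, [seed, 2])
    gate.fit(X, y)
    return MEETModel(
        experts=experts,
        gate=gate,
        partition=part,
        feature_schema=schema,
        train_seed=seed,
        hyperparams=hp,
        fusion=fusion,
    )


@dataclass(frozen=True)
class FusionVectors:
    """Stacked expert vector Z and gate vector M for one sample."""

    Z: np.ndarray
    M: np.ndarray


def fusion_vectors(model: MEETModel, row: np.ndarray) -> FusionVectors:
    """Z and M for a single feature row."""
    row = np.asarray(row, dtype=np.float64)
    if row.ndim != 1:
        raise InputError("row must be a single 1-D feature vector")
    return FusionVectors(
        Z=model.expert_probabilities(row)[0], M=model.gate_probabilities(row)[0]
    )


def fuse_predict(Z, M, class_order) -> int:
    """argmax of the elementwise product Z * M, lowest class code on ties."""
    z = np.asarray(Z, dtype=np.float64)
    m = np.asarray(M, dtype=np.float64)
    order = [int(c) for c in class_order]
    if z.shape != m.shape or z.ndim != 1 or z.size != len(order):
        raise InputError(
            f"Z, M and class_order lengths must agree, got {z.shape}, {m.shape}, {len(order)}"
        )
    for name, v in (("Z", z), ("M", m)):
        if np.any(v < 0) or np.any(v > 1):
            raise InputError(f"{name} entries must lie in [0, 1]")
    # class_order is ascending and argmax returns the first maximum
    return order[int(np.argmax(z * m))]


def predict(model: MEETModel, features: FeatureMatrix | np.ndarray) -> np.ndarray:
    """Fused prediction for every row; empty input gives an empty output."""
    X = features.values if isinstance(features, FeatureMatrix) else np.asarray(features)
    if X.size == 0:
        return np.array([], dtype=np.int64)
    scores = model.fused_scores(X)
    order = np.asarray(model.class_order)
    return order[np.argmax(scores, axis=1)].astype(np.int64)


def save_model(model: MEETModel, path: str | Path) -> None:
    """Persist a model bundle plus a JSON metadata sidecar."""
    path = Path(path)
    joblib.dump(model, path)
    sidecar = {
        "partition": [list(s) for s in model.partition.subsets],
        "class_order": list(model.class_order),
        "a": model.partition.a,
        "feature_schema": model.feature_schema,
        "train_seed": model.train_seed,
        "hyperparams": model.hyperparams,
        "fusion": model.fusion,
    }
    path.with_suffix(path.suffix + ".json").write_text(json.dumps(sidecar, indent=2))


def load_model(path: str | Path) -> MEETModel:
    return joblib.load(Path(path))
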