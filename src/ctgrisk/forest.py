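"""Per-tree class-balanced random forest with out-of-bag epoch probabilities.

The classification target is healthy vs pathological (acidosis or HIE)
at the *epoch* level. Class imbalance is severe (HIE-group epochs are <1%
of the cohort), so each tree is fit on its own balanced bootstrap: sample
with replacement m epochs from each class, where m is the minority class
size. The forest's score for an epoch, pHIE, is the fraction of trees
voting pathological; on the training set, the out-of-bag (OOB) variant uses
only the trees whose bootstrap excluded that epoch, giving an unbiased
internal validation signal used downstream for policy selection.

Tree induction itself is standard CART (scikit-learn
``DecisionTreeClassifier``); the balanced bootstrap, in-bag bookkeeping and
OOB aggregation live here.
"""

from __future__ import annotations

import hashlib
from dataclasses import dataclass, field

import joblib
import numpy as np
import pandas as pd
from sklearn.tree import DecisionTreeClassifier

from .features import FEATURE_NAMES

HEALTHY, PATHOLOGICAL = 0, 1

#: forest size of the full-scale configuration
DEFAULT_N_TREES = 2500


@dataclass
class ForestConfig:
    """Forest hyperparameters.

    ``max_features=3`` is floor(sqrt(11)) — the standard forest default for
    the 11-feature epoch vector. Depth is unlimited by default.
    """

    n_trees: int = DEFAULT_N_TREES
    max_features: int = 3
    max_depth: int | None = None
    min_samples_leaf: int = 1


def balanced_bootstrap(labels: np.ndarray, rng: np.random.Generator) -> np.ndarray:
    """In-bag index multiset: m draws with replacement per class, m = minority size."""
    labels = np.asarray(labels)
    idx0 = np.flatnonzero(labels == HEALTHY)
    idx1 = np.flatnonzero(labels == PATHOLOGICAL)
    if len(idx0) == 0 or len(idx1) == 0:
        raise ValueError("balanced bootstrap needs both classes present")
    m = min(len(idx0), len(idx1))
    return np.concatenate([rng.choice(idx0, m, replace=True), rng.choice(idx1, m, replace=True)])


def _table_to_matrix(feature_table: pd.DataFrame | np.ndarray) -> np.ndarray:
    if isinstance(feature_table, pd.DataFrame):
        missing = set(FEATURE_NAMES) - set(feature_table.columns)
        if missing:
            raise ValueError(f"feature table missing feature columns: {sorted(missing)}")
        X = feature_table.loc[:, list(FEATURE_NAMES)].to_numpy(dtype=float)
    else:
        X = np.asarray(feature_table, dtype=float)
    if X.ndim != 2 or X.shape[1] != len(FEATURE_NAMES):
        raise ValueError(f"expected {len(FEATURE_NAMES)} features, got shape {X.shape}")
    return X


def _matrix_digest(X: np.ndarray, y: np.ndarray) -> str:
    h = hashlib.sha1()
    h.update(np.ascontiguousarray(X).tobytes())
    h.update(np.ascontiguousarray(y).tobytes())
    return h.hexdigest()


@dataclass
class RiskModel:
    """A trained balanced forest plus its in-bag bookkeeping."""

    trees: list[DecisionTreeClassifier]
    inbag: list[np.ndarray]  # per-tree in-bag row indices into the training table
    config: ForestConfig
    seed: int | None
    n_train: int
    train_digest: str
    feature_names: tuple[str, ...] = tuple(FEATURE_NAMES)

    @property
    def n_trees(self) -> int:
        return len(self.trees)

    def save(self, path) -> None:
        joblib.dump(self, path)

    @staticmethod
    def load(path) -> "RiskModel":
        model = joblib.load(path)
        if not isinstance(model, RiskModel):
            raise TypeError(f"{path} does not contain a RiskModel")
        return model


def train_forest(
    feature_table: pd.DataFrame | np.ndarray,
    labels: np.ndarray,
    config: ForestConfig | None = None,
    rng: np.random.Generator | int | None = None,
) -> RiskModel:
    """Fit the balanced forest on valid epochs only.

    ``labels`` is binary (1 = pathological). Rows must be complete — the
    featurizer marks invalid epochs with NaN features, and those must be
    excluded before training.
    """
    config = config or ForestConfig()
    X = _table_to_matrix(feature_table)
    y = np.asarray(labels, dtype=int)
    if len(y) != len(X):
        raise ValueError("labels and feature table lengths differ")
    if np.isnan(X).any():
        raise ValueError("feature table contains NaN rows; drop invalid epochs first")
    for cls in (HEALTHY, PATHOLOGICAL):
        if (y == cls).sum() < 2:
            raise ValueError("need at least 2 epochs per class to train")
    seed = rng if isinstance(rng, (int, np.integer)) else None
    gen = np.random.default_rng(rng)
    trees: list[DecisionTreeClassifier] = []
    inbag: list[np.ndarray] = []
    for _ in range(config.n_trees):
        idx = balanced_bootstrap(y, gen)
        tree = DecisionTreeClassifier(
            max_features=config.max_features,
            max_depth=config.max_depth,
            min_samples_leaf=config.min_samples_leaf,
            random_state=int(gen.integers(2**31 - 1)),
        )
        tree.fit(X[idx], y[idx])
        trees.append(tree)
        inbag.append(idx)
    return RiskModel(
        trees=trees,
        inbag=inbag,
        config=config,
        seed=seed if seed is None else int(seed),
        n_train=len(X),
        train_digest=_matrix_digest(X, y),
    )


def _tree_votes(tree: DecisionTreeClassifier, X: np.ndarray) -> np.ndarray:
    """Per-row pathological vote (0/1) of one tree."""
    pred = tree.predict(X)
    return (pred == PATHOLOGICAL).astype(np.int32)


def oob_probabilities(
    model: RiskModel, feature_table: pd.DataFrame | np.ndarray, labels: np.ndarray
) -> np.ndarray:
    """Out-of-bag pHIE per training epoch; NaN where every tree bagged it.

    ``feature_table``/``labels`` must be exactly the table the model was
    trained on (checked by digest); the OOB probability of epoch i is the
    fraction of pathological votes among trees whose bootstrap excluded i.
    """
    X = _table_to_matrix(feature_table)
    y = np.asarray(labels, dtype=int)
    if len(X) != model.n_train or _matrix_digest(X, y) != model.train_digest:
        raise ValueError("feature table does not match the model's training table")
    votes = np.zeros(len(X))
    counts = np.zeros(len(X))
    for tree, idx in zip(model.trees, model.inbag):
        oob_mask = np.ones(len(X), dtype=bool)
        oob_mask[idx] = False
        if not oob_mask.any():
            continue
        votes[oob_mask] += _tree_votes(tree, X[oob_mask])
        counts[oob_mask] += 1
    with np.errstate(invalid="ignore"):
        phie = votes / counts
    phie[counts == 0] = np.nan
    return phie


def predict_p(model: RiskModel, feature_rows: pd.DataFrame | np.ndarray) -> np.ndarray:
    """pHIE for new epochs: fraction of all trees voting pathological.

    Rows flagged invalid (NaN features) are refused — callers must keep
    them on the epoch grid as missing instead of scoring them.
    """
    X = _table_to_matrix(feature_rows)
    if np.isnan(X).any():
        raise ValueError("cannot score invalid (NaN-feature) epochs")
    votes = np.zeros(len(X))
    for tree in model.trees:
        votes += _tree_votes(tree, X)
    return votes / model.n_trees
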