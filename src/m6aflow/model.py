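"""Balanced CNN ensemble for scoring candidate single-base m6A sites.

miCLIP-derived training sets are heavily imbalanced (far more clean DRACH
negatives than validated positives).  The classifier therefore partitions
the negatives into ``n_members`` near-equal subsets and trains one CNN per
subset, each on (all positives, one negative subset); the reported site
probability is the arithmetic mean of the member probabilities.

``DeepM6AClassifier`` follows the scikit-learn estimator protocol (``fit`` /
``predict_proba`` / ``get_params``) so it composes with sklearn model
selection; inputs are the (n, 4, 101) encoded windows from
:mod:`m6aflow.encoding` (flattened (n, 404) is accepted too).
"""

from __future__ import annotations

import json
from dataclasses import asdict
from pathlib import Path
from typing import Sequence

import numpy as np
from sklearn.base import BaseEstimator, ClassifierMixin
from sklearn.metrics import average_precision_score, roc_auc_score
from sklearn.model_selection import StratifiedKFold
from sklearn.utils.validation import check_is_fitted

from .nn import CNNHyperparams, ConvNet

#: site-call threshold: the probability at which the published 10-fold CV
#: reaches a precision of 0.7
DEFAULT_THRESHOLD = 0.907


def split_negatives(
    n_negatives: int, k: int = 7, rng: np.random.Generator | int | None = None
) -> list[np.ndarray]:
    """Seeded random partition of negative indices into ``k`` near-equal subsets.

    Subset sizes differ by at most one.  Returns index arrays into the
    negative pool.
    """
    if k <= 0:
        raise ValueError(f"number of subsets must be positive, got {k}")
    if n_negatives < k:
        raise ValueError(f"cannot split {n_negatives} negatives into {k} subsets")
    rng = np.random.default_rng(rng) if not isinstance(rng, np.random.Generator) else rng
    perm = rng.permutation(n_negatives)
    return [np.sort(part) for part in np.array_split(perm, k)]


class DeepM6AClassifier(ClassifierMixin, BaseEstimator):
    """Balanced ensemble of small CNNs over encoded 101-nt windows.

    Parameters
    ----------
    hyperparams
        CNN architecture; defaults to the published optimum
        (kernel 4x5, 32 filters, pool 1x4, dropout 0.25/0.25, 12 dense nodes).
    n_members
        Number of ensemble members = negative subsets (published value 7).
    epochs, batch_size
        Training schedule for every member.
    random_state
        Seeds weight init, the negative split, batching and dropout.

    Attributes
    ----------
    members_ : list[ConvNet]
        The trained networks.
    classes_ : ndarray
        Always ``[0, 1]``.
    """

    def __init__(
        self,
        hyperparams: CNNHyperparams | None = None,
        n_members: int = 7,
        epochs: int = 50,
        batch_size: int = 64,
        random_state: int | None = None,
    ):
        self.hyperparams = hyperparams
        self.n_members = n_members
        self.epochs = epochs
        self.batch_size = batch_size
        self.random_state = random_state

    # -- helpers ---------------------------------------------------------

    @staticmethod
    def _as_matrix(x: np.ndarray) -> np.ndarray:
        x = np.asarray(x, dtype=np.float64)
        if x.ndim == 2:  # flattened (n, 4*L)
            if x.shape[1] % 4:
                raise ValueError(f"flattened input width {x.shape[1]} not 4*L")
            x = x.reshape(x.shape[0], 4, x.shape[1] // 4)
        if x.ndim != 3 or x.shape[1] != 4:
            raise ValueError(f"expected (n, 4, L) encoded windows, got {x.shape}")
        return x

    # -- estimator API ---------------------------------------------------

    def fit(self, X: np.ndarray, y: Sequence[int]) -> "DeepM6AClassifier":
        X = self._as_matrix(X)
        y = np.asarray(y, dtype=int)
        if X.shape[0] != y.shape[0]:
            raise ValueError("X and y length mismatch")
        if not set(np.unique(y)) <= {0, 1}:
            raise ValueError("labels must be binary 0/1")
        pos_idx = np.flatnonzero(y == 1)
        neg_idx = np.flatnonzero(y == 0)
        if len(pos_idx) == 0 or len(neg_idx) == 0:
            raise ValueError("both classes must be present in training data")

        hp = self.hyperparams or CNNHyperparams()
        seed_seq = np.random.SeedSequence(self.random_state)
        split_rng = np.random.default_rng(seed_seq.spawn(1)[0])
        k = min(self.n_members, len(neg_idx))
        subsets = split_negatives(len(neg_idx), k, split_rng)

        self.members_ = []
        self.history_ = []
        member_seeds = seed_seq.spawn(k)
        for subset, member_seed in zip(subsets, member_seeds):
            rng = np.random.default_rng(member_seed)
            net = ConvNet(hp, input_len=X.shape[2], rng=rng)
            idx = np.concatenate([pos_idx, neg_idx[subset]])
            if self.epochs > 0:
                self.history_.append(
                    net.fit(X[idx], y[idx], epochs=self.epochs,
                            batch_size=self.batch_size, rng=rng)
                )
            else:
                self.history_.append([])
            self.members_.append(net)
        self.classes_ = np.array([0, 1])
        self.n_features_in_ = X.shape[1] * X.shape[2]
        return self

    def predict_proba(self, X: np.ndarray) -> np.ndarray:
        """Mean of the member class probabilities, shape (n, 2)."""
        check_is_fitted(self, "members_")
        X = self._as_matrix(X)
        probs = np.mean([m.predict_proba(X) for m in self.members_], axis=0)
        return probs

    def predict(self, X: np.ndarray) -> np.ndarray:
        return (self.predict_proba(X)[:, 1] >= 0.5).astype(int)

    def decision_function(self, X: np.ndarray) -> np.ndarray:
        return self.predict_proba(X)[:, 1]

    # -- persistence -----------------------------------------------------

    def save(self, directory: str | Path) -> None:
        """Write member weights and metadata into ``directory``."""
        check_is_fitted(self, "members_")
        directory = Path(directory)
        directory.mkdir(parents=True, exist_ok=True)
        hp = self.hyperparams or CNNHyperparams()
        meta = {
            "hyperparams": asdict(hp),
            "n_members": len(self.members_),
            "epochs": self.epochs,
            "batch_size": self.batch_size,
            "random_state": self.random_state,
            "input_len": self.members_[0].input_len,
        }
        (directory / "ensemble.json").write_text(json.dumps(meta, indent=2))
        for i, member in enumerate(self.members_):
            np.savez(directory / f"member_{i:02d}.npz", **member.get_weights())

    @classmethod
    def load(cls, directory: str | Path) -> "DeepM6AClassifier":
        directory = Path(directory)
        meta = json.loads((directory / "ensemble.json").read_text())
        hp_kwargs = meta["hyperparams"]
        hp_kwargs["kernel_size"] = tuple(hp_kwargs["kernel_size"])
        hp_kwargs["pool_size"] = tuple(hp_kwargs["pool_size"])
        hp = CNNHyperparams(**hp_kwargs)
        est = cls(
            hyperparams=hp,
            n_members=meta["n_members"],
            epochs=meta["epochs"],
            batch_size=meta["batch_size"],
            random_state=meta["random_state"],
        )
        est.members_ = []
        for i in range(meta["n_members"]):
            net = ConvNet(hp, input_len=meta["input_len"],
                          rng=np.random.default_rng(0))
            with np.load(directory / f"member_{i:02d}.npz") as data:
                net.set_weights({k: data[k] for k in data.files})
            est.members_.append(net)
        est.classes_ = np.array([0, 1])
        est.n_features_in_ = 4 * meta["input_len"]
        return est


def call_sites(
    probabilities: dict | Sequence[tuple],
    threshold: float = DEFAULT_THRESHOLD,
) -> set:
    """Sites whose ensemble probability strictly exceeds ``threshold``.

    ``probabilities`` maps site keys to probabilities (or is an iterable of
    (site, probability) pairs).  The comparison is strict: a probability
    exactly at the threshold is not called.
    """
    if not 0 < threshold < 1:
        raise ValueError(f"threshold must be in (0, 1), got {threshold}")
    items = probabilities.items() if hasattr(probabilities, "items") else probabilities
    return {site for site, p in items if p > threshold}


def grid_search_hyperparams(
    X: np.ndarray,
    y: Sequence[int],
    grid: dict[str, Sequence] | None = None,
    validation_fraction: float = 0.25,
    n_members: int = 1,
    epochs: int = 10,
    batch_size: int = 64,
    random_state: int | None = None,
) -> tuple[CNNHyperparams, list[dict]]:
    """Optional architecture search over a hyperparameter grid.

    Each combination is scored by AUC on a single stratified validation
    split (the search uses one fold, not the full CV).  Returns the best
    hyperparameters and the per-combination scores.  With no ``grid`` the
    published defaults are returned untouched.
    """
    if not grid:
        return CNNHyperparams(), []
    from itertools import product

    from sklearn.model_selection import train_test_split

    X = DeepM6AClassifier._as_matrix(X)
    y = np.asarray(y, dtype=int)
    train_idx, val_idx = train_test_split(
        np.arange(len(y)), test_size=validation_fraction, stratify=y,
        random_state=random_state,
    )
    keys = sorted(grid)
    results = []
    for values in product(*(grid[k] for k in keys)):
        hp = CNNHyperparams(**dict(zip(keys, values)))
        est = DeepM6AClassifier(
            hyperparams=hp, n_members=n_members, epochs=epochs,
            batch_size=batch_size, random_state=random_state,
        )
        est.fit(X[train_idx], y[train_idx])
        score = roc_auc_score(
            y[val_idx], est.predict_proba(X[val_idx])[:, 1]
        )
        results.append({"hyperparams": hp, "auc": float(score)})
    best = max(results, key=lambda r: r["auc"])
    return best["hyperparams"], results


def cross_validate(
    X: np.ndarray,
    y: Sequence[int],
    folds: int = 10,
    hyperparams: CNNHyperparams | None = None,
    n_members: int = 7,
    epochs: int = 50,
    batch_size: int = 64,
    random_state: int | None = None,
) -> dict:
    """Stratified k-fold CV of the balanced ensemble.

    Every sample is scored exactly once out-of-fold; per-fold AUC/PRAUC and
    the pooled out-of-fold ROC/PR AUCs are returned, plus the pooled scores
    themselves for curve plotting.
    """
    if folds < 2:
        raise ValueError("need at least 2 folds")
    X = DeepM6AClassifier._as_matrix(X)
    y = np.asarray(y, dtype=int)
    skf = StratifiedKFold(n_splits=folds, shuffle=True, random_state=random_state)
    oof = np.full(len(y), np.nan)
    fold_auc, fold_prauc = [], []
    for fold, (train_idx, test_idx) in enumerate(skf.split(X, y)):
        if y[train_idx].sum() == 0 or y[test_idx].sum() == 0:
            raise ValueError(f"fold {fold} lacks positive samples")
        est = DeepM6AClassifier(
            hyperparams=hyperparams, n_members=n_members, epochs=epochs,
            batch_size=batch_size,
            random_state=None if random_state is None else random_state + fold,
        )
        est.fit(X[train_idx], y[train_idx])
        scores = est.predict_proba(X[test_idx])[:, 1]
        oof[test_idx] = scores
        fold_auc.append(roc_auc_score(y[test_idx], scores))
        fold_prauc.append(average_precision_score(y[test_idx], scores))
    return {
        "fold_auc": fold_auc,
        "fold_prauc": fold_prauc,
        "pooled_auc": float(roc_auc_score(y, oof)),
        "pooled_prauc": float(average_precision_score(y, oof)),
        "oof_scores": oof,
        "labels": y,
    }
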