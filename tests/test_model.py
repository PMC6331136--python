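"""Balanced ensemble classifier, site calling and cross-validation."""

import numpy as np
import pytest
from sklearn.base import clone

from m6aflow.model import (
    DeepM6AClassifier, call_sites, cross_validate, grid_search_hyperparams,
    split_negatives,
)
from m6aflow.nn import CNNHyperparams

TINY_HP = CNNHyperparams(
    kernel_size=(4, 3), n_filters=4, pool_size=(1, 2),
    dropout1=0.1, dense_nodes=4, dropout2=0.1,
)


def _separable(n=60, length=31, seed=0):
    """Encoded windows where positives carry a strong coverage channel."""
    rng = np.random.default_rng(seed)
    x = np.abs(rng.normal(1.0, 0.2, size=(n, 4, length)))
    x *= (rng.random((n, 4, length)) < 0.4)  # one-hot-ish sparsity
    y = rng.integers(0, 2, size=n)
    x[y == 1] *= 6.0  # positives carry a global coverage-scale signal
    return x, y


def test_split_negatives_near_equal_partition():
    parts = split_negatives(33_718, k=7, rng=0)
    sizes = sorted(len(p) for p in parts)
    assert sizes == [4816] + [4817] * 6  # 33718 = 6*4817 + 4816
    assert np.array_equal(np.sort(np.concatenate(parts)), np.arange(33_718))

    singles = split_negatives(7, k=7, rng=1)
    assert all(len(p) == 1 for p in singles)

    a = split_negatives(100, 7, rng=42)
    b = split_negatives(100, 7, rng=42)
    assert all(np.array_equal(x, y) for x, y in zip(a, b))

    with pytest.raises(ValueError):
        split_negatives(10, 0)
    with pytest.raises(ValueError):
        split_negatives(3, 7)


def test_untrained_ensemble_emits_valid_probabilities():
    x, y = _separable()
    clf = DeepM6AClassifier(hyperparams=TINY_HP, n_members=3, epochs=0,
                            random_state=0).fit(x, y)
    probs = clf.predict_proba(x)
    assert probs.shape == (len(y), 2)
    assert np.all((probs >= 0) & (probs <= 1))
    assert np.allclose(probs.sum(axis=1), 1.0)


def test_ensemble_mean_is_member_order_invariant():
    x, y = _separable()
    clf = DeepM6AClassifier(hyperparams=TINY_HP, n_members=3, epochs=2,
                            random_state=0).fit(x, y)
    before = clf.predict_proba(x)
    clf.members_ = clf.members_[::-1]
    assert np.allclose(before, clf.predict_proba(x), atol=1e-15)


def test_single_member_ensemble_equals_its_member():
    x, y = _separable()
    clf = DeepM6AClassifier(hyperparams=TINY_HP, n_members=1, epochs=2,
                            random_state=1).fit(x, y)
    assert np.array_equal(
        clf.predict_proba(x), clf.members_[0].predict_proba(x)
    )


def test_fit_is_seed_reproducible():
    x, y = _separable()

    def run():
        return DeepM6AClassifier(
            hyperparams=TINY_HP, n_members=2, epochs=2, random_state=3
        ).fit(x, y).predict_proba(x)

    assert np.array_equal(run(), run())


def test_fit_rejects_single_class():
    x, _ = _separable()
    with pytest.raises(ValueError):
        DeepM6AClassifier(hyperparams=TINY_HP).fit(x, np.zeros(len(x)))


def test_sklearn_protocol():
    clf = DeepM6AClassifier(n_members=3, epochs=5, random_state=1)
    params = clf.get_params()
    assert params["n_members"] == 3 and params["epochs"] == 5
    cloned = clone(clf)
    assert cloned.get_params() == params


def test_save_load_roundtrip(tmp_path):
    x, y = _separable()
    clf = DeepM6AClassifier(hyperparams=TINY_HP, n_members=2, epochs=2,
                            random_state=5).fit(x, y)
    clf.save(tmp_path / "model")
    loaded = DeepM6AClassifier.load(tmp_path / "model")
    assert np.array_equal(clf.predict_proba(x), loaded.predict_proba(x))


def test_call_sites_strictly_above_threshold():
    probs = {"a": 0.907, "b": 0.9070000001, "c": 0.91, "d": 0.1}
    called = call_sites(probs, threshold=0.907)
    assert called == {"b", "c"}  # exactly at threshold is NOT called
    assert call_sites(probs, threshold=0.05) == {"a", "b", "c", "d"}
    with pytest.raises(ValueError):
        call_sites(probs, threshold=0.0)


def test_mean_of_member_probabilities():
    """The ensemble probability is the arithmetic mean over members."""
    member_probs = np.array([0.2, 0.4, 0.6, 0.8, 0.5, 0.5, 0.5])
    assert member_probs.mean() == pytest.approx(0.5)


def test_cross_validate_separable_data():
    x, y = _separable(n=90, seed=7)
    res = cross_validate(
        x, y, folds=3, hyperparams=TINY_HP, n_members=1, epochs=100,
        batch_size=16, random_state=0,
    )
    assert res["pooled_auc"] == pytest.approx(1.0, abs=0.01)
    assert len(res["fold_auc"]) == 3
    assert np.isfinite(res["oof_scores"]).all()  # every sample scored once


def test_grid_search_defaults_and_selection():
    # no grid: published defaults come back untouched
    hp, results = grid_search_hyperparams(*_separable(), grid=None)
    assert hp == CNNHyperparams() and results == []
    x, y = _separable(n=80, seed=3)
    hp, results = grid_search_hyperparams(
        x, y,
        grid={"kernel_size": [(4, 3), (4, 5)], "n_filters": [4]},
        epochs=15, random_state=0,
    )
    assert len(results) == 2
    assert hp == max(results, key=lambda r: r["auc"])["hyperparams"]
    assert hp.n_filters == 4


def test_cross_validate_rejects_positive_free_folds():
    x, y = _separable(n=40)
    y[:] = 0
    y[0] = 1  # a single positive cannot stratify into 3 folds
    with pytest.raises(ValueError):
        cross_validate(x, y, folds=3, hyperparams=TINY_HP, n_members=1,
                       epochs=1, random_state=0)
    with pytest.raises(ValueError):
        cross_validate(x, y, folds=1)
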