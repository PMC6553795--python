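import numpy as np
import pandas as pd
import pytest

from giddi import (
    HyperparamSpace,
    TrialRecord,
    assemble_pairs,
    train_classifier,
    tune_hyperparameters,
)
from giddi.model import Dimension, holdout_loss, _tpe_propose
from giddi.pairs import SplitPlan, holdout_splits


def toy_problem(n_drugs=24, seed=0):
    """Pairs with a single informative feature separating the classes."""
    rng = np.random.default_rng(seed)
    drugs = [f"D{i:02d}" for i in range(n_drugs)]
    positives = []
    rows = {}
    for i, a in enumerate(drugs):
        for b in drugs[i + 1 :]:
            y = int(rng.random() < 0.25)
            if y:
                positives.append((a, b))
            x0 = y + rng.normal(0, 0.4)
            rows[(a, b)] = [x0, rng.normal(), rng.normal()]
    pair_set = assemble_pairs(positives, drugs)
    idx = pd.MultiIndex.from_tuples(rows.keys(), names=["drug_a", "drug_b"])
    features = pd.DataFrame(list(rows.values()), index=idx, columns=["f0", "f1", "f2"])
    return pair_set, features


class TestDimension:
    def test_uniform_and_integer_sampling_within_bounds(self):
        rng = np.random.default_rng(0)
        d = Dimension("depth", 2, 8, integer=True)
        draws = {d.sample(rng) for _ in range(200)}
        assert draws <= set(range(2, 9))
        assert len(draws) > 3

    def test_loguniform_favors_small_values(self):
        rng = np.random.default_rng(1)
        d = Dimension("lr", 0.01, 1.0, log=True)
        draws = np.array([d.sample(rng) for _ in range(2000)])
        assert np.all((draws >= 0.01) & (draws <= 1.0))
        # log-uniform: median at the geometric midpoint, not the arithmetic
        assert abs(np.median(draws) - 0.1) < 0.02

    def test_invalid_bounds_rejected(self):
        with pytest.raises(ValueError):
            Dimension("x", 1.0, 1.0)
        with pytest.raises(ValueError):
            Dimension("x", -1.0, 1.0, log=True)

    def test_default_space_covers_standard_knobs(self):
        space = HyperparamSpace.default()
        names = {d.name for d in space.dimensions}
        assert {"learning_rate", "max_depth", "n_estimators", "subsample"} <= names
        rng = np.random.default_rng(2)
        params = space.sample(rng)
        assert space.contains(params)
        assert isinstance(params["max_depth"], int)


class TestTrainClassifier:
    def test_learns_separable_data_and_is_deterministic(self):
        rng = np.random.default_rng(3)
        X = rng.normal(size=(200, 3))
        y = (X[:, 0] > 0).astype(int)
        m1 = train_classifier(X, y, seed=5)
        m2 = train_classifier(X, y, seed=5)
        p1 = m1.predict_proba(X)[:, 1]
        p2 = m2.predict_proba(X)[:, 1]
        assert np.array_equal(p1, p2)
        assert ((p1 > 0.5) == y).mean() > 0.95

    def test_single_class_rejected(self):
        with pytest.raises(ValueError):
            train_classifier(np.zeros((10, 2)), np.zeros(10))

    def test_hyperparams_are_applied(self):
        rng = np.random.default_rng(4)
        X = rng.normal(size=(50, 2))
        y = (X[:, 0] > 0).astype(int)
        m = train_classifier(X, y, {"n_estimators": 37, "max_depth": 3})
        assert m.get_params()["n_estimators"] == 37
        assert m.get_params()["max_depth"] == 3


class TestTrialRecord:
    def test_loss_outside_unit_interval_rejected(self):
        with pytest.raises(ValueError):
            TrialRecord({}, 1.5, [], [], 0)


class TestHoldoutLoss:
    def test_informative_feature_beats_noise_only(self):
        pair_set, features = toy_problem(seed=6)
        outer = SplitPlan(
            train_drugs=pair_set.drugs,
            test_drugs=frozenset(),
            train_pairs=pair_set.pairs,
            test_pairs=(),
            dropped_pairs=(),
            seed=0,
            ratio=(2, 1),
        )
        plans = holdout_splits(outer, n_trials=4, seed=1)
        params = {"n_estimators": 40, "max_depth": 3}
        loss_full, auprs, aurocs = holdout_loss(params, plans, features, ["f0"], seed=0)
        loss_noise, _, _ = holdout_loss(params, plans, features, ["f1", "f2"], seed=0)
        assert len(auprs) == len(aurocs) == 4
        assert loss_full < loss_noise

    def test_holdout_drugs_never_seen_in_fit(self):
        pair_set, _ = toy_problem(seed=6)
        outer = SplitPlan(
            train_drugs=pair_set.drugs,
            test_drugs=frozenset(),
            train_pairs=pair_set.pairs,
            test_pairs=(),
            dropped_pairs=(),
            seed=0,
            ratio=(2, 1),
        )
        for plan in holdout_splits(outer, n_trials=6, seed=3):
            fit_drugs = {d for a, b, _ in plan.train_pairs for d in (a, b)}
            val_drugs = {d for a, b, _ in plan.test_pairs for d in (a, b)}
            assert not fit_drugs & val_drugs


class TestTpe:
    def _history(self, space, rng, n, loss_fn):
        hist = []
        for _ in range(n):
            p = space.sample(rng)
            hist.append(TrialRecord(p, loss_fn(p), [], [], 0))
        return hist

    def test_proposals_stay_in_bounds(self):
        space = HyperparamSpace.default()
        rng = np.random.default_rng(7)
        hist = self._history(space, rng, 20, lambda p: float(rng.random()))
        for _ in range(20):
            params = _tpe_propose(space, hist, rng, 0.25, 24)
            assert space.contains(params)

    def test_proposals_concentrate_near_good_region(self):
        # 1-D quadratic loss with minimum at lr = 0.1: TPE proposals should
        # sit closer to the optimum than uniform sampling does on average
        space = HyperparamSpace(
            dimensions=(Dimension("learning_rate", 0.01, 0.3, log=True),)
        )
        rng = np.random.default_rng(8)

        def loss(p):
            return min(1.0, (np.log(p["learning_rate"]) - np.log(0.1)) ** 2)

        hist = self._history(space, rng, 40, loss)
        proposals = [
            _tpe_propose(space, hist, rng, 0.25, 24)["learning_rate"] for _ in range(30)
        ]
        uniform = [space.sample(rng)["learning_rate"] for _ in range(30)]
        d_tpe = np.mean([abs(np.log(v) - np.log(0.1)) for v in proposals])
        d_uni = np.mean([abs(np.log(v) - np.log(0.1)) for v in uniform])
        assert d_tpe < d_uni


class TestTuneHyperparameters:
    def test_full_tuning_runs_and_is_deterministic(self):
        pair_set, features = toy_problem(n_drugs=20, seed=9)
        kwargs = dict(
            features=features,
            feature_names=["f0", "f1", "f2"],
            n_iter=6,
            n_holdout=3,
            seed=2,
            n_warmup=3,
        )
        best1, hist1 = tune_hyperparameters(pair_set, **kwargs)
        best2, hist2 = tune_hyperparameters(pair_set, **kwargs)
        assert best1 == best2
        assert [t.loss for t in hist1] == [t.loss for t in hist2]
        assert len(hist1) == 6
        assert best1 == min(hist1, key=lambda t: t.loss).hyperparams
        assert all(0.0 <= t.loss <= 1.0 for t in hist1)

    def test_random_sampler_supported(self):
        pair_set, features = toy_problem(n_drugs=20, seed=9)
        best, hist = tune_hyperparameters(
            pair_set,
            features,
            ["f0"],
            n_iter=3,
            n_holdout=2,
            seed=4,
            sampler="random",
        )
        assert len(hist) == 3
        assert HyperparamSpace.default().contains(best)

    def test_invalid_sampler_rejected(self):
        pair_set, features = toy_problem(n_drugs=20, seed=9)
        with pytest.raises(ValueError):
            tune_hyperparameters(pair_set, features, ["f0"], sampler="grid")
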