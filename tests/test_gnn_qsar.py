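import itertools

import numpy as np
import pytest

from crossreact3d.gnn_qsar import (
    ActivityTable,
    DescriptorPool,
    NeuralNet411,
    QsarModel,
    consensus_predict,
    ga_select,
    load_models,
    loo_q2,
    predict,
    q2_score,
    run_ensemble,
    save_models,
    scale_activities,
    train_net,
)


def _toy_pool(n_mols=12, n_cols=12, seed=0, planted_col=3):
    rng = np.random.default_rng(seed)
    x = rng.uniform(0.9, 1.0, size=(n_mols, n_cols))
    y = 60.0 * x[:, planted_col] ** 8 - 20.0
    ids = [f"m{i}" for i in range(n_mols)]
    pool = DescriptorPool(
        molecule_ids=ids,
        column_ids=[(f"r{c}", "shape") for c in range(n_cols)],
        matrix=x,
    )
    return pool, ActivityTable(dict(zip(ids, y)))


class TestScaleActivities:
    def test_endpoints(self):
        scaled, sc = scale_activities(np.array([-17.0, 56.0]))
        assert scaled[0] == pytest.approx(0.1)
        assert scaled[1] == pytest.approx(0.9)

    def test_midpoint(self):
        scaled, _ = scale_activities(np.array([0.0, 10.0, 20.0]))
        assert scaled[1] == pytest.approx(0.5)

    def test_roundtrip(self):
        y = np.array([-17.0, 3.0, 12.0, 56.0])
        scaled, sc = scale_activities(y)
        np.testing.assert_allclose(sc.inverse(scaled), y, atol=1e-12)

    def test_constant_errors(self):
        with pytest.raises(ValueError):
            scale_activities(np.array([5.0, 5.0, 5.0]))


class TestTrainNet:
    def test_constant_targets(self):
        rng = np.random.default_rng(0)
        x = rng.uniform(0, 1, size=(10, 4))
        _, sc = scale_activities(np.array([0.0, 1.0]))
        net = train_net(x, np.full(10, 0.5), sc, seed=1)
        np.testing.assert_allclose(net.forward(x), 0.5, atol=1e-3)

    def test_monotone_toy_fit(self):
        rng = np.random.default_rng(1)
        x = rng.uniform(0, 1, size=(4, 4))
        raw = x.mean(axis=1)
        t, sc = scale_activities(raw)
        with pytest.warns(UserWarning):  # 4 rows < recommended minimum
            net = train_net(x, t, sc, seed=2, max_iter=2000)
        sse = float(np.sum((net.forward(x) - t) ** 2))
        assert sse < 1e-3

    def test_determinism(self):
        rng = np.random.default_rng(2)
        x = rng.uniform(0, 1, size=(8, 4))
        t = rng.uniform(0.1, 0.9, size=8)
        _, sc = scale_activities(t)
        n1 = train_net(x, t, sc, seed=7)
        n2 = train_net(x, t, sc, seed=7)
        assert np.array_equal(n1.params, n2.params)

    def test_nonfinite_errors(self):
        _, sc = scale_activities(np.array([0.0, 1.0]))
        x = np.full((6, 4), np.nan)
        with pytest.raises(ValueError):
            train_net(x, np.linspace(0.1, 0.9, 6), sc, seed=0)

    def test_seven_parameters(self):
        _, sc = scale_activities(np.array([0.0, 1.0]))
        net = train_net(np.random.default_rng(0).random((8, 4)), np.linspace(0.1, 0.9, 8), sc)
        assert net.params.size == 7


class TestQ2:
    def test_perfect_predictions(self):
        y = np.array([1.0, 2.0, 5.0])
        assert q2_score(y, y) == 1.0

    def test_mean_predictor_exactly_zero(self):
        y = np.array([0.0, 2.0, 4.0, 9.0])
        assert q2_score(y, np.full(4, y.mean())) == 0.0

    def test_hand_worked_value(self):
        assert q2_score([0, 2, 4], [1, 2, 3]) == pytest.approx(0.75)

    def test_degenerate_variance_errors(self):
        with pytest.raises(ValueError):
            q2_score([3.0, 3.0, 3.0], [1.0, 2.0, 3.0])


class TestLooQ2:
    def test_planted_subset_scores_high(self):
        pool, act = _toy_pool()
        q_good = loo_q2(pool, [3, 5, 7, 9], act, seed=1)
        q_bad = loo_q2(pool, [0, 1, 2, 4], act, seed=1)
        assert q_good > 0.8
        assert q_good > q_bad

    def test_q2_never_exceeds_one(self):
        pool, act = _toy_pool(seed=5)
        for subset in ([0, 1, 2, 3], [4, 5, 6, 7]):
            assert loo_q2(pool, subset, act, seed=0) <= 1.0

    def test_duplicate_subset_errors(self):
        pool, act = _toy_pool()
        with pytest.raises(ValueError):
            loo_q2(pool, [1, 1, 2, 3], act)

    def test_degenerate_activities_error(self):
        pool, _ = _toy_pool()
        const = ActivityTable({i: 1.0 for i in pool.molecule_ids})
        with pytest.raises(ValueError):
            loo_q2(pool, [0, 1, 2, 3], const)


class TestGaSelect:
    def test_pool_of_four_columns(self):
        pool, act = _toy_pool(n_cols=4)
        models = ga_select(pool, act, population=10, generations=2, seed=0)
        assert len(models) == 1
        assert models[0].descriptor_indices == [0, 1, 2, 3]
        assert models[0].q2 == pytest.approx(loo_q2(pool, [0, 1, 2, 3], act, seed=0))

    def test_matches_exhaustive_small_pool(self):
        pool, act = _toy_pool(n_mols=10, n_cols=8, seed=3)
        best_exhaustive = max(
            loo_q2(pool, list(s), act, seed=1, max_iter=100)
            for s in itertools.combinations(range(8), 4)
        )
        models = ga_select(pool, act, population=30, generations=15, seed=1, max_iter=100)
        assert models[0].q2 >= best_exhaustive - 0.02

    def test_determinism(self):
        pool, act = _toy_pool()
        m1 = ga_select(pool, act, population=20, generations=5, seed=4)
        m2 = ga_select(pool, act, population=20, generations=5, seed=4)
        assert m1[0].descriptor_indices == m2[0].descriptor_indices
        assert m1[0].q2 == m2[0].q2

    def test_no_duplicate_descriptors(self):
        pool, act = _toy_pool()
        for model in ga_select(pool, act, population=20, generations=5, seed=2):
            assert len(set(model.descriptor_indices)) == 4

    def test_elitism_monotone_history(self):
        pool, act = _toy_pool()
        hist: list = []
        ga_select(pool, act, population=20, generations=10, seed=3, history=hist)
        assert all(b >= a - 1e-12 for a, b in zip(hist, hist[1:]))

    def test_too_few_columns_errors(self):
        pool, act = _toy_pool(n_cols=3, planted_col=0)
        with pytest.raises(ValueError):
            ga_select(pool, act)


class TestRunEnsemble:
    def test_single_run_equals_ga_select(self):
        pool, act = _toy_pool()
        solo = ga_select(pool, act, population=20, generations=5, seed=11, top_k=5)
        ens = run_ensemble(pool, act, n_runs=1, base_seed=11,
                           population=20, generations=5, top_k=5)
        assert [m.descriptor_indices for m in ens] == [m.descriptor_indices for m in solo]

    def test_dedup_keeps_best(self):
        pool, act = _toy_pool()
        models = run_ensemble(pool, act, n_runs=3, base_seed=0,
                              population=20, generations=5, top_k=5)
        subsets = [tuple(m.descriptor_indices) for m in models]
        assert len(subsets) == len(set(subsets))
        assert all(a.q2 >= b.q2 for a, b in zip(models, models[1:]))

    def test_planted_descriptor_recovered(self):
        pool, act = _toy_pool(n_mols=12, n_cols=24, seed=0, planted_col=3)
        models = run_ensemble(pool, act, n_runs=3, base_seed=1,
                              population=50, generations=15, top_k=5)
        assert models[0].q2 >= 0.8
        assert ("r3", "shape") in [tuple(d) for d in models[0].descriptor_ids]

    def test_invalid_runs(self):
        pool, act = _toy_pool()
        with pytest.raises(ValueError):
            run_ensemble(pool, act, n_runs=0)


class TestPredict:
    def _model(self):
        pool, act = _toy_pool()
        models = ga_select(pool, act, population=20, generations=5, seed=0)
        return pool, act, models[0]

    def test_training_molecule_consistency(self):
        pool, act, model = self._model()
        row = pool.columns(model.descriptor_indices)[0]
        fitted = model.net.predict_activity(pool.columns(model.descriptor_indices))[0]
        assert predict(model, row) == pytest.approx(float(fitted))

    def test_out_of_range_warns_but_computes(self):
        _, _, model = self._model()
        with pytest.warns(UserWarning):
            val = predict(model, np.array([1.5, 0.9, 0.9, 0.9]))
        assert np.isfinite(val)

    def test_wrong_length_errors(self):
        _, _, model = self._model()
        with pytest.raises(ValueError):
            predict(model, np.array([0.9, 0.9]))

    def test_consensus_mean_and_permutation(self):
        pool, act, model = self._model()
        row = pool.columns(model.descriptor_indices)[2]
        p = predict(model, row)
        assert consensus_predict([model], [row]) == pytest.approx(p)
        three = consensus_predict([model, model, model], [row] * 3)
        assert three == pytest.approx(p)

    def test_consensus_requires_models(self):
        with pytest.raises(ValueError):
            consensus_predict([], [])


class TestSerialization:
    def test_roundtrip(self, tmp_path):
        pool, act = _toy_pool()
        models = ga_select(pool, act, population=20, generations=3, seed=0, top_k=3)
        path = tmp_path / "models.json"
        save_models(models, path)
        back = load_models(path)
        assert len(back) == len(models)
        for a, b in zip(models, back):
            assert a.descriptor_ids == b.descriptor_ids
            assert a.q2 == pytest.approx(b.q2)
            np.testing.assert_allclose(a.net.params, b.net.params)
            row = pool.columns(a.descriptor_indices)[0]
            assert predict(a, row) == pytest.approx(predict(b, row))
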