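import numpy as np
import pytest

from crossreact3d import PUBLISHED_TEST_INACTIVE
from crossreact3d.gnn_qsar import (
    ActivityTable,
    DescriptorPool,
    NeuralNet411,
    QsarModel,
    ga_select,
    scale_activities,
)
from crossreact3d.validation_suite import (
    Partition,
    external_test_stats,
    functional_dependence,
    partition_by_activity,
    pearson_r,
    y_randomize,
)


class TestPartition:
    def test_published_partition(self, table1_activities):
        part = partition_by_activity(
            table1_activities, explicit_test_inactive=PUBLISHED_TEST_INACTIVE
        )
        assert len(part.training_ids) == 17
        assert len(part.test_ids) == 6
        assert sorted(part.test_ids, key=int) == ["10", "56", "58", "100", "104", "108"]

    def test_active_test_members_fixed(self, table1_activities):
        # regardless of the inactive draw, the ranked-group scheme fixes these
        part = partition_by_activity(table1_activities, seed=123)
        assert {"10", "56", "58"} <= set(part.test_ids)
        assert len(part.training_ids) == 17 and len(part.test_ids) == 6

    def test_twelve_actives_three_in_test(self):
        scores = {f"a{i}": float(50 - i) for i in range(12)}
        scores.update({f"n{i}": -5.0 for i in range(6)})
        part = partition_by_activity(ActivityTable(scores), seed=0)
        actives_in_test = [i for i in part.test_ids if i.startswith("a")]
        assert len(actives_in_test) == 3

    def test_deterministic_given_seed(self):
        scores = {f"m{i}": float(i) for i in range(20)}
        scores.update({f"z{i}": -1.0 for i in range(5)})
        t = ActivityTable(scores)
        p1 = partition_by_activity(t, seed=9)
        p2 = partition_by_activity(t, seed=9)
        assert p1.test_ids == p2.test_ids and p1.training_ids == p2.training_ids

    def test_insufficient_actives_errors(self):
        scores = {"a": 3.0, "b": 2.0, "c": 1.0, "z1": 0.0, "z2": 0.0}
        with pytest.raises(ValueError):
            partition_by_activity(ActivityTable(scores))

    def test_overlap_rejected(self):
        with pytest.raises(ValueError):
            Partition(training_ids=["a", "b"], test_ids=["b", "c"])


class TestPearson:
    def test_linear_is_one(self):
        x = np.array([1.0, 2.0, 3.0, 4.0])
        assert pearson_r(x, 2 * x + 1) == pytest.approx(1.0)

    def test_anticorrelated(self):
        x = np.array([1.0, 2.0, 3.0])
        assert pearson_r(x, -x) == pytest.approx(-1.0)

    def test_hand_value(self):
        assert pearson_r([1, 2, 3], [1, 2, 2]) == pytest.approx(0.866, abs=5e-4)

    def test_zero_variance_errors(self):
        with pytest.raises(ValueError):
            pearson_r([1, 2, 3], [5, 5, 5])

    def test_too_few_points(self):
        with pytest.raises(ValueError):
            pearson_r([1, 2], [3, 4])


@pytest.fixture(scope="module")
def trained_planted(planted_23):
    """Models trained on the activity-ranked training split of the planted set."""
    part = partition_by_activity(planted_23["activities"], seed=0)
    pool = DescriptorPool.from_similarity(
        planted_23["similarity"], molecule_ids=part.training_ids
    )
    acts = ActivityTable(
        {i: planted_23["activities"].scores[i] for i in part.training_ids}
    )
    models = ga_select(pool, acts, population=60, generations=20, seed=1, max_iter=100)
    return part, pool, acts, models


class TestExternalTestStats:
    def test_planted_model_predicts_test_set(self, planted_23, trained_planted):
        part, pool, acts, models = trained_planted
        stats = external_test_stats(
            models[:1], part, planted_23["similarity"], planted_23["activities"]
        )
        assert stats["r"] > 0.8  # strong planted signal carries to the test set

    def test_training_leak_rejected(self, planted_23):
        ids = planted_23["pool"].molecule_ids
        part = Partition(training_ids=ids[:17], test_ids=ids[17:])
        pool = planted_23["pool"]  # trained on ALL molecules, including test
        models = ga_select(
            pool, planted_23["activities"],
            population=10, generations=1, seed=0, max_iter=30,
        )
        with pytest.raises(ValueError, match="outside the training split"):
            external_test_stats(models[:1], part, planted_23["similarity"],
                                planted_23["activities"])

    def test_small_test_set_errors(self, planted_23, trained_planted):
        part, _, _, models = trained_planted
        tiny = Partition(training_ids=part.training_ids, test_ids=part.test_ids[:2])
        with pytest.raises(ValueError):
            external_test_stats(models[:1], tiny, planted_23["similarity"],
                                planted_23["activities"])


class TestFunctionalDependence:
    def _stub_model(self, pool, params):
        _, scaler = scale_activities(np.array([0.0, 10.0]))
        net = NeuralNet411(params=np.array(params, dtype=float), scaler=scaler)
        return QsarModel(
            descriptor_ids=pool.column_ids[:4],
            descriptor_indices=[0, 1, 2, 3],
            net=net,
            q2=0.5,
            training_ids=pool.molecule_ids,
            seed=0,
        )

    def _pool(self):
        rng = np.random.default_rng(0)
        x = rng.uniform(0.8, 1.0, size=(10, 6))
        return DescriptorPool(
            molecule_ids=[f"m{i}" for i in range(10)],
            column_ids=[(f"r{c}", "shape") for c in range(6)],
            matrix=x,
        )

    def test_zero_weight_descriptor_flat(self):
        pool = self._pool()
        model = self._stub_model(pool, [0.0, 1.0, 1.0, 1.0, 0.1, 2.0, -0.5])
        scan, preds = functional_dependence(model, 0, pool)
        assert np.ptp(preds) < 1e-12

    def test_curve_value_at_average(self):
        pool = self._pool()
        model = self._stub_model(pool, [1.0, -2.0, 0.5, 1.5, 0.1, 2.0, -0.5])
        cols = pool.columns(model.descriptor_indices)
        avg = cols.mean(axis=0)
        # symmetric odd-point scan puts the training average exactly mid-scan
        scan, preds = functional_dependence(
            model, 1, pool, n_points=51, scan_range=(avg[1] - 0.1, avg[1] + 0.1)
        )
        at_avg = model.net.predict_activity(avg)[0]
        assert scan[25] == pytest.approx(avg[1])
        assert preds[25] == pytest.approx(float(at_avg), abs=1e-9)

    def test_planted_monotone_curve(self, planted_23):
        pool = planted_23["pool"]
        models = ga_select(pool, planted_23["activities"],
                           population=60, generations=20, seed=2, max_iter=100)
        model = models[0]
        ref = planted_23["truth"].reference_ids[0]
        ids = [tuple(d) for d in model.descriptor_ids]
        if (ref, "shape") in ids:
            idx = ids.index((ref, "shape"))
            scan, preds = functional_dependence(model, idx, pool)
            # monotone non-decreasing trend overall
            assert preds[-1] > preds[0]


class TestYRandomize:
    def test_planted_separation_scaled(self, planted_23):
        pool = planted_23["pool"]
        acts = planted_23["activities"]
        report = y_randomize(
            pool, acts, n_shuffles=3, runs_per_shuffle=2, keep_best=5, seed=0,
            population=30, generations=8, max_iter=80,
        )
        assert report.separation
        best_real = max(q for q, _ in report.real_models)
        assert best_real > report.max_randomized_q2()

    def test_pure_noise_no_separation(self, planted_23, noise_23):
        pool = planted_23["pool"]
        report = y_randomize(
            pool, noise_23, n_shuffles=2, runs_per_shuffle=1, keep_best=5, seed=1,
            population=20, generations=5, max_iter=60,
        )
        assert not report.separation

    def test_shuffles_preserve_multiset(self, planted_23):
        # asserted inside y_randomize on every shuffle; exercise the path
        report = y_randomize(
            planted_23["pool"], planted_23["activities"],
            n_shuffles=1, runs_per_shuffle=1, keep_best=3, seed=2,
            population=10, generations=2, max_iter=40,
        )
        assert len(report.randomized_models) == 1
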