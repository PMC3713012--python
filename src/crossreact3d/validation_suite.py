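"""Model validation: partitioning, external-test statistics, functional
dependence scans and y-randomization."""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
from scipy import stats

from .gnn_qsar import (
    ActivityTable,
    DescriptorPool,
    QsarModel,
    predict,
    run_ensemble,
)
from .similarity import SimilarityMatrix

__all__ = [
    "Partition",
    "RandomizationReport",
    "partition_by_activity",
    "external_test_stats",
    "functional_dependence",
    "y_randomize",
    "pearson_r",
]


@dataclass
class Partition:
    training_ids: list[str]
    test_ids: list[str]

    def __post_init__(self) -> None:
        overlap = set(self.training_ids) & set(self.test_ids)
        if overlap:
            raise ValueError(f"training and test overlap: {sorted(overlap)}")


def partition_by_activity(
    activities: ActivityTable,
    ranked_group_size: int = 4,
    n_random_inactive_test: int = 3,
    seed: int | None = None,
    explicit_test_inactive: Sequence[str] | None = None,
) -> Partition:
    """Activity-ranked train/test split.

    Molecules above the tied minimal score ("actives") are sorted descending
    by score (stable: ties keep input order), chunked into groups of
    ranked_group_size; within each group the most active ranked_group_size-1
    go to training and the least active member goes to the test set.  Of the
    tied-minimal "inactive" block, n_random_inactive_test members go to the
    test set -- drawn with the given seed, or exactly the ids in
    explicit_test_inactive when provided -- and the rest to training.
    """
    ids = activities.ids()
    scores = activities.values_for(ids)
    floor = scores.min()
    inactive = [i for i, s in zip(ids, scores) if s == floor]
    active = [(i, s) for i, s in zip(ids, scores) if s > floor]
    if len(active) < 3 * ranked_group_size:
        raise ValueError(
            f"{len(active)} actives; need >= {3 * ranked_group_size} for ranked groups"
        )
    # stable descending sort by score: ties keep input (table) order
    active_sorted = sorted(active, key=lambda t: -t[1])

    train: list[str] = []
    test: list[str] = []
    for start in range(0, len(active_sorted), ranked_group_size):
        group = active_sorted[start : start + ranked_group_size]
        keep = min(ranked_group_size - 1, len(group))
        train.extend(i for i, _ in group[:keep])
        test.extend(i for i, _ in group[keep:])

    if explicit_test_inactive is not None:
        chosen = [str(i) for i in explicit_test_inactive]
        missing = [i for i in chosen if i not in inactive]
        if missing:
            raise ValueError(f"explicit test inactives not in the tied block: {missing}")
    else:
        rng = np.random.default_rng(seed)
        n_draw = min(n_random_inactive_test, len(inactive))
        idx = rng.choice(len(inactive), size=n_draw, replace=False)
        chosen = [inactive[k] for k in sorted(idx.tolist())]
    test.extend(chosen)
    train.extend(i for i in inactive if i not in chosen)

    if len(test) < 5:
        import warnings

        warnings.warn(f"external test set has only {len(test)} members", stacklevel=2)
    return Partition(training_ids=train, test_ids=test)


def pearson_r(x: Sequence[float], y: Sequence[float]) -> float:
    """Pearson product-moment correlation; errors on degenerate variance."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size < 3 or y.size != x.size:
        raise ValueError("need >= 3 paired values")
    if np.std(x) == 0 or np.std(y) == 0:
        raise ValueError("zero variance")
    return float(stats.pearsonr(x, y).statistic)


def external_test_stats(
    models: Sequence[QsarModel],
    partition: Partition,
    sim: SimilarityMatrix,
    activities: ActivityTable,
) -> dict:
    """Predicted-vs-experimental statistics on the external test set.

    Uses the first (best) model; predictions are the consensus when several
    models are passed.  Returns Pearson r plus the least-squares slope and
    intercept of predicted (y) on experimental (x).
    """
    if len(partition.test_ids) < 3:
        raise ValueError("test set too small for regression statistics")
    for model in models:
        if set(model.training_ids) - set(partition.training_ids):
            raise ValueError("model was trained on molecules outside the training split")
    pool = DescriptorPool.from_similarity(sim, molecule_ids=partition.training_ids)
    preds = []
    for test_id in partition.test_ids:
        per_model = []
        for model in models:
            row = pool.query_row(sim, test_id, model.descriptor_ids)
            per_model.append(predict(model, row))
        preds.append(float(np.mean(per_model)))
    y_exp = activities.values_for(partition.test_ids)
    fit = stats.linregress(y_exp, preds)
    return {
        "r": float(fit.rvalue),
        "slope": float(fit.slope),
        "intercept": float(fit.intercept),
        "predictions": dict(zip(partition.test_ids, preds)),
        "experimental": dict(zip(partition.test_ids, y_exp.tolist())),
    }


def functional_dependence(
    model: QsarModel,
    descriptor_index: int,
    pool: DescriptorPool,
    scan_range: tuple[float, float] | None = None,
    n_points: int = 50,
) -> tuple[np.ndarray, np.ndarray]:
    """Predicted activity versus one descriptor, others pinned at their mean.

    The scanned descriptor varies over scan_range (default: its observed
    [min, max] in the pool); the remaining three inputs are fixed at their
    training-set average.  Returns (scanned values, predicted activities).
    """
    cols = pool.columns(model.descriptor_indices)
    averages = cols.mean(axis=0)
    if scan_range is None:
        scan_range = (float(cols[:, descriptor_index].min()), float(cols[:, descriptor_index].max()))
    scan = np.linspace(scan_range[0], scan_range[1], n_points)
    x = np.tile(averages, (n_points, 1))
    x[:, descriptor_index] = scan
    preds = model.net.predict_activity(x).ravel()
    return scan, preds


@dataclass
class RandomizationReport:
    real_models: list[tuple[float, float]]  # (q2, r2) of the real top models
    randomized_models: list[list[tuple[float, float]]]  # per shuffle, kept models
    separation: bool = False

    def max_randomized_q2(self) -> float:
        q2s = [q for shuffle in self.randomized_models for q, _ in shuffle]
        return max(q2s) if q2s else float("-inf")


def _training_r2(model: QsarModel, pool: DescriptorPool, activities: ActivityTable) -> float:
    y_exp = activities.values_for(pool.molecule_ids)
    preds = model.net.predict_activity(pool.columns(model.descriptor_indices)).ravel()
    if np.std(preds) == 0:
        return 0.0
    return float(stats.pearsonr(y_exp, preds).statistic ** 2)


def y_randomize(
    pool: DescriptorPool,
    activities: ActivityTable,
    n_shuffles: int = 100,
    runs_per_shuffle: int = 50,
    keep_best: int = 10,
    seed: int = 0,
    real_models: Sequence[QsarModel] | None = None,
    **ga_kwargs,
) -> RandomizationReport:
    """Refit with shuffled activities and compare against the real models.

    Each shuffle permutes the activity vector over the molecules (preserving
    its multiset), reruns the GNN ensemble, and keeps the keep_best models
    with q2 >= 0.  The separation flag is true iff every real model's q2
    strictly exceeds every retained randomized q2.
    """
    rng = np.random.default_rng(seed)
    ids = pool.molecule_ids
    y = activities.values_for(ids)

    if real_models is None:
        real_models = run_ensemble(
            pool, activities, n_runs=runs_per_shuffle, base_seed=seed, **ga_kwargs
        )[:3]
    real_pairs = [(m.q2, _training_r2(m, pool, activities)) for m in real_models]

    randomized: list[list[tuple[float, float]]] = []
    for shuffle_i in range(n_shuffles):
        perm = rng.permutation(len(ids))
        shuffled = ActivityTable(scores=dict(zip(ids, y[perm])))
        assert sorted(shuffled.scores.values()) == sorted(y.tolist())
        models = run_ensemble(
            pool,
            shuffled,
            n_runs=runs_per_shuffle,
            base_seed=seed + 1000 * (shuffle_i + 1),
            **ga_kwargs,
        )
        kept = [
            (m.q2, _training_r2(m, pool, shuffled))
            for m in models[:keep_best]
            if m.q2 >= 0
        ]
        randomized.append(kept)

    report = RandomizationReport(real_models=real_pairs, randomized_models=randomized)
    max_rand = report.max_randomized_q2()
    report.separation = all(q2 > max_rand for q2, _ in real_pairs)
    return report
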