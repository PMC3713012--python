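"""Genetic-neural-network QSAR on similarity descriptors.

A genetic algorithm selects 4 columns from the descriptor pool (the
similarity of every training molecule to every reference molecule, in both
the shape and the electrostatic field, 2N columns for N molecules).  Each
candidate subset is scored by the leave-one-out cross-validated q2 of a
4-1-1 feed-forward network (4 input weights, 1 hidden bias, 1 output weight,
1 output bias -- 7 adjustable parameters, logistic sigmoid on the hidden and
the output unit).  Activities are affinely mapped onto [0.1, 0.9] for the
sigmoid output and mapped back for prediction.

Training uses iRprop- (sign-based resilient backpropagation), which is
deterministic for a fixed seed and vectorises over LOO folds and over whole
GA populations at once; this batching is what makes exhaustive-subset
benchmarking feasible.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

from .similarity import SimilarityMatrix

__all__ = [
    "ActivityTable",
    "ActivityScaler",
    "scale_activities",
    "DescriptorPool",
    "NeuralNet411",
    "train_net",
    "loo_q2",
    "q2_score",
    "ga_select",
    "run_ensemble",
    "QsarModel",
    "predict",
    "consensus_predict",
    "save_models",
    "load_models",
]

N_PARAMS = 7  # 4 input weights + hidden bias + output weight + output bias


# --------------------------------------------------------------------------
# activities
# --------------------------------------------------------------------------


@dataclass
class ActivityTable:
    """Per-molecule activity scores (e.g. cross-reactivity sums)."""

    scores: dict[str, float]

    def __post_init__(self) -> None:
        self.scores = {str(k): float(v) for k, v in self.scores.items()}

    def ids(self) -> list[str]:
        return list(self.scores)

    def values_for(self, ids: Sequence[str]) -> np.ndarray:
        missing = [i for i in ids if i not in self.scores]
        if missing:
            raise KeyError(f"no activity for molecules: {missing}")
        return np.array([self.scores[i] for i in ids], dtype=float)

    @classmethod
    def from_csv(cls, path: str | Path) -> "ActivityTable":
        df = pd.read_csv(path)
        id_col, score_col = df.columns[0], df.columns[1]
        return cls(scores=dict(zip(df[id_col].astype(str), df[score_col].astype(float))))

    def to_csv(self, path: str | Path) -> None:
        pd.DataFrame(
            {"molecule_id": list(self.scores), "score": list(self.scores.values())}
        ).to_csv(path, index=False)


@dataclass(frozen=True)
class ActivityScaler:
    """Affine map of the observed score range onto [lo, hi] and back."""

    score_min: float
    score_max: float
    lo: float = 0.1
    hi: float = 0.9

    def transform(self, y: np.ndarray | float) -> np.ndarray | float:
        span = self.score_max - self.score_min
        return self.lo + (np.asarray(y, dtype=float) - self.score_min) * (self.hi - self.lo) / span

    def inverse(self, t: np.ndarray | float) -> np.ndarray | float:
        span = self.score_max - self.score_min
        return self.score_min + (np.asarray(t, dtype=float) - self.lo) * span / (self.hi - self.lo)


def scale_activities(scores: np.ndarray, lo: float = 0.1, hi: float = 0.9) -> tuple[np.ndarray, ActivityScaler]:
    """Map scores onto [lo, hi]; returns (scaled, scaler with inverse)."""
    y = np.asarray(scores, dtype=float)
    if y.size < 2 or np.ptp(y) == 0:
        raise ValueError("activity scaling needs >= 2 distinct scores")
    scaler = ActivityScaler(score_min=float(y.min()), score_max=float(y.max()), lo=lo, hi=hi)
    return np.asarray(scaler.transform(y)), scaler


# --------------------------------------------------------------------------
# descriptor pool
# --------------------------------------------------------------------------


@dataclass
class DescriptorPool:
    """Similarity-to-reference columns for a fixed ordered set of molecules.

    Column c is the similarity of each pool molecule to reference molecule
    ``column_ids[c][0]`` in field ``column_ids[c][1]`` ("shape" or
    "electrostatic"); self-similarity entries (=1) are included.
    """

    molecule_ids: list[str]
    column_ids: list[tuple[str, str]]
    matrix: np.ndarray  # (n_molecules, n_columns)

    def __post_init__(self) -> None:
        self.matrix = np.asarray(self.matrix, dtype=float)
        if self.matrix.shape != (len(self.molecule_ids), len(self.column_ids)):
            raise ValueError("pool matrix shape does not match ids")

    @property
    def n_columns(self) -> int:
        return len(self.column_ids)

    @classmethod
    def from_similarity(
        cls,
        sim: SimilarityMatrix,
        molecule_ids: Sequence[str] | None = None,
        reference_ids: Sequence[str] | None = None,
    ) -> "DescriptorPool":
        """Build the 2N-column pool (shape + electrostatic references).

        ``molecule_ids`` restricts the rows (e.g. to a training partition);
        ``reference_ids`` restricts the reference columns (defaults to the
        same set, giving the 2N training-reference columns).
        """
        mol_ids = [str(i) for i in (molecule_ids if molecule_ids is not None else sim.molecule_ids)]
        ref_ids = [str(i) for i in (reference_ids if reference_ids is not None else mol_ids)]
        index = {m: k for k, m in enumerate(sim.molecule_ids)}
        rows = [index[m] for m in mol_ids]
        cols = [index[r] for r in ref_ids]
        blocks = [sim.shape[np.ix_(rows, cols)], sim.electrostatic[np.ix_(rows, cols)]]
        column_ids = [(r, "shape") for r in ref_ids] + [(r, "electrostatic") for r in ref_ids]
        return cls(molecule_ids=mol_ids, column_ids=column_ids, matrix=np.hstack(blocks))

    def columns(self, subset: Sequence[int]) -> np.ndarray:
        return self.matrix[:, list(subset)]

    def query_row(self, sim: SimilarityMatrix, query_id: str, subset_ids: Sequence[tuple[str, str]]) -> np.ndarray:
        """Descriptor values of a query molecule present in *sim*."""
        index = {m: k for k, m in enumerate(sim.molecule_ids)}
        qi = index[str(query_id)]
        out = []
        for ref, kind in subset_ids:
            m = sim.shape if kind == "shape" else sim.electrostatic
            out.append(m[qi, index[str(ref)]])
        return np.array(out)


# --------------------------------------------------------------------------
# 4-1-1 network
# --------------------------------------------------------------------------


def _sigmoid(z: np.ndarray) -> np.ndarray:
    out = np.empty_like(z)
    pos = z >= 0
    out[pos] = 1.0 / (1.0 + np.exp(-z[pos]))
    ez = np.exp(z[~pos])
    out[~pos] = ez / (1.0 + ez)
    return out


def _forward(params: np.ndarray, x: np.ndarray) -> np.ndarray:
    """Batched forward pass: params (..., 7), x (..., n, 4) -> (..., n)."""
    w_in = params[..., :4]
    b_h = params[..., 4:5]
    w_out = params[..., 5:6]
    b_o = params[..., 6:7]
    h = _sigmoid(np.einsum("...ni,...i->...n", x, w_in) + b_h)
    return _sigmoid(w_out * h + b_o)


def _sse_and_grad(params: np.ndarray, x: np.ndarray, y: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Sum-of-squares loss and gradient, batched over leading dims."""
    w_in = params[..., :4]
    b_h = params[..., 4:5]
    w_out = params[..., 5:6]
    b_o = params[..., 6:7]
    z1 = np.einsum("...ni,...i->...n", x, w_in) + b_h
    h = _sigmoid(z1)
    o = _sigmoid(w_out * h + b_o)
    r = o - y
    sse = np.sum(r * r, axis=-1)
    do = 2.0 * r * o * (1.0 - o)  # (..., n)
    g_wout = np.sum(do * h, axis=-1, keepdims=True)
    g_bo = np.sum(do, axis=-1, keepdims=True)
    dz1 = do * w_out * h * (1.0 - h)
    g_win = np.einsum("...n,...ni->...i", dz1, x)
    g_bh = np.sum(dz1, axis=-1, keepdims=True)
    return sse, np.concatenate([g_win, g_bh, g_wout, g_bo], axis=-1)


def _fit_batched(
    x: np.ndarray,
    y: np.ndarray,
    seed: int,
    max_iter: int = 500,
    tol: float = 1e-6,
    mask: np.ndarray | None = None,
) -> np.ndarray:
    """Fit independent 4-1-1 nets for every leading index of x/y.

    x has shape (..., n, 4) and y (..., n); a boolean *mask* (..., n) can
    exclude rows (used for LOO folds).  All nets start from the same seeded
    initial parameter vector, so a single-problem fit and the same problem
    inside a batch give identical results.  Optimiser: iRprop- with step
    bounds [1e-8, 1.0], eta+ 1.2, eta- 0.5.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if not (np.all(np.isfinite(x)) and np.all(np.isfinite(y))):
        raise ValueError("non-finite inputs or targets")
    batch_shape = y.shape[:-1]
    rng = np.random.default_rng(seed)
    init = rng.normal(0.0, 0.5, size=N_PARAMS)
    params = np.broadcast_to(init, batch_shape + (N_PARAMS,)).copy()

    if mask is not None:
        w = mask.astype(float)
    else:
        w = None

    def grad_of(p: np.ndarray) -> np.ndarray:
        if w is None:
            _, g = _sse_and_grad(p, x, y)
        else:
            # zero the contribution of masked-out rows
            _, g = _sse_and_grad_weighted(p, x, y, w)
        return g

    step = np.full_like(params, 0.1)
    g_prev = np.zeros_like(params)
    for _ in range(max_iter):
        g = grad_of(params)
        if np.max(np.abs(g)) <= tol:
            break
        same = g * g_prev
        step = np.where(same > 0, np.minimum(step * 1.2, 1.0), step)
        step = np.where(same < 0, np.maximum(step * 0.5, 1e-8), step)
        g = np.where(same < 0, 0.0, g)  # iRprop-: skip update after sign flip
        params = params - np.sign(g) * step
        g_prev = g
    return params


def _sse_and_grad_weighted(
    params: np.ndarray, x: np.ndarray, y: np.ndarray, w: np.ndarray
) -> tuple[np.ndarray, np.ndarray]:
    w_in = params[..., :4]
    b_h = params[..., 4:5]
    w_out = params[..., 5:6]
    b_o = params[..., 6:7]
    z1 = np.einsum("...ni,...i->...n", x, w_in) + b_h
    h = _sigmoid(z1)
    o = _sigmoid(w_out * h + b_o)
    r = (o - y) * w
    sse = np.sum(r * r, axis=-1)
    do = 2.0 * r * o * (1.0 - o) * w
    g_wout = np.sum(do * h, axis=-1, keepdims=True)
    g_bo = np.sum(do, axis=-1, keepdims=True)
    dz1 = do * w_out * h * (1.0 - h)
    g_win = np.einsum("...n,...ni->...i", dz1, x)
    g_bh = np.sum(dz1, axis=-1, keepdims=True)
    return sse, np.concatenate([g_win, g_bh, g_wout, g_bo], axis=-1)


def _standardize_stats(x: np.ndarray, mask: np.ndarray | None = None) -> tuple[np.ndarray, np.ndarray]:
    """Per-descriptor mean/std over the (masked) training rows.

    x: (..., n, 4); mask: (..., n) selecting training rows.  Descriptor
    similarities span a very narrow band near 1, which makes the raw
    weight/bias landscape badly conditioned; centering is a fixed,
    data-derived preprocessing (like the activity scaling), not an
    adjustable parameter.
    """
    if mask is None:
        mean = x.mean(axis=-2, keepdims=True)
        std = x.std(axis=-2, keepdims=True)
    else:
        w = mask[..., None].astype(float)
        count = w.sum(axis=-2, keepdims=True)
        mean = (x * w).sum(axis=-2, keepdims=True) / count
        var = (w * (x - mean) ** 2).sum(axis=-2, keepdims=True) / count
        std = np.sqrt(var)
    std = np.where(std > 0, std, 1.0)
    return mean, std


@dataclass
class NeuralNet411:
    """Trained 4-1-1 network plus the fixed input/output scalings.

    ``x_mean``/``x_scale`` standardize the descriptor inputs (fit-time
    training statistics); the 7 entries of ``params`` are the adjustable
    weights and thresholds.
    """

    params: np.ndarray  # length 7
    scaler: ActivityScaler
    x_mean: np.ndarray = None  # type: ignore[assignment]
    x_scale: np.ndarray = None  # type: ignore[assignment]

    def __post_init__(self) -> None:
        self.params = np.asarray(self.params, dtype=float).ravel()
        if self.params.size != N_PARAMS:
            raise ValueError(f"expected {N_PARAMS} parameters, got {self.params.size}")
        if not np.all(np.isfinite(self.params)):
            raise ValueError("non-finite network parameters")
        self.x_mean = np.zeros(4) if self.x_mean is None else np.asarray(self.x_mean, dtype=float).ravel()
        self.x_scale = np.ones(4) if self.x_scale is None else np.asarray(self.x_scale, dtype=float).ravel()

    def forward(self, x: np.ndarray) -> np.ndarray:
        """Scaled-space output for descriptor rows x of shape (n, 4) or (4,)."""
        x = np.atleast_2d(np.asarray(x, dtype=float))
        return _forward(self.params, (x - self.x_mean) / self.x_scale)

    def predict_activity(self, x: np.ndarray) -> np.ndarray:
        return np.asarray(self.scaler.inverse(self.forward(x)))


def train_net(
    inputs: np.ndarray,
    targets: np.ndarray,
    scaler: ActivityScaler,
    seed: int = 0,
    max_iter: int = 500,
    tol: float = 1e-6,
) -> NeuralNet411:
    """Fit one 4-1-1 net on scaled targets; deterministic for a fixed seed."""
    x = np.asarray(inputs, dtype=float)
    t = np.asarray(targets, dtype=float)
    if x.ndim != 2 or x.shape[1] != 4:
        raise ValueError("inputs must be (n, 4)")
    if x.shape[0] < 5:
        import warnings

        warnings.warn(
            f"{x.shape[0]} training rows for {N_PARAMS} parameters", stacklevel=2
        )
    mean, std = _standardize_stats(x)
    xs = (x - mean) / std
    params = _fit_batched(xs, t, seed=seed, max_iter=max_iter, tol=tol)
    # multi-start quasi-Newton polish: iRprop- can stall on the curved narrow
    # valley of this tiny net, so a few deterministic BFGS restarts (seeded
    # inits, 7 parameters -- cheap) pick up the exact minimum when one exists
    from scipy.optimize import minimize

    best_params = params
    best_sse = float(_sse_and_grad(params, xs, t)[0])
    rng = np.random.default_rng(seed)
    starts = [params] + [rng.normal(0.0, 2.0, size=N_PARAMS) for _ in range(4)]
    for p0 in starts:
        res = minimize(
            lambda p: tuple(v for v in _sse_and_grad(p, xs, t)),
            p0,
            jac=True,
            method="BFGS",
            options={"maxiter": max_iter, "gtol": tol},
        )
        if np.all(np.isfinite(res.x)) and res.fun < best_sse:
            best_sse = float(res.fun)
            best_params = res.x
    return NeuralNet411(params=best_params, scaler=scaler, x_mean=mean.ravel(), x_scale=std.ravel())


# --------------------------------------------------------------------------
# leave-one-out q2
# --------------------------------------------------------------------------


def q2_score(y_exp: np.ndarray, y_pred: np.ndarray) -> float:
    """q2 = 1 - PRESS / SS_tot about the mean experimental activity."""
    y_exp = np.asarray(y_exp, dtype=float)
    y_pred = np.asarray(y_pred, dtype=float)
    ss_tot = float(np.sum((y_exp - y_exp.mean()) ** 2))
    if ss_tot == 0:
        raise ValueError("degenerate activity variance")
    return 1.0 - float(np.sum((y_pred - y_exp) ** 2)) / ss_tot


def _loo_q2_batch(
    x_subsets: np.ndarray,
    y_scaled: np.ndarray,
    y_exp: np.ndarray,
    scaler: ActivityScaler,
    seed: int,
    max_iter: int,
    tol: float,
) -> np.ndarray:
    """LOO q2 for a batch of descriptor subsets.

    x_subsets: (S, N, 4); returns q2 array of length S.  All S*N fold nets
    are trained in one vectorised iRprop- run, each fold masking out its
    held-out molecule.
    """
    s, n, _ = x_subsets.shape
    fold_mask = ~np.eye(n, dtype=bool)  # (N folds, N rows)
    x_folds = np.broadcast_to(x_subsets[:, None, :, :], (s, n, n, 4))
    y_folds = np.broadcast_to(y_scaled[None, None, :], (s, n, n))
    mask = np.broadcast_to(fold_mask[None, :, :], (s, n, n))
    # per-fold standardization from the fold's own training rows only
    mean, std = _standardize_stats(x_folds, mask)
    params = _fit_batched(
        (x_folds - mean) / std, y_folds, seed=seed, max_iter=max_iter, tol=tol, mask=mask
    )
    # predict each held-out molecule with its fold's net and fold's scaling
    held_x = (x_subsets[:, :, None, :] - mean) / std  # (S, N, 1, 4)
    preds_scaled = _forward(params, held_x)[..., 0]  # (S, N)
    preds = np.asarray(scaler.inverse(preds_scaled))
    ss_tot = float(np.sum((y_exp - y_exp.mean()) ** 2))
    press = np.sum((preds - y_exp[None, :]) ** 2, axis=1)
    return 1.0 - press / ss_tot


def loo_q2(
    pool: DescriptorPool,
    subset: Sequence[int],
    activities: ActivityTable,
    seed: int = 0,
    max_iter: int = 200,
    tol: float = 1e-6,
) -> float:
    """Leave-one-out cross-validated q2 of one 4-descriptor subset."""
    subset = list(subset)
    if len(set(subset)) != len(subset):
        raise ValueError("descriptor subset must be distinct")
    y_exp = activities.values_for(pool.molecule_ids)
    if y_exp.size < 3:
        raise ValueError("need at least 3 molecules for LOO q2")
    y_scaled, scaler = scale_activities(y_exp)
    x = pool.columns(subset)[None, :, :]
    return float(
        _loo_q2_batch(x, y_scaled, y_exp, scaler, seed=seed, max_iter=max_iter, tol=tol)[0]
    )


# --------------------------------------------------------------------------
# QSAR model container
# --------------------------------------------------------------------------


@dataclass
class QsarModel:
    descriptor_ids: list[tuple[str, str]]  # (reference molecule, field)
    descriptor_indices: list[int]
    net: NeuralNet411
    q2: float
    training_ids: list[str]
    seed: int
    run_index: int = 0

    def __post_init__(self) -> None:
        if len(set(map(tuple, self.descriptor_ids))) != len(self.descriptor_ids):
            raise ValueError("descriptor ids must be distinct")
        if self.q2 > 1.0 + 1e-12:
            raise ValueError("q2 cannot exceed 1")

    def to_dict(self) -> dict:
        return {
            "descriptor_ids": [list(d) for d in self.descriptor_ids],
            "descriptor_indices": list(map(int, self.descriptor_indices)),
            "params": self.net.params.tolist(),
            "x_mean": self.net.x_mean.tolist(),
            "x_scale": self.net.x_scale.tolist(),
            "scaler": {
                "score_min": self.net.scaler.score_min,
                "score_max": self.net.scaler.score_max,
                "lo": self.net.scaler.lo,
                "hi": self.net.scaler.hi,
            },
            "q2": self.q2,
            "training_ids": self.training_ids,
            "seed": self.seed,
            "run_index": self.run_index,
        }

    @classmethod
    def from_dict(cls, d: dict) -> "QsarModel":
        scaler = ActivityScaler(**d["scaler"])
        return cls(
            descriptor_ids=[tuple(x) for x in d["descriptor_ids"]],
            descriptor_indices=list(d["descriptor_indices"]),
            net=NeuralNet411(
                params=np.array(d["params"]),
                scaler=scaler,
                x_mean=np.array(d.get("x_mean", np.zeros(4))),
                x_scale=np.array(d.get("x_scale", np.ones(4))),
            ),
            q2=float(d["q2"]),
            training_ids=list(d["training_ids"]),
            seed=int(d["seed"]),
            run_index=int(d.get("run_index", 0)),
        )


def save_models(models: Sequence[QsarModel], path: str | Path) -> None:
    Path(path).write_text(json.dumps([m.to_dict() for m in models], indent=2))


def load_models(path: str | Path) -> list[QsarModel]:
    return [QsarModel.from_dict(d) for d in json.loads(Path(path).read_text())]


def _final_model(
    pool: DescriptorPool,
    subset: tuple[int, ...],
    q2: float,
    activities: ActivityTable,
    seed: int,
    run_index: int,
    max_iter: int,
    tol: float,
) -> QsarModel:
    y_exp = activities.values_for(pool.molecule_ids)
    y_scaled, scaler = scale_activities(y_exp)
    net = train_net(pool.columns(subset), y_scaled, scaler, seed=seed, max_iter=max_iter, tol=tol)
    return QsarModel(
        descriptor_ids=[pool.column_ids[i] for i in subset],
        descriptor_indices=list(subset),
        net=net,
        q2=float(q2),
        training_ids=list(pool.molecule_ids),
        seed=seed,
        run_index=run_index,
    )


# --------------------------------------------------------------------------
# genetic algorithm
# --------------------------------------------------------------------------


def ga_select(
    pool: DescriptorPool,
    activities: ActivityTable,
    population: int = 250,
    generations: int = 75,
    subset_size: int = 4,
    seed: int = 0,
    mutation_rate: float = 0.05,
    top_k: int = 10,
    max_iter: int = 200,
    tol: float = 1e-6,
    run_index: int = 0,
    history: list | None = None,
) -> list[QsarModel]:
    """Evolve descriptor subsets with LOO q2 fitness.

    Integer-set chromosomes (subset_size distinct column indices), tournament
    selection of size 2, uniform crossover with duplicate repair, per-gene
    mutation resampling an unused column, elitism of 1.  Returns the top_k
    unique subsets ever evaluated, as fully trained models sorted by q2
    descending.  Deterministic for a fixed seed.  If *history* is a list, the
    best fitness in each generation's population is appended to it.
    """
    n_cols = pool.n_columns
    if n_cols < subset_size:
        raise ValueError(f"pool has {n_cols} columns; need >= {subset_size}")
    y_exp = activities.values_for(pool.molecule_ids)
    y_scaled, scaler = scale_activities(y_exp)
    rng = np.random.default_rng(seed)

    cache: dict[tuple[int, ...], float] = {}

    def evaluate(subsets: list[tuple[int, ...]]) -> None:
        todo = sorted({s for s in subsets if s not in cache})
        if not todo:
            return
        x = np.stack([pool.columns(s) for s in todo])
        q2s = _loo_q2_batch(x, y_scaled, y_exp, scaler, seed=seed, max_iter=max_iter, tol=tol)
        for s, q in zip(todo, q2s):
            cache[s] = float(q)

    def random_subset() -> tuple[int, ...]:
        return tuple(sorted(rng.choice(n_cols, size=subset_size, replace=False).tolist()))

    if n_cols == subset_size:
        only = tuple(range(n_cols))
        evaluate([only])
        return [
            _final_model(pool, only, cache[only], activities, seed, run_index, max_iter, tol)
        ]

    pop = [random_subset() for _ in range(population)]
    evaluate(pop)
    if history is not None:
        history.append(max(cache[s] for s in pop))

    for _ in range(generations):
        fitness = np.array([cache[s] for s in pop])
        elite = pop[int(np.argmax(fitness))]
        children: list[tuple[int, ...]] = [elite]
        while len(children) < population:
            # tournament selection, size 2
            parents = []
            for _ in range(2):
                a, b = rng.integers(0, population, size=2)
                parents.append(pop[a] if fitness[a] >= fitness[b] else pop[b])
            # uniform crossover with duplicate repair
            genes: list[int] = []
            for g1, g2 in zip(*parents):
                genes.append(g1 if rng.random() < 0.5 else g2)
            child = set(genes)
            union = set(parents[0]) | set(parents[1])
            spares = sorted(union - child)
            while len(child) < subset_size:
                if spares:
                    pick = spares.pop(int(rng.integers(0, len(spares))))
                else:
                    pick = int(rng.integers(0, n_cols))
                child.add(pick)
            # per-gene mutation: resample an unused column
            mutated = set(child)
            for gene in sorted(child):
                if rng.random() < mutation_rate:
                    mutated.discard(gene)
                    while len(mutated) < subset_size:
                        mutated.add(int(rng.integers(0, n_cols)))
            children.append(tuple(sorted(mutated)))
        pop = children
        evaluate(pop)
        if history is not None:
            history.append(max(cache[s] for s in pop))

    ranked = sorted(cache.items(), key=lambda kv: (-kv[1], kv[0]))[:top_k]
    return [
        _final_model(pool, subset, q2, activities, seed, run_index, max_iter, tol)
        for subset, q2 in ranked
    ]


def run_ensemble(
    pool: DescriptorPool,
    activities: ActivityTable,
    n_runs: int = 10,
    base_seed: int = 0,
    top_k: int = 10,
    **ga_kwargs,
) -> list[QsarModel]:
    """Repeat ga_select with per-run seeds; merge models, deduplicated by subset.

    When two runs find the same descriptor subset the higher-q2 model is
    kept.  Returns the merged models sorted by q2 descending (top_k of them).
    """
    if n_runs < 1:
        raise ValueError("n_runs must be >= 1")
    best: dict[tuple[int, ...], QsarModel] = {}
    for run in range(n_runs):
        models = ga_select(
            pool, activities, seed=base_seed + run, run_index=run, top_k=top_k, **ga_kwargs
        )
        for model in models:
            key = tuple(model.descriptor_indices)
            if key not in best or model.q2 > best[key].q2:
                best[key] = model
    ranked = sorted(best.values(), key=lambda m: (-m.q2, tuple(m.descriptor_indices)))
    return ranked[:top_k]


# --------------------------------------------------------------------------
# prediction
# --------------------------------------------------------------------------


def predict(model: QsarModel, similarity_row: np.ndarray) -> float:
    """Predict activity (original score scale) from the model's 4 descriptors."""
    x = np.asarray(similarity_row, dtype=float).ravel()
    if x.size != 4:
        raise ValueError("expected 4 descriptor values")
    if np.any(np.abs(x) > 1.0 + 1e-9):
        import warnings

        warnings.warn("similarity values outside [-1, 1]", stacklevel=2)
    return float(model.net.predict_activity(x)[0])


def consensus_predict(models: Sequence[QsarModel], rows: Sequence[np.ndarray]) -> float:
    """Mean of per-model predictions; rows[i] are the descriptors of models[i]."""
    if not models:
        raise ValueError("at least one model required")
    if len(rows) != len(models):
        raise ValueError("one descriptor row per model required")
    return float(np.mean([predict(m, r) for m, r in zip(models, rows)]))
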