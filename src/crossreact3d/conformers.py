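"""Conformer-cluster free-energy ranking and representative selection.

Clusters are connected components of the RMSD threshold graph.  Each cluster
is scored by a conformational free energy G = <W> - T*S, where <W> is the
Boltzmann-weighted mean effective energy over cluster members, S is the Gibbs
entropy of the member probabilities, and the conformation-independent
constant is dropped.  The representative conformer is the centre (minimum
RMSD sum to the other members) of the lowest-G cluster.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import networkx as nx
import numpy as np

__all__ = [
    "KB_KCAL",
    "ConformerEnsemble",
    "Cluster",
    "cluster_by_rmsd",
    "boltzmann_weights",
    "cluster_entropy",
    "rank_and_select",
]

#: Boltzmann constant in kcal/(mol*K).
KB_KCAL = 0.0019872041

_G_TIE_TOL = 1e-9


@dataclass
class ConformerEnsemble:
    conformer_ids: list[str]
    energies: np.ndarray  # kcal/mol, effective energy per conformer
    rmsd_matrix: np.ndarray  # Å, symmetric, zero diagonal
    temperature: float = 300.0

    def __post_init__(self) -> None:
        self.energies = np.asarray(self.energies, dtype=float)
        self.rmsd_matrix = np.asarray(self.rmsd_matrix, dtype=float)
        n = len(self.conformer_ids)
        if self.energies.shape != (n,):
            raise ValueError("energies must have one value per conformer")
        if self.rmsd_matrix.shape != (n, n):
            raise ValueError("rmsd_matrix must be square, one row per conformer")
        if not np.all(np.isfinite(self.energies)):
            raise ValueError("energies must be finite")
        if not np.allclose(self.rmsd_matrix, self.rmsd_matrix.T, atol=1e-8):
            raise ValueError("rmsd_matrix must be symmetric")
        if not np.allclose(np.diag(self.rmsd_matrix), 0.0, atol=1e-8):
            raise ValueError("rmsd_matrix diagonal must be zero")

    def __len__(self) -> int:
        return len(self.conformer_ids)


@dataclass
class Cluster:
    member_indices: list[int]
    mean_energy: float = float("nan")  # <W>, kcal/mol
    probabilities: np.ndarray = field(default_factory=lambda: np.empty(0))
    partition_function: float = float("nan")
    entropy: float = float("nan")  # kcal/(mol*K)
    free_energy: float = float("nan")  # G = <W> - T*S
    center_index: int = -1

    @property
    def size(self) -> int:
        return len(self.member_indices)


def cluster_by_rmsd(ensemble: ConformerEnsemble, threshold: float = 1.0) -> list[Cluster]:
    """Partition conformers into connected components of the RMSD graph.

    Two conformers are linked when their pairwise RMSD is <= threshold.
    Returns clusters with membership only (energetics filled by
    :func:`rank_and_select`), ordered by smallest member index.
    """
    if threshold <= 0:
        raise ValueError("threshold must be > 0")
    n = len(ensemble)
    g = nx.Graph()
    g.add_nodes_from(range(n))
    ii, jj = np.nonzero(np.triu(ensemble.rmsd_matrix <= threshold, k=1))
    g.add_edges_from(zip(ii.tolist(), jj.tolist()))
    components = sorted((sorted(c) for c in nx.connected_components(g)), key=lambda c: c[0])
    return [Cluster(member_indices=list(c)) for c in components]


def boltzmann_weights(energies: np.ndarray, temperature: float = 300.0) -> tuple[np.ndarray, float]:
    """Return (probabilities, partition function) for energies in kcal/mol.

    Energies are shifted by their minimum before exponentiation, which leaves
    the probabilities unchanged but avoids overflow; the returned partition
    function is the shifted one.
    """
    w = np.asarray(energies, dtype=float)
    if w.size == 0:
        raise ValueError("at least one energy required")
    beta = 1.0 / (KB_KCAL * temperature)
    shifted = w - w.min()
    boltz = np.exp(-beta * shifted)
    z = float(boltz.sum())
    return boltz / z, z


def cluster_entropy(probabilities: np.ndarray) -> float:
    """Gibbs entropy S = -k_B * sum(p ln p) in kcal/(mol*K); 0*ln 0 := 0."""
    p = np.asarray(probabilities, dtype=float)
    if p.size == 0:
        return 0.0
    if np.any(p < -1e-12) or abs(p.sum() - 1.0) > 1e-6:
        raise ValueError("not a probability vector")
    nz = p[p > 0]
    return float(-KB_KCAL * np.sum(nz * np.log(nz)))


def rank_and_select(
    ensemble: ConformerEnsemble, clusters: list[Cluster] | None = None, threshold: float = 1.0
) -> tuple[list[Cluster], str]:
    """Score clusters by conformational free energy; pick the representative.

    Each cluster gets within-cluster Boltzmann probabilities, <W>, S and
    G = <W> - T*S.  Clusters are returned sorted ascending in G (ties broken
    by smallest member index); the representative is the centre of the best
    cluster, i.e. the member with the smallest RMSD sum to the other members
    (lowest index on ties).  Returns (ranked clusters, representative id).
    """
    if clusters is None:
        clusters = cluster_by_rmsd(ensemble, threshold)
    covered = sorted(i for c in clusters for i in c.member_indices)
    if covered != list(range(len(ensemble))):
        raise ValueError("clusters must cover the ensemble exactly once")

    temperature = ensemble.temperature
    for cluster in clusters:
        members = np.array(cluster.member_indices)
        w = ensemble.energies[members]
        p, z = boltzmann_weights(w, temperature)
        cluster.probabilities = p
        cluster.partition_function = z
        cluster.mean_energy = float(np.dot(p, w))
        cluster.entropy = cluster_entropy(p)
        cluster.free_energy = cluster.mean_energy - temperature * cluster.entropy

        sub = ensemble.rmsd_matrix[np.ix_(members, members)]
        rmsd_sums = sub.sum(axis=1)
        cluster.center_index = int(members[int(np.argmin(rmsd_sums))])

    order = sorted(
        range(len(clusters)),
        key=lambda i: (round(clusters[i].free_energy / _G_TIE_TOL), clusters[i].member_indices[0]),
    )
    ranked = [clusters[i] for i in order]
    representative = ensemble.conformer_ids[ranked[0].center_index]
    return ranked, representative
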