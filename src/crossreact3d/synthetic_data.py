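"""Synthetic data generators with planted ground truth.

These produce superposed decapeptide-like structure sets whose pairwise shape
similarities sit in a configurable narrow high band, activities from a
planted monotone function of the shape similarity to a reference molecule
(optionally with a tied-minimal "inactive" block, mimicking real
cross-reactivity tables), conformer ensembles with a planted best cluster,
and per-clone recognition profiles.  Every generator is deterministic for a
fixed seed and returns the planted truth alongside the data, so recovery can
be scored exactly.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Callable

import numpy as np

from .activity_scoring import CloneRecognitionProfile
from .conformers import ConformerEnsemble
from .gnn_qsar import ActivityTable
from .grid_fields import build_common_grid, shape_field
from .molecular_io import Atom, Molecule
from .similarity import carbo

__all__ = [
    "SyntheticSpec",
    "SyntheticTruth",
    "generate_structure_set",
    "generate_conformer_ensemble",
    "generate_clone_profiles",
]

_BACKBONE_NAMES = ("N", "CA", "C", "O")


@dataclass
class SyntheticSpec:
    """Parameters of a planted structure-activity data set."""

    n_molecules: int = 23
    n_residues: int = 10
    atoms_per_residue: int = 7
    reference_count: int = 1
    coordinate_jitter: float = 0.3  # Å; ignored when similarity_band is set
    jitter_heterogeneity: float = 0.0  # per-molecule jitter-scale spread (fraction)
    exact_reference: bool = False  # keep reference molecule(s) at the template
    charge_jitter: float = 0.05  # e
    activity_scale: float = 60.0  # a in a*(sim^k) + b + noise
    activity_exponent: float = 8.0  # k
    activity_offset: float = -20.0  # b
    noise_sigma: float = 0.0  # score units
    n_inactive: int = 0  # size of the tied-minimal block
    similarity_band: tuple[float, float] | None = None  # target (min, max) shape sim
    grid_spacing: float = 1.0
    grid_margin: float = 3.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_molecules < 2:
            raise ValueError("n_molecules must be >= 2")
        if self.coordinate_jitter < 0 or self.charge_jitter < 0:
            raise ValueError("jitters must be >= 0")


@dataclass
class SyntheticTruth:
    """Everything needed to score recovery of the planted signal."""

    reference_ids: list[str]
    noiseless_activities: dict[str, float]
    shape_similarity_to_reference: dict[str, float]
    model_params: dict = field(default_factory=dict)
    inactive_ids: list[str] = field(default_factory=list)
    best_cluster_members: list[int] = field(default_factory=list)
    best_center_index: int = -1


def _template(n_residues: int, atoms_per_residue: int) -> tuple[np.ndarray, list[tuple[str, int]]]:
    """Extended-chain heavy-atom template: coordinates + (atom name, residue)."""
    coords: list[list[float]] = []
    names: list[tuple[str, int]] = []
    for res in range(n_residues):
        x0 = 3.0 * res
        local = [
            (0.0, 0.0, 0.0),  # N
            (1.2, 0.8, 0.0),  # CA
            (2.4, 0.0, 0.2),  # C
            (2.5, -1.2, 0.3),  # O
        ]
        # side-chain-like atoms branch off CA
        for k in range(atoms_per_residue - 4):
            local.append((1.2 + 0.3 * k, 1.8 + 1.2 * k, 0.6 * ((-1) ** k)))
        for j, (dx, dy, dz) in enumerate(local[:atoms_per_residue]):
            coords.append([x0 + dx, dy, dz])
            name = _BACKBONE_NAMES[j] if j < 4 else f"S{j - 3}"
            names.append((name, res + 1))
    return np.array(coords), names


def _make_molecules(
    spec: SyntheticSpec, jitter: float, rng: np.random.Generator
) -> list[Molecule]:
    template, names = _template(spec.n_residues, spec.atoms_per_residue)
    n_atoms = len(template)
    base_charges = 0.3 * np.sin(np.arange(n_atoms))  # fixed alternating pattern
    h = spec.jitter_heterogeneity
    if h > 0:
        factors = np.clip(rng.uniform(1.0 - h, 1.0 + h, size=spec.n_molecules), 0.05, None)
    else:
        factors = np.ones(spec.n_molecules)
    if spec.exact_reference:
        factors[: spec.reference_count] = 0.0
    molecules = []
    for m in range(spec.n_molecules):
        coords = template + rng.normal(0.0, 1.0, size=template.shape) * (jitter * factors[m])
        charges = base_charges + rng.normal(0.0, spec.charge_jitter, size=n_atoms)
        atoms = [
            Atom(
                element="C",
                name=name,
                residue_name="SYN",
                residue_index=res,
                chain_id="A",
                coords=tuple(coords[a]),
                vdw_radius=1.7,
                partial_charge=float(charges[a]),
            )
            for a, (name, res) in enumerate(names)
        ]
        molecules.append(Molecule(id=f"S{m + 1:02d}", atoms=atoms, frame_tag="synthetic"))
    return molecules


def _shape_similarity_to_ref(
    molecules: list[Molecule], ref_index: int, spacing: float, margin: float
) -> np.ndarray:
    grid = build_common_grid(molecules, margin=margin, spacing=spacing)
    fields = [shape_field(m, grid) for m in molecules]
    ref = fields[ref_index]
    return np.array([carbo(f, ref) for f in fields])


def _min_offdiag_similarity(molecules: list[Molecule], spacing: float, margin: float) -> float:
    grid = build_common_grid(molecules, margin=margin, spacing=spacing)
    fields = [shape_field(m, grid) for m in molecules]
    sims = [
        carbo(fields[i], fields[j])
        for i in range(len(fields))
        for j in range(i + 1, len(fields))
    ]
    return min(sims)


def _calibrate_jitter(spec: SyntheticSpec, target_min: float) -> float:
    """Bisect the coordinate jitter so the realized min shape similarity hits
    the band floor (similarity decreases monotonically with jitter)."""
    lo, hi = 0.01, 2.5
    for _ in range(12):
        mid = 0.5 * (lo + hi)
        rng = np.random.default_rng(spec.seed)
        mols = _make_molecules(spec, mid, rng)
        realized = _min_offdiag_similarity(mols, spec.grid_spacing, spec.grid_margin)
        if realized > target_min:
            lo = mid
        else:
            hi = mid
    return 0.5 * (lo + hi)


def generate_structure_set(
    spec: SyntheticSpec,
) -> tuple[list[Molecule], ActivityTable, SyntheticTruth]:
    """Generate a superposed structure set with a planted activity model.

    Activities are ``a * sim^k + b + noise`` where ``sim`` is each molecule's
    shape similarity (Carbo, on the generator's grid) to the reference
    molecule(s); when several references are requested their similarities are
    averaged.  The ``n_inactive`` lowest-activity molecules are floored to a
    common minimal score (rounded down), mimicking a tied inactive block.
    """
    jitter = spec.coordinate_jitter
    if spec.similarity_band is not None:
        jitter = _calibrate_jitter(spec, spec.similarity_band[0])
    rng = np.random.default_rng(spec.seed)
    molecules = _make_molecules(spec, jitter, rng)

    ref_indices = list(range(spec.reference_count))
    sims = np.mean(
        [
            _shape_similarity_to_ref(molecules, r, spec.grid_spacing, spec.grid_margin)
            for r in ref_indices
        ],
        axis=0,
    )
    noiseless = spec.activity_scale * sims**spec.activity_exponent + spec.activity_offset
    noise = rng.normal(0.0, spec.noise_sigma, size=len(molecules)) if spec.noise_sigma else 0.0
    activities = noiseless + noise

    inactive_ids: list[str] = []
    if spec.n_inactive > 0:
        order = np.argsort(activities)
        block = order[: spec.n_inactive]
        floor = float(np.floor(activities[block].max()))
        activities = activities.copy()
        activities[block] = floor
        inactive_ids = [molecules[i].id for i in block]

    table = ActivityTable(
        scores={m.id: float(a) for m, a in zip(molecules, activities)}
    )
    truth = SyntheticTruth(
        reference_ids=[molecules[r].id for r in ref_indices],
        noiseless_activities={m.id: float(a) for m, a in zip(molecules, noiseless)},
        shape_similarity_to_reference={m.id: float(s) for m, s in zip(molecules, sims)},
        model_params={
            "a": spec.activity_scale,
            "k": spec.activity_exponent,
            "b": spec.activity_offset,
            "sigma": spec.noise_sigma,
            "jitter": jitter,
        },
        inactive_ids=inactive_ids,
    )
    return molecules, table, truth


def generate_conformer_ensemble(
    n_conformers: int = 30,
    n_clusters: int = 3,
    spread: float = 0.8,
    energy_gap: float = 5.0,
    seed: int = 0,
    temperature: float = 300.0,
) -> tuple[ConformerEnsemble, SyntheticTruth]:
    """Conformer ensemble with a planted tight low-energy cluster.

    Conformers are embedded as 3D points; cluster centres sit far apart
    (>> spread) and members are jittered within spread/3, so the RMSD matrix
    (Euclidean distances between embeddings, a valid metric) has
    within-cluster values < spread < between-cluster values.  Cluster 0 is
    the planted winner: its members' energies are lower by *energy_gap*.
    """
    if n_clusters < 1:
        raise ValueError("n_clusters must be >= 1")
    rng = np.random.default_rng(seed)
    sizes = np.full(n_clusters, n_conformers // n_clusters)
    sizes[: n_conformers % n_clusters] += 1
    centers = 20.0 * spread * np.arange(n_clusters)[:, None] * np.array([[1.0, 0.0, 0.0]])
    points = []
    labels = []
    for c in range(n_clusters):
        pts = centers[c] + rng.normal(0.0, spread / 3.0, size=(sizes[c], 3))
        points.append(pts)
        labels.extend([c] * sizes[c])
    points = np.vstack(points)
    labels = np.array(labels)

    diff = points[:, None, :] - points[None, :, :]
    rmsd_matrix = np.sqrt((diff**2).sum(axis=2))

    energies = rng.normal(0.0, 0.5, size=n_conformers)
    energies[labels == 0] -= energy_gap

    ids = [f"c{i}" for i in range(n_conformers)]
    ensemble = ConformerEnsemble(
        conformer_ids=ids,
        energies=energies,
        rmsd_matrix=rmsd_matrix,
        temperature=temperature,
    )

    best_members = np.nonzero(labels == 0)[0]
    sub = rmsd_matrix[np.ix_(best_members, best_members)]
    center = int(best_members[int(np.argmin(sub.sum(axis=1)))])
    truth = SyntheticTruth(
        reference_ids=[],
        noiseless_activities={},
        shape_similarity_to_reference={},
        best_cluster_members=best_members.tolist(),
        best_center_index=center,
    )
    return ensemble, truth


def generate_clone_profiles(
    n_peptides: int = 10,
    n_clones: int = 17,
    activity_link: Callable[[int], float] | None = None,
    seed: int = 0,
) -> tuple[list[CloneRecognitionProfile], dict[str, int]]:
    """Per-clone lysis profiles with known category sums.

    ``activity_link`` maps a peptide index to a recognition propensity in
    [0, 1] (default: linear ramp); each clone's category is drawn from that
    propensity and converted to a lysis percentage lying strictly inside the
    category's band.  Returns (profiles, expected cross-reactivity scores).
    """
    if activity_link is None:
        activity_link = lambda i: i / max(n_peptides - 1, 1)  # noqa: E731
    rng = np.random.default_rng(seed)
    # representative lysis for each category, strictly inside its band
    lysis_bands = {-1: (0.0, 10.0), 1: (10.5, 20.0), 2: (20.5, 40.0), 3: (40.5, 60.0), 4: (60.5, 100.0)}
    profiles = []
    expected: dict[str, int] = {}
    for p in range(n_peptides):
        propensity = float(np.clip(activity_link(p), 0.0, 1.0))
        entries: dict[str, float] = {}
        score = 0
        for c in range(n_clones):
            if rng.random() < propensity:
                category = int(rng.integers(1, 5))
            else:
                category = -1
            lo, hi = lysis_bands[category]
            entries[f"clone{c + 1}"] = float(rng.uniform(lo, hi))
            score += category
        pid = f"P{p + 1:02d}"
        profiles.append(
            CloneRecognitionProfile(peptide_id=pid, entries=entries, n_clones=n_clones)
        )
        expected[pid] = score
    return profiles, expected
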