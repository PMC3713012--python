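"""Field similarity indices and the double similarity matrix.

Electrostatic similarity uses the Hodgkin index,
``2*sum(PA*PB) / (sum(PA^2) + sum(PB^2))``; shape similarity uses the Carbo
index, ``sum(PA*PB) / sqrt(sum(PA^2)*sum(PB^2))``, which for binary fields
equals ``U_AB / sqrt(T_A*T_B)`` with U_AB the shared interior count and
T_A, T_B the interior counts.  The Meyer form ``2*U_AB/(T_A+T_B)`` is
available for binary fields as well.  Sums run over all grid points.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

from .grid_fields import ScalarField

__all__ = [
    "SimilarityMatrix",
    "hodgkin",
    "carbo",
    "meyer",
    "build_similarity_matrix",
]


def _check_grids(pa: ScalarField, pb: ScalarField) -> tuple[np.ndarray, np.ndarray]:
    if pa.grid != pb.grid:
        raise ValueError("fields must share an identical GridSpec")
    return np.asarray(pa.values, dtype=float), np.asarray(pb.values, dtype=float)


def hodgkin(pa: ScalarField, pb: ScalarField) -> float:
    """Hodgkin similarity; 1 when both fields are identically zero."""
    a, b = _check_grids(pa, pb)
    denom = float(a @ a + b @ b)
    if denom == 0.0:
        return 1.0
    return float(2.0 * (a @ b) / denom)


def carbo(pa: ScalarField, pb: ScalarField) -> float:
    """Carbo similarity; 1 when both fields are identically zero, 0 if one is."""
    a, b = _check_grids(pa, pb)
    na2 = float(a @ a)
    nb2 = float(b @ b)
    if na2 == 0.0 and nb2 == 0.0:
        return 1.0
    if na2 == 0.0 or nb2 == 0.0:
        return 0.0
    return float((a @ b) / np.sqrt(na2 * nb2))


def meyer(pa: ScalarField, pb: ScalarField) -> float:
    """Meyer overlap index 2*U_AB/(T_A+T_B) for binary fields."""
    a, b = _check_grids(pa, pb)
    if not (set(np.unique(a)) <= {0.0, 1.0} and set(np.unique(b)) <= {0.0, 1.0}):
        raise ValueError("Meyer index requires binary (0/1) fields")
    ta, tb = float(a.sum()), float(b.sum())
    if ta + tb == 0.0:
        return 1.0
    return float(2.0 * (a @ b) / (ta + tb))


@dataclass
class SimilarityMatrix:
    """Per-field molecule-by-molecule similarity tables (the double matrix)."""

    molecule_ids: list[str]
    shape: np.ndarray
    electrostatic: np.ndarray

    def __post_init__(self) -> None:
        n = len(self.molecule_ids)
        self.shape = np.asarray(self.shape, dtype=float)
        self.electrostatic = np.asarray(self.electrostatic, dtype=float)
        for name, m in (("shape", self.shape), ("electrostatic", self.electrostatic)):
            if m.shape != (n, n):
                raise ValueError(f"{name} matrix must be {n}x{n}")
            if not np.allclose(m, m.T, atol=1e-10):
                raise ValueError(f"{name} matrix must be symmetric")

    def to_frames(self) -> tuple[pd.DataFrame, pd.DataFrame]:
        ids = self.molecule_ids
        return (
            pd.DataFrame(self.shape, index=ids, columns=ids),
            pd.DataFrame(self.electrostatic, index=ids, columns=ids),
        )

    def write_csv(self, shape_path: str | Path, elec_path: str | Path) -> None:
        shape_df, elec_df = self.to_frames()
        shape_df.to_csv(shape_path)
        elec_df.to_csv(elec_path)

    @classmethod
    def read_csv(cls, shape_path: str | Path, elec_path: str | Path) -> "SimilarityMatrix":
        shape_df = pd.read_csv(shape_path, index_col=0)
        elec_df = pd.read_csv(elec_path, index_col=0)
        ids = [str(c) for c in shape_df.columns]
        if [str(c) for c in elec_df.columns] != ids:
            raise ValueError("shape and electrostatic CSVs list different molecules")
        return cls(molecule_ids=ids, shape=shape_df.to_numpy(), electrostatic=elec_df.to_numpy())


def build_similarity_matrix(
    fields_by_molecule: dict[str, dict[str, ScalarField]],
    shape_index: str = "carbo",
) -> SimilarityMatrix:
    """Assemble the double similarity matrix from per-molecule fields.

    ``fields_by_molecule`` maps molecule id -> {"shape": field,
    "electrostatic": field}, all on one shared grid.  Shape entries use the
    Carbo index by default (``shape_index="meyer"`` switches to the Meyer
    form); electrostatic entries use the Hodgkin index.
    """
    ids = list(fields_by_molecule)
    for mol_id in ids:
        fields = fields_by_molecule[mol_id]
        for kind in ("shape", "electrostatic"):
            if kind not in fields:
                raise ValueError(f"molecule {mol_id!r} is missing its {kind} field")
    shape_fn = {"carbo": carbo, "meyer": meyer}[shape_index]
    n = len(ids)
    shape = np.eye(n)
    elec = np.eye(n)
    for i in range(n):
        fi = fields_by_molecule[ids[i]]
        for j in range(i, n):
            fj = fields_by_molecule[ids[j]]
            shape[i, j] = shape[j, i] = shape_fn(fi["shape"], fj["shape"])
            elec[i, j] = elec[j, i] = hodgkin(fi["electrostatic"], fj["electrostatic"])
    return SimilarityMatrix(molecule_ids=ids, shape=shape, electrostatic=elec)
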