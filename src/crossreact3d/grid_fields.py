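"""Shared-grid construction and molecular field evaluation.

A single axis-aligned grid (0.5 Å spacing by default, extended at least 6 Å
beyond every atom of the data set) is shared by all molecules of one
analysis.  Two fields are evaluated per molecule on that grid:

* a binary *shape* field: 1 inside the van der Waals surface, 0 outside;
* an *electrostatic* field for a unit positive probe with a
  distance-dependent dielectric (eps = 4r, so the energy denominator is
  4*d**2), zeroed inside the molecule's own vdW surface and truncated to
  +/- 5 kcal/mol.

Values are stored flattened with x varying fastest, then y, then z; the grid
origin is the minimum corner.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np

from .molecular_io import Molecule

__all__ = [
    "COULOMB_K",
    "GridSpec",
    "ScalarField",
    "build_common_grid",
    "shape_field",
    "electrostatic_field",
    "field_stats",
    "write_dx",
]

#: Coulomb constant in kcal*Å/(mol*e^2) (CHARMM convention).
COULOMB_K = 332.0716


@dataclass(frozen=True)
class GridSpec:
    """Regular 3D grid: origin at the minimum corner, uniform spacing."""

    origin: tuple[float, float, float]
    spacing: float
    dims: tuple[int, int, int]

    def __post_init__(self) -> None:
        if self.spacing <= 0:
            raise ValueError("spacing must be > 0")
        if any(d < 2 for d in self.dims):
            raise ValueError("each grid dimension must be >= 2")

    @property
    def n_points(self) -> int:
        nx, ny, nz = self.dims
        return nx * ny * nz

    def points(self) -> np.ndarray:
        """All grid points as an (n_points, 3) array, x fastest."""
        nx, ny, nz = self.dims
        ox, oy, oz = self.origin
        x = ox + self.spacing * np.arange(nx)
        y = oy + self.spacing * np.arange(ny)
        z = oz + self.spacing * np.arange(nz)
        zz, yy, xx = np.meshgrid(z, y, x, indexing="ij")
        return np.column_stack([xx.ravel(), yy.ravel(), zz.ravel()])


@dataclass
class ScalarField:
    grid: GridSpec
    kind: str  # "shape" | "electrostatic"
    values: np.ndarray  # flat, length n_points

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float).ravel()
        if self.values.size != self.grid.n_points:
            raise ValueError(
                f"value count {self.values.size} != grid points {self.grid.n_points}"
            )
        if self.kind not in ("shape", "electrostatic"):
            raise ValueError(f"unknown field kind {self.kind!r}")


def build_common_grid(
    mols: Sequence[Molecule], margin: float = 6.0, spacing: float = 0.5
) -> GridSpec:
    """Bounding grid covering every atom of every molecule plus *margin* Å.

    The box faces are snapped outward to integer multiples of *spacing* so
    they are at least *margin* from every atomic coordinate.
    """
    coords = [m.coordinates() for m in mols if len(m)]
    if not coords:
        raise ValueError("at least one molecule with atoms is required")
    all_xyz = np.vstack(coords)
    lo = np.floor((all_xyz.min(axis=0) - margin) / spacing) * spacing
    hi = np.ceil((all_xyz.max(axis=0) + margin) / spacing) * spacing
    dims = tuple(int(np.rint((h - l) / spacing)) + 1 for l, h in zip(lo, hi))
    return GridSpec(origin=tuple(float(v) for v in lo), spacing=spacing, dims=dims)


def _occupancy(mol: Molecule, grid: GridSpec) -> np.ndarray:
    """Boolean mask of grid points inside any atom's vdW sphere (closed)."""
    n = grid.n_points
    if len(mol) == 0:
        return np.zeros(n, dtype=bool)
    points = grid.points()
    centers = mol.coordinates()
    radii = mol.radii()
    inside = np.zeros(n, dtype=bool)
    # chunk over atoms: distance matrix n_points x n_atoms can be large
    for start in range(0, len(centers), 64):
        c = centers[start : start + 64]
        r = radii[start : start + 64]
        d2 = ((points[:, None, :] - c[None, :, :]) ** 2).sum(axis=2)
        inside |= (d2 <= r**2).any(axis=1)
    return inside


def shape_field(mol: Molecule, grid: GridSpec) -> ScalarField:
    """Binary occupancy of the molecule's van der Waals volume."""
    return ScalarField(grid=grid, kind="shape", values=_occupancy(mol, grid).astype(float))


def electrostatic_field(
    mol: Molecule, grid: GridSpec, clamp: float | None = 5.0
) -> ScalarField:
    """Probe energy of a unit positive charge, eps = 4r, on the shared grid.

    E(p) = sum_i K * q_i / (4 * d_i(p)^2) for points outside the molecule's
    vdW surface; points inside any of the molecule's vdW spheres are set to
    exactly 0 (which also removes the r -> 0 singularity).  Pass
    ``clamp=None`` to skip truncation (used for pre-truncation statistics).
    """
    n = grid.n_points
    if len(mol) == 0:
        return ScalarField(grid=grid, kind="electrostatic", values=np.zeros(n))
    points = grid.points()
    centers = mol.coordinates()
    radii = mol.radii()
    charges = mol.charges()
    energy = np.zeros(n)
    inside = np.zeros(n, dtype=bool)
    for start in range(0, len(centers), 64):
        c = centers[start : start + 64]
        r = radii[start : start + 64]
        q = charges[start : start + 64]
        d2 = ((points[:, None, :] - c[None, :, :]) ** 2).sum(axis=2)
        inside |= (d2 <= r**2).any(axis=1)
        with np.errstate(divide="ignore", invalid="ignore"):
            contrib = COULOMB_K * q[None, :] / (4.0 * d2)
            energy += np.nan_to_num(contrib, nan=0.0, posinf=0.0, neginf=0.0).sum(axis=1)
    energy[inside] = 0.0
    if clamp is not None:
        np.clip(energy, -clamp, clamp, out=energy)
    return ScalarField(grid=grid, kind="electrostatic", values=energy)


def field_stats(fields: Iterable[ScalarField], window: float = 5.0) -> dict:
    """Pooled distribution summary of (pre-truncation) field values.

    Returns the fraction of values with |E| <= window, min, max and a
    histogram over all grid points of all fields.
    """
    values = np.concatenate([np.asarray(f.values) for f in fields])
    if values.size == 0:
        raise ValueError("no field values")
    in_range = np.abs(values) <= window
    hist, edges = np.histogram(values, bins=50)
    return {
        "fraction_in_range": float(in_range.mean()),
        "window": window,
        "min": float(values.min()),
        "max": float(values.max()),
        "n_values": int(values.size),
        "histogram": hist.tolist(),
        "bin_edges": edges.tolist(),
    }


def write_dx(field: ScalarField, path: str | Path) -> None:
    """Export a field in OpenDX scalar-grid format."""
    g = field.grid
    nx, ny, nz = g.dims
    # DX wants z fastest; our storage is x fastest
    vals = field.values.reshape(nz, ny, nx).transpose(2, 1, 0).ravel()
    lines = [
        f"object 1 class gridpositions counts {nx} {ny} {nz}",
        f"origin {g.origin[0]:.6f} {g.origin[1]:.6f} {g.origin[2]:.6f}",
        f"delta {g.spacing:.6f} 0 0",
        f"delta 0 {g.spacing:.6f} 0",
        f"delta 0 0 {g.spacing:.6f}",
        f"object 2 class gridconnections counts {nx} {ny} {nz}",
        f"object 3 class array type double rank 0 items {vals.size} data follows",
    ]
    for start in range(0, vals.size, 3):
        lines.append(" ".join(f"{v:.6e}" for v in vals[start : start + 3]))
    lines.append('attribute "dep" string "positions"')
    Path(path).write_text("\n".join(lines) + "\n")
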