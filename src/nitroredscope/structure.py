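"""Solvent-accessible surface area, buried dimer interface, CPK volume.

Nitroreductase-family enzymes are obligate homodimers with unusually large,
intertwined monomer-monomer interfaces.  The interface size is quantified
from per-chain solvent-accessible surface areas (ASA) as

    buried ASA = (ASA(A) + ASA(B) - ASA(AB)) / 2

i.e. the area of one monomer's surface removed from solvent on dimer
formation, and as the buried fraction 100 * buried / ASA(A).

ASA is computed by deterministic sphere-point sampling: each atom's van der
Waals sphere is expanded by the probe radius (1.4 A water probe), a
Fibonacci lattice of test points is placed on the expanded sphere, and
points inside any neighbor's expanded sphere are discarded.  The point set
is a fixed lattice (no RNG), so results are bit-stable across runs.

CPK molecular volume — the volume of the union of van der Waals spheres —
is computed by grid integration over the bounding box.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
from scipy.spatial import cKDTree

__all__ = [
    "VDW_RADII",
    "DEFAULT_RADIUS",
    "AtomRecord",
    "StructureModel",
    "InterfaceReport",
    "read_structure",
    "sasa",
    "buried_interface",
    "cpk_volume",
    "write_pdb",
]

#: Per-element van der Waals radii (A).
VDW_RADII: dict[str, float] = {
    "H": 1.2, "C": 1.7, "N": 1.55, "O": 1.52, "S": 1.8,
    "P": 1.8, "F": 1.47, "CL": 1.75, "BR": 1.85, "I": 1.98,
    "SE": 1.9, "FE": 1.4, "ZN": 1.39, "MG": 1.73, "CA": 1.4,
    "NA": 2.27, "K": 2.75, "MN": 1.4,
}

#: Fallback radius (A) for elements absent from the table.
DEFAULT_RADIUS = 1.8


@dataclass(frozen=True)
class AtomRecord:
    """One atom: element, chain, residue bookkeeping, coordinates (A) and
    van der Waals radius (A)."""

    element: str
    chain_id: str
    res_name: str
    res_seq: int
    atom_name: str
    x: float
    y: float
    z: float
    radius: float

    def __post_init__(self) -> None:
        if self.radius <= 0:
            raise ValueError("vdW radius must be positive")
        if not all(math.isfinite(c) for c in (self.x, self.y, self.z)):
            raise ValueError("coordinates must be finite")


class StructureModel:
    """A set of atoms with chain identifiers.

    Thin container over a list of :class:`AtomRecord`; provides numpy views
    of coordinates and radii and chain-wise subsetting.
    """

    def __init__(self, atoms: Sequence[AtomRecord]):
        self.atoms: list[AtomRecord] = list(atoms)

    def __len__(self) -> int:
        return len(self.atoms)

    @property
    def chains(self) -> set[str]:
        return {a.chain_id for a in self.atoms}

    def coords(self) -> np.ndarray:
        return np.array([[a.x, a.y, a.z] for a in self.atoms], dtype=float)

    def radii(self) -> np.ndarray:
        return np.array([a.radius for a in self.atoms], dtype=float)

    def subset(self, chain_ids: str | Sequence[str]) -> "StructureModel":
        if isinstance(chain_ids, str):
            chain_ids = [chain_ids]
        wanted = set(chain_ids)
        sub = StructureModel([a for a in self.atoms if a.chain_id in wanted])
        if not sub.atoms:
            raise ValueError(f"no atoms in chain(s) {sorted(wanted)}")
        return sub

    def translated(self, offset: Sequence[float], chain_ids: Sequence[str] | None = None) -> "StructureModel":
        """Copy with selected chains (default: all) rigidly translated."""
        dx, dy, dz = offset
        wanted = set(chain_ids) if chain_ids is not None else None
        out = []
        for a in self.atoms:
            if wanted is None or a.chain_id in wanted:
                out.append(AtomRecord(a.element, a.chain_id, a.res_name, a.res_seq,
                                      a.atom_name, a.x + dx, a.y + dy, a.z + dz, a.radius))
            else:
                out.append(a)
        return StructureModel(out)


@dataclass
class InterfaceReport:
    """Per-chain ASA, complex ASA, buried interface area and buried fraction."""

    asa_A: float
    asa_B: float
    asa_AB: float
    buried: float
    buried_fraction_A: float
    probe_radius: float
    n_sphere_points: int

    @classmethod
    def from_areas(
        cls, asa_A: float, asa_B: float, asa_AB: float,
        probe_radius: float = 1.4, n_sphere_points: int = 960,
    ) -> "InterfaceReport":
        """Apply buried = (ASA(A) + ASA(B) - ASA(AB))/2 and
        buried_fraction_A = 100 * buried / ASA(A)."""
        buried = (asa_A + asa_B - asa_AB) / 2.0
        return cls(
            asa_A=asa_A, asa_B=asa_B, asa_AB=asa_AB, buried=buried,
            buried_fraction_A=100.0 * buried / asa_A,
            probe_radius=probe_radius, n_sphere_points=n_sphere_points,
        )


# ---------------------------------------------------------------------------
# structure reading (gemmi behind the scenes)
# ---------------------------------------------------------------------------

def radius_for_element(element: str) -> float:
    """vdW radius for an element symbol; warns and falls back for unknowns."""
    r = VDW_RADII.get(element.upper())
    if r is None:
        warnings.warn(
            f"unknown element {element!r}; using fallback radius {DEFAULT_RADIUS} A",
            stacklevel=2,
        )
        return DEFAULT_RADIUS
    return r


def read_structure(
    path: str | Path,
    include_hetero: bool = False,
    include_hydrogens: bool = False,
    include_waters: bool = False,
) -> StructureModel:
    """Read a PDB or mmCIF file into a :class:`StructureModel`.

    Only the first model is used.  For atoms with alternate locations, the
    highest-occupancy conformer is kept.  Waters and hetero (non-polymer)
    residues are excluded by default, as are hydrogens (the crystal
    structures of interest lack them).
    """
    import gemmi

    st = gemmi.read_structure(str(path))
    if len(st) == 0:
        raise ValueError(f"{path}: no models in structure")
    model = st[0]
    # keep highest-occupancy altloc per (chain, residue, atom name)
    best: dict[tuple, tuple[float, AtomRecord]] = {}
    order: list[tuple] = []
    for chain in model:
        for residue in chain:
            if residue.is_water() and not include_waters:
                continue
            if residue.het_flag == "H" and not residue.is_water() and not include_hetero:
                continue
            for atom in residue:
                el = atom.element.name
                if el.upper() == "H" and not include_hydrogens:
                    continue
                key = (chain.name, residue.seqid.num, residue.name, atom.name)
                rec = AtomRecord(
                    element=el, chain_id=chain.name, res_name=residue.name,
                    res_seq=residue.seqid.num, atom_name=atom.name,
                    x=atom.pos.x, y=atom.pos.y, z=atom.pos.z,
                    radius=radius_for_element(el),
                )
                occ = atom.occ if atom.occ is not None else 1.0
                if key not in best:
                    best[key] = (occ, rec)
                    order.append(key)
                elif occ > best[key][0]:
                    best[key] = (occ, rec)
    atoms = [best[k][1] for k in order]
    if not atoms:
        raise ValueError(f"{path}: no usable ATOM records")
    return StructureModel(atoms)


# ---------------------------------------------------------------------------
# solvent-accessible surface area
# ---------------------------------------------------------------------------

def _fibonacci_sphere(n: int) -> np.ndarray:
    """Deterministic near-uniform unit-sphere lattice of n points."""
    i = np.arange(n, dtype=float) + 0.5
    phi = math.pi * (3.0 - math.sqrt(5.0)) * i  # golden-angle increments
    z = 1.0 - 2.0 * i / n
    r = np.sqrt(np.clip(1.0 - z * z, 0.0, None))
    return np.column_stack([r * np.cos(phi), r * np.sin(phi), z])


def sasa(
    model: StructureModel,
    probe: float = 1.4,
    n_points: int = 960,
) -> tuple[np.ndarray, float]:
    """Solvent-accessible surface area by deterministic sphere sampling.

    Returns (per-atom ASA array, total ASA) in A^2.  Each atom contributes
    4*pi*(r+probe)^2 times the fraction of its lattice points not occluded
    by any neighbor's expanded sphere.
    """
    if probe <= 0:
        raise ValueError("probe radius must be positive")
    if n_points <= 0:
        raise ValueError("n_points must be positive")
    if len(model) == 0:
        raise ValueError("model has no atoms")
    xyz = model.coords()
    rad = model.radii() + probe
    unit = _fibonacci_sphere(n_points)
    tree = cKDTree(xyz)
    rmax = rad.max()
    areas = np.empty(len(model))
    for i in range(len(model)):
        ri = rad[i]
        pts = xyz[i] + ri * unit
        neighbors = [j for j in tree.query_ball_point(xyz[i], ri + rmax) if j != i]
        accessible = np.ones(n_points, dtype=bool)
        for j in neighbors:
            d2 = np.sum((pts - xyz[j]) ** 2, axis=1)
            accessible &= d2 > rad[j] ** 2
            if not accessible.any():
                break
        areas[i] = 4.0 * math.pi * ri * ri * accessible.mean()
    return areas, float(areas.sum())


def buried_interface(
    model: StructureModel,
    chain_A: str,
    chain_B: str,
    probe: float = 1.4,
    n_points: int = 960,
) -> InterfaceReport:
    """Buried dimer-interface area between two chains.

    Computes ASA of chain A alone, chain B alone and the AB complex, then
    buried = (ASA(A) + ASA(B) - ASA(AB)) / 2 and the percent of chain A's
    surface buried on dimerization.
    """
    sub_a = model.subset(chain_A)
    sub_b = model.subset(chain_B)
    complex_ab = StructureModel(sub_a.atoms + sub_b.atoms)
    _, asa_a = sasa(sub_a, probe, n_points)
    _, asa_b = sasa(sub_b, probe, n_points)
    _, asa_ab = sasa(complex_ab, probe, n_points)
    report = InterfaceReport.from_areas(asa_a, asa_b, asa_ab, probe, n_points)
    return report


# ---------------------------------------------------------------------------
# CPK molecular volume
# ---------------------------------------------------------------------------

def cpk_volume(model: StructureModel, grid_spacing: float = 0.2) -> float:
    """Volume (A^3) of the union of van der Waals spheres by grid integration.

    A regular grid at ``grid_spacing`` covers the bounding box; a voxel
    counts as occupied if its center lies inside any sphere.
    """
    if grid_spacing <= 0:
        raise ValueError("grid_spacing must be positive")
    if len(model) == 0:
        raise ValueError("model has no atoms")
    xyz = model.coords()
    rad = model.radii()
    lo = (xyz - rad[:, None]).min(axis=0) - grid_spacing
    hi = (xyz + rad[:, None]).max(axis=0) + grid_spacing
    axes = [np.arange(lo[k] + grid_spacing / 2, hi[k], grid_spacing) for k in range(3)]
    nx, ny, nz = (len(a) for a in axes)
    occupied = np.zeros((nx, ny, nz), dtype=bool)
    for c, r in zip(xyz, rad):
        idx = []
        for k in range(3):
            sel = np.nonzero(np.abs(axes[k] - c[k]) <= r)[0]
            if sel.size == 0:
                break
            idx.append(sel)
        else:
            gx, gy, gz = np.meshgrid(axes[0][idx[0]], axes[1][idx[1]], axes[2][idx[2]],
                                     indexing="ij")
            inside = (gx - c[0]) ** 2 + (gy - c[1]) ** 2 + (gz - c[2]) ** 2 <= r * r
            occupied[np.ix_(idx[0], idx[1], idx[2])] |= inside
    return float(occupied.sum()) * grid_spacing**3


# ---------------------------------------------------------------------------
# PDB writing (for synthetic fixtures and CLI round-trips)
# ---------------------------------------------------------------------------

def write_pdb(model: StructureModel, path: str | Path) -> None:
    """Write a minimal, valid PDB file (ATOM records + TER/END)."""
    lines = []
    serial = 0
    last_chain = None
    for a in model.atoms:
        if last_chain is not None and a.chain_id != last_chain:
            lines.append("TER")
        last_chain = a.chain_id
        serial += 1
        name = a.atom_name if len(a.atom_name) >= 4 else f" {a.atom_name:<3s}"
        lines.append(
            f"ATOM  {serial:5d} {name:<4s} {a.res_name:<3s} {a.chain_id:1s}"
            f"{a.res_seq:4d}    {a.x:8.3f}{a.y:8.3f}{a.z:8.3f}"
            f"{1.0:6.2f}{0.0:6.2f}          {a.element:>2s}"
        )
    lines += ["TER", "END", ""]
    Path(path).write_text("\n".join(lines))
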