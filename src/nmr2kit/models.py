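"""Structural models shared by the engine, simulator and file I/O."""

from __future__ import annotations

from dataclasses import dataclass, replace
from typing import Mapping

import numpy as np

__all__ = ["MethylGroup", "ReceptorModel", "LigandProtonGroup", "Torsion", "LigandModel"]


@dataclass(frozen=True)
class MethylGroup:
    """A receptor methyl group represented by its pseudoatom.

    The pseudoatom sits at the mean of the three methyl proton
    positions (or at the methyl carbon when no protons are present).
    """

    id: str
    residue_number: int
    residue_name: str
    atom_name: str
    residue_class: str  # Ala | Thr | Met | ILV
    coord: tuple[float, float, float]

    @property
    def xyz(self) -> np.ndarray:
        return np.asarray(self.coord, dtype=float)


@dataclass(frozen=True)
class ReceptorModel:
    """Receptor structure with its methyl-group inventory."""

    elements: tuple[str, ...]
    atom_names: tuple[str, ...]
    residue_numbers: tuple[int, ...]
    residue_names: tuple[str, ...]
    coords: np.ndarray  # (n_atoms, 3), Angstrom
    methyl_groups: tuple[MethylGroup, ...]
    pocket_center: tuple[float, float, float] = (0.0, 0.0, 0.0)
    flexible_sidechain_residues: tuple[int, ...] = ()

    def __post_init__(self) -> None:
        coords = np.asarray(self.coords, dtype=float)
        if coords.ndim != 2 or coords.shape[1] != 3:
            raise ValueError("coords must be (n_atoms, 3)")
        if not np.all(np.isfinite(coords)):
            raise ValueError("receptor coordinates must be finite")
        object.__setattr__(self, "coords", coords)

    @property
    def n_atoms(self) -> int:
        return self.coords.shape[0]

    @property
    def methyl_by_id(self) -> Mapping[str, MethylGroup]:
        return {m.id: m for m in self.methyl_groups}

    @property
    def methyl_coords(self) -> np.ndarray:
        return np.array([m.coord for m in self.methyl_groups], dtype=float)

    def with_coords(self, coords: np.ndarray, methyl_coords: np.ndarray) -> "ReceptorModel":
        methyls = tuple(
            replace(m, coord=tuple(float(v) for v in xyz))
            for m, xyz in zip(self.methyl_groups, methyl_coords)
        )
        return replace(self, coords=np.asarray(coords, dtype=float), methyl_groups=methyls)


@dataclass(frozen=True)
class LigandProtonGroup:
    """A ligand proton group mapped to the atoms that carry it."""

    id: str
    atom_indices: tuple[int, ...]
    multiplicity: int = 1


@dataclass(frozen=True)
class Torsion:
    """A rotatable bond: axis from atom i to atom j; ``moving`` atoms rotate."""

    atom_i: int
    atom_j: int
    moving: tuple[int, ...]


@dataclass(frozen=True)
class LigandModel:
    """Ligand reference conformer with proton groups and rotatable torsions."""

    atom_names: tuple[str, ...]
    elements: tuple[str, ...]
    coords: np.ndarray  # reference conformer, (n_atoms, 3)
    proton_groups: tuple[LigandProtonGroup, ...] = ()
    torsions: tuple[Torsion, ...] = ()
    residue_name: str = "LIG"

    def __post_init__(self) -> None:
        coords = np.asarray(self.coords, dtype=float)
        if coords.ndim != 2 or coords.shape[1] != 3:
            raise ValueError("coords must be (n_atoms, 3)")
        object.__setattr__(self, "coords", coords)
        n = coords.shape[0]
        for g in self.proton_groups:
            if any(i >= n or i < 0 for i in g.atom_indices):
                raise ValueError(f"proton group {g.id} references out-of-range atoms")

    @property
    def n_atoms(self) -> int:
        return self.coords.shape[0]

    @property
    def group_by_id(self) -> Mapping[str, LigandProtonGroup]:
        return {g.id: g for g in self.proton_groups}

    @property
    def heavy_atom_indices(self) -> np.ndarray:
        return np.array([i for i, e in enumerate(self.elements) if e != "H"], dtype=int)

    def group_coords(self, atom_coords: np.ndarray | None = None) -> np.ndarray:
        """Per-group coordinates: mean over member atoms, (n_groups, 3)."""
        xyz = self.coords if atom_coords is None else np.asarray(atom_coords, dtype=float)
        return np.array([xyz[list(g.atom_indices)].mean(axis=0) for g in self.proton_groups])
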