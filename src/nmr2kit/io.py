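"""File formats: PDB structures, CYANA-dialect restraint lists, run configs."""

from __future__ import annotations

import hashlib
import json
from dataclasses import asdict, dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import yaml

import biotite.structure as struc
from biotite.structure.io.pdb import PDBFile

from .models import LigandModel, LigandProtonGroup, MethylGroup, ReceptorModel
from .restraints import RESIDUE_TO_CLASS, DistanceRestraint

__all__ = [
    "METHYL_TEMPLATES",
    "read_receptor_pdb",
    "write_receptor_pdb",
    "read_ligand_pdb",
    "write_ligand_pdb",
    "write_restraints",
    "read_restraints",
    "RunConfig",
    "load_config",
    "config_hash",
]

#: (residue name, carbon name) pairs recognised as methyl groups.
METHYL_TEMPLATES = {
    ("ALA", "CB"),
    ("THR", "CG2"),
    ("VAL", "CG1"),
    ("VAL", "CG2"),
    ("LEU", "CD1"),
    ("LEU", "CD2"),
    ("ILE", "CD1"),
    ("ILE", "CG2"),
    ("MET", "CE"),
}


def _methyl_proton_prefix(carbon_name: str) -> str:
    # CB -> HB, CG2 -> HG2, CD1 -> HD1, CE -> HE
    return "H" + carbon_name[1:]


def read_receptor_pdb(
    path,
    pocket_center: Sequence[float] | None = None,
    pocket_radius: float | None = None,
) -> ReceptorModel:
    """Read a receptor PDB and detect its methyl groups.

    Methyls are found from residue/atom-name templates (Ala CB, Thr CG2,
    Val CG1/CG2, Leu CD1/CD2, Ile CD1/CG2, Met CE).  The pseudoatom
    coordinate is the mean of the three methyl protons when present,
    otherwise the carbon position.  Altlocs resolve to the first
    occurrence; only the first model is used.  When ``pocket_center``
    and ``pocket_radius`` are given, only methyls within the radius are
    registered (binding-site focus).
    """
    path = Path(path)
    try:
        pdb = PDBFile.read(str(path))
        atoms = pdb.get_structure(model=1, altloc="first")
    except Exception as exc:  # biotite raises several parse error types
        raise ValueError(f"failed to parse PDB {path}: {exc}") from exc

    methyls: list[MethylGroup] = []
    for i in range(atoms.array_length()):
        key = (str(atoms.res_name[i]), str(atoms.atom_name[i]))
        if key not in METHYL_TEMPLATES:
            continue
        resnum = int(atoms.res_id[i])
        chain = str(atoms.chain_id[i])
        prefix = _methyl_proton_prefix(key[1])
        same_res = (
            (atoms.res_id == atoms.res_id[i])
            & (atoms.chain_id == atoms.chain_id[i])
            & (atoms.res_name == atoms.res_name[i])
        )
        proton_names = [n for n in np.asarray(atoms.atom_name[same_res]) if str(n).startswith(prefix)]
        if len(proton_names) == 3:
            mask = same_res & np.isin(atoms.atom_name, proton_names)
            coord = atoms.coord[mask].mean(axis=0)
        else:
            coord = atoms.coord[i]
        if pocket_center is not None and pocket_radius is not None:
            if np.linalg.norm(coord - np.asarray(pocket_center, float)) > pocket_radius:
                continue
        methyls.append(
            MethylGroup(
                id=f"{key[0]}{resnum}:{key[1]}",
                residue_number=resnum,
                residue_name=key[0],
                atom_name=key[1],
                residue_class=RESIDUE_TO_CLASS[key[0]],
                coord=tuple(float(v) for v in coord),
            )
        )
    if not methyls:
        raise ValueError(f"no methyl groups found in {path}")
    center = (
        tuple(float(v) for v in pocket_center)
        if pocket_center is not None
        else tuple(float(v) for v in np.mean([m.coord for m in methyls], axis=0))
    )
    return ReceptorModel(
        elements=tuple(str(e) for e in atoms.element),
        atom_names=tuple(str(n) for n in atoms.atom_name),
        residue_numbers=tuple(int(r) for r in atoms.res_id),
        residue_names=tuple(str(r) for r in atoms.res_name),
        coords=np.asarray(atoms.coord, dtype=float),
        methyl_groups=tuple(methyls),
        pocket_center=center,
    )


def _atom_array(
    elements: Sequence[str],
    names: Sequence[str],
    res_ids: Sequence[int],
    res_names: Sequence[str],
    coords: np.ndarray,
) -> struc.AtomArray:
    n = len(elements)
    arr = struc.AtomArray(n)
    arr.coord = np.asarray(coords, dtype=np.float32)
    arr.chain_id = np.array(["A"] * n)
    arr.res_id = np.array(res_ids, dtype=int)
    arr.res_name = np.array(res_names)
    arr.atom_name = np.array(names)
    arr.element = np.array(elements)
    arr.hetero = np.array([False] * n)
    return arr


def write_receptor_pdb(receptor: ReceptorModel, path) -> None:
    arr = _atom_array(
        receptor.elements,
        receptor.atom_names,
        receptor.residue_numbers,
        receptor.residue_names,
        receptor.coords,
    )
    pdb = PDBFile()
    pdb.set_structure(arr)
    pdb.write(str(path))


def write_ligand_pdb(
    ligand: LigandModel, path, coords: np.ndarray | None = None
) -> None:
    """Ligand as a single LIG residue; proton groups go to a JSON sidecar."""
    xyz = ligand.coords if coords is None else coords
    arr = _atom_array(
        ligand.elements,
        ligand.atom_names,
        [1] * ligand.n_atoms,
        [ligand.residue_name] * ligand.n_atoms,
        xyz,
    )
    pdb = PDBFile()
    pdb.set_structure(arr)
    pdb.write(str(path))
    sidecar = Path(str(path)).with_suffix(".groups.json")
    payload = {
        "proton_groups": [
            {"id": g.id, "atom_indices": list(g.atom_indices), "multiplicity": g.multiplicity}
            for g in ligand.proton_groups
        ],
        "torsions": [
            {"atom_i": t.atom_i, "atom_j": t.atom_j, "moving": list(t.moving)}
            for t in ligand.torsions
        ],
    }
    sidecar.write_text(json.dumps(payload, indent=1))


def write_pose_ensemble(ligand: LigandModel, poses: Sequence[np.ndarray], path) -> None:
    """Multi-MODEL PDB of ligand coordinate sets."""
    from biotite.structure import AtomArrayStack

    arrs = [
        _atom_array(
            ligand.elements,
            ligand.atom_names,
            [1] * ligand.n_atoms,
            [ligand.residue_name] * ligand.n_atoms,
            xyz,
        )
        for xyz in poses
    ]
    stack = struc.stack(arrs)
    pdb = PDBFile()
    pdb.set_structure(stack)
    pdb.write(str(path))


def read_ligand_pdb(path) -> LigandModel:
    """Read a ligand PDB (with its ``.groups.json`` sidecar when present).

    Without a sidecar every atom becomes its own single-proton group
    named after the atom.
    """
    path = Path(path)
    try:
        pdb = PDBFile.read(str(path))
        atoms = pdb.get_structure(model=1, altloc="first")
    except Exception as exc:
        raise ValueError(f"failed to parse PDB {path}: {exc}") from exc
    sidecar = path.with_suffix(".groups.json")
    from .models import Torsion

    if sidecar.exists():
        payload = json.loads(sidecar.read_text())
        groups = tuple(
            LigandProtonGroup(
                id=g["id"],
                atom_indices=tuple(g["atom_indices"]),
                multiplicity=g["multiplicity"],
            )
            for g in payload["proton_groups"]
        )
        torsions = tuple(
            Torsion(atom_i=t["atom_i"], atom_j=t["atom_j"], moving=tuple(t["moving"]))
            for t in payload.get("torsions", [])
        )
    else:
        groups = tuple(
            LigandProtonGroup(id=str(atoms.atom_name[i]), atom_indices=(i,))
            for i in range(atoms.array_length())
        )
        torsions = ()
    return LigandModel(
        atom_names=tuple(str(n) for n in atoms.atom_name),
        elements=tuple(str(e) for e in atoms.element),
        coords=np.asarray(atoms.coord, dtype=float),
        proton_groups=groups,
        torsions=torsions,
        residue_name=str(atoms.res_name[0]) if atoms.array_length() else "LIG",
    )


# ---------------------------------------------------------------------------
# CYANA-dialect restraint lists (.upl / .lol)
# ---------------------------------------------------------------------------

_HEADER = "# nmr2kit {kind}-limit distance restraints (CYANA dialect)\n"


def _methyl_fields(methyl_id: str) -> tuple[int, str, str]:
    # "LEU105:CD1" -> (105, "LEU", "CD1")
    respart, atom = methyl_id.split(":")
    resname, resnum = respart[:3], int(respart[3:])
    return resnum, resname, atom


def _format_lines(restraints: Sequence[DistanceRestraint], kind: str) -> str:
    out = [_HEADER.format(kind=kind)]
    group_no = 0
    for r in sorted(restraints, key=lambda r: r.dedup_key()):
        if r.source == "intraligand":
            out.append(
                f"{1:>4} {'LIG':<4} {r.ligand_group:<5} "
                f"{1:>4} {'LIG':<4} {r.ligand_partner:<5} "
                f"{r.bound:6.2f}  # src=intraligand\n"
            )
            continue
        cands = sorted(r.candidate_receptor_groups)
        group_no += 1
        tag = f" amb={group_no}" if len(cands) > 1 else ""
        for mid in cands:
            resnum, resname, atom = _methyl_fields(mid)
            out.append(
                f"{1:>4} {'LIG':<4} {r.ligand_group:<5} "
                f"{resnum:>4} {resname:<4} {atom:<5} "
                f"{r.bound:6.2f}  # src={r.source} res={r.resonance}{tag}\n"
            )
    return "".join(out)


def write_restraints(
    restraints: Iterable[DistanceRestraint], upl_path, lol_path
) -> None:
    """Write upper limits to ``.upl`` and lower limits to ``.lol``.

    Ambiguous restraints are exported as grouped alternative lines that
    share an ``amb=<n>`` identifier.  ``read_restraints(write(x)) == x``.
    """
    rs = list(restraints)
    for r in rs:
        if r.source != "intraligand" and any(
            ":" not in m for m in r.candidate_receptor_groups
        ):
            raise ValueError(f"cannot export unmapped methyl-group id in {r}")
    uppers = [r for r in rs if r.bound_type == "upper"]
    lowers = [r for r in rs if r.bound_type == "lower"]
    Path(upl_path).write_text(_format_lines(uppers, "upper"))
    Path(lol_path).write_text(_format_lines(lowers, "lower"))


def _parse_lines(text: str, bound_type: str) -> list[DistanceRestraint]:
    grouped: dict[tuple, dict] = {}
    order: list[tuple] = []
    for lineno, line in enumerate(text.splitlines(), start=1):
        body = line.split("#", 1)
        comment = body[1].strip() if len(body) > 1 else ""
        core = body[0].strip()
        if not core:
            continue
        fields = core.split()
        if len(fields) != 7:
            raise ValueError(f"line {lineno}: expected 7 columns, got {len(fields)}")
        tags = dict(t.split("=", 1) for t in comment.split() if "=" in t)
        bound = float(fields[6])
        if tags.get("src") == "intraligand":
            key = ("intra", fields[2], fields[5], bound)
            grouped[key] = {
                "restraint": DistanceRestraint(
                    ligand_group=fields[2],
                    bound_type=bound_type,
                    bound=bound,
                    source="intraligand",
                    ligand_partner=fields[5],
                )
            }
            order.append(key)
            continue
        mid = f"{fields[4]}{fields[3]}:{fields[5]}"
        resonance = tags.get("res")
        amb = tags.get("amb")
        key = ("amb", amb) if amb else ("single", lineno)
        if key not in grouped:
            grouped[key] = {
                "ligand_group": fields[2],
                "resonance": resonance,
                "source": tags.get("src", "NOE"),
                "bound": bound,
                "cands": set(),
            }
            order.append(key)
        grouped[key]["cands"].add(mid)
    out = []
    for key in order:
        entry = grouped[key]
        if "restraint" in entry:
            out.append(entry["restraint"])
        else:
            out.append(
                DistanceRestraint(
                    ligand_group=entry["ligand_group"],
                    candidate_receptor_groups=frozenset(entry["cands"]),
                    bound_type=bound_type,
                    bound=entry["bound"],
                    source=entry["source"],
                    resonance=entry["resonance"],
                )
            )
    return out


def read_restraints(upl_path, lol_path) -> list[DistanceRestraint]:
    rs = _parse_lines(Path(upl_path).read_text(), "upper")
    rs += _parse_lines(Path(lol_path).read_text(), "lower")
    return rs


# ---------------------------------------------------------------------------
# Run configuration
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class RunConfig:
    """Validated run configuration with documented defaults."""

    protocol: str = "brd4"  # brd4 | trim24
    single_proton_floor: float = 5.5
    two_methyl_floor: float = 6.5
    anti_noe_one_methyl: float = 3.0
    anti_noe_two_methyl: float = 3.6
    quality_threshold: float = 0.10
    rel_tolerance: float = 0.125  # trim24-style calibration: d*(1+rel)+abs
    abs_tolerance: float = 0.3
    use_anti_noes: bool | None = None  # None -> protocol default
    tau_c: float = 10.1e-9
    field_mhz: float = 800.0
    pocket_center: tuple[float, float, float] | None = None
    pocket_radius: float = 12.0
    n_restarts: int = 8
    n_steps: int = 400
    max_full_opt: int = 40
    seed: int = 0

    def __post_init__(self) -> None:
        if self.protocol not in ("brd4", "trim24"):
            raise ValueError(f"unknown protocol {self.protocol!r}")
        for name in (
            "single_proton_floor",
            "two_methyl_floor",
            "anti_noe_one_methyl",
            "anti_noe_two_methyl",
            "quality_threshold",
            "tau_c",
            "field_mhz",
            "pocket_radius",
        ):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")
        if self.n_restarts < 1 or self.n_steps < 1 or self.max_full_opt < 1:
            raise ValueError("annealing parameters must be >= 1")

    def calibration_protocol(self):
        from .restraints import CalibrationProtocol

        return CalibrationProtocol(
            name=self.protocol,
            single_proton_floor=self.single_proton_floor,
            two_methyl_floor=self.two_methyl_floor,
            anti_noe_one_methyl=self.anti_noe_one_methyl,
            anti_noe_two_methyl=self.anti_noe_two_methyl,
            use_floors=self.protocol == "brd4",
            use_anti_noes=(
                self.protocol == "brd4" if self.use_anti_noes is None else self.use_anti_noes
            ),
            rel_tolerance=self.rel_tolerance,
            abs_tolerance=self.abs_tolerance,
        )


def load_config(path) -> RunConfig:
    """Load a YAML config, rejecting unknown keys."""
    payload = yaml.safe_load(Path(path).read_text()) or {}
    if not isinstance(payload, dict):
        raise ValueError("config must be a mapping")
    known = set(RunConfig.__dataclass_fields__)
    unknown = set(payload) - known
    if unknown:
        raise ValueError(f"unknown config key(s): {', '.join(sorted(unknown))}")
    if "pocket_center" in payload and payload["pocket_center"] is not None:
        payload["pocket_center"] = tuple(float(v) for v in payload["pocket_center"])
    return RunConfig(**payload)


def config_hash(config: RunConfig) -> str:
    blob = json.dumps(asdict(config), sort_keys=True, default=str).encode()
    return hashlib.sha256(blob).hexdigest()[:16]
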