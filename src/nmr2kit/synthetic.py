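"""Ground-truth generator for end-to-end tests.

Builds a toy receptor pocket decorated with methyl groups plus a bound
ligand, simulates NOESY build-up series through the *full* relaxation
matrix (spin diffusion included), and emits the peak tables, visibility
tables, class annotations and hidden assignments that the rest of the
pipeline consumes.  The toy geometry is abstract — one pseudoatom per
methyl proton group — but serialises as regular PDB.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field, replace
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .buildup import PEAK_TABLE_COLUMNS
from .models import LigandModel, LigandProtonGroup, MethylGroup, ReceptorModel
from .relaxation import RelaxationContext, sigma_from_distance
from .restraints import (
    BRD4_PROTOCOL,
    DistanceRestraint,
    ProtonGroup,
    VisibilityTable,
    build_anti_noe,
)

__all__ = [
    "SyntheticComplexSpec",
    "GroundTruth",
    "BlindInputs",
    "Benchmark",
    "make_toy_complex",
    "simulate_noesy",
    "blind_inputs",
    "make_relay_system",
    "make_benchmark",
    "benchmark_engine_config",
]

# residue templates cycled through for the ILV class
_ILV_TEMPLATES = (("LEU", "CD1"), ("VAL", "CG1"), ("ILE", "CD1"))
_CLASS_TEMPLATES = {"Met": ("MET", "CE"), "Thr": ("THR", "CG2"), "Ala": ("ALA", "CB")}


@dataclass(frozen=True)
class SyntheticComplexSpec:
    """Parameters of the toy complex and its NOESY acquisition."""

    n_pocket_methyls: int = 12
    n_ligand_protons: int = 8  # ligand proton groups
    n_ligand_methyls: int = 2  # of which CH3 groups
    residue_classes: tuple[str, ...] = (
        "Met", "Met", "Thr", "Thr", "Ala", "Ala",
        "ILV", "ILV", "ILV", "ILV", "ILV", "ILV",
    )
    tau_c: float = 10.1e-9  # s
    field_mhz: float = 800.0
    mixing_times: tuple[float, ...] = (0.05, 0.10, 0.15, 0.20)  # s
    noise_sd: float = 0.0  # fraction of the largest diagonal intensity
    detection_threshold: float = 0.005  # same units
    leak_rate: float = 1.0  # s^-1 external relaxation on diagonals
    shell_radius: float = 6.0  # A, methyl shell around the pocket center
    min_methyl_separation: float = 3.5  # A
    ligand_radius: float = 3.0  # A, ligand atoms within this of the center
    min_ligand_separation: float = 1.6  # A
    min_contact: float = 2.7  # A, closest allowed ligand-methyl approach
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_pocket_methyls <= 0 or self.n_ligand_protons <= 0:
            raise ValueError("counts must be positive")
        if len(self.residue_classes) != self.n_pocket_methyls:
            raise ValueError("residue_classes length must equal n_pocket_methyls")
        if self.noise_sd < 0.0:
            raise ValueError("noise_sd must be >= 0")
        if not all(b > a for a, b in zip(self.mixing_times, self.mixing_times[1:])):
            raise ValueError("mixing times must be strictly increasing")

    @property
    def context(self) -> RelaxationContext:
        return RelaxationContext.from_field(self.tau_c, self.field_mhz)


@dataclass
class GroundTruth:
    """Everything the blinding step hides, retained for scoring."""

    assignment: dict[str, str]  # resonance label -> true methyl id (after blinding)
    pose: np.ndarray  # true ligand coordinates (n_atoms, 3)
    group_ids: tuple[str, ...]  # ligand groups then methyl ids, simulator order
    distance_matrix: np.ndarray  # (n_groups, n_groups) A, symmetric, zero diagonal
    visible_pairs: list = field(default_factory=list)
    invisible_pairs: list = field(default_factory=list)

    def distance(self, gid_a: str, gid_b: str) -> float:
        i = self.group_ids.index(gid_a)
        j = self.group_ids.index(gid_b)
        return float(self.distance_matrix[i, j])


class GenerationError(RuntimeError):
    """The spec could not be realised (shell too crowded, no contacts...)."""


def _sample_shell_points(
    rng: np.random.Generator, n: int, radius: float, min_sep: float, max_tries: int = 20000
) -> np.ndarray:
    points: list[np.ndarray] = []
    for _ in range(max_tries):
        v = rng.normal(size=3)
        v *= radius / max(np.linalg.norm(v), 1e-12)
        if all(np.linalg.norm(v - p) >= min_sep for p in points):
            points.append(v)
            if len(points) == n:
                return np.array(points)
    raise GenerationError(
        f"could not place {n} methyls on a {radius} A shell with "
        f"{min_sep} A separation"
    )


def _sample_ligand_points(
    rng: np.random.Generator,
    n: int,
    radius: float,
    min_sep: float,
    methyls: np.ndarray,
    min_contact: float,
    max_tries: int = 20000,
) -> np.ndarray:
    points: list[np.ndarray] = []
    for _ in range(max_tries):
        v = rng.normal(size=3)
        v *= (radius * rng.uniform() ** (1.0 / 3.0)) / max(np.linalg.norm(v), 1e-12)
        if any(np.linalg.norm(v - p) < min_sep for p in points):
            continue
        if np.min(np.linalg.norm(methyls - v, axis=1)) < min_contact:
            continue
        points.append(v)
        if len(points) == n:
            return np.array(points)
    raise GenerationError(f"could not place {n} ligand protons inside the pocket")


def make_toy_complex(
    spec: SyntheticComplexSpec,
) -> tuple[ReceptorModel, LigandModel, GroundTruth]:
    """Deterministic toy pocket + ligand with guaranteed informative NOEs.

    Pocket methyls sit on a shell around the origin with a minimum
    separation; the ligand sits inside with at least 3 protons within
    5 A of at least 2 methyls each.
    """
    rng = np.random.default_rng(spec.seed)
    for attempt in range(50):
        methyl_xyz = _sample_shell_points(
            rng, spec.n_pocket_methyls, spec.shell_radius, spec.min_methyl_separation
        )
        try:
            ligand_xyz = _sample_ligand_points(
                rng,
                spec.n_ligand_protons,
                spec.ligand_radius,
                spec.min_ligand_separation,
                methyl_xyz,
                spec.min_contact,
            )
        except GenerationError:
            continue
        d = np.linalg.norm(ligand_xyz[:, None, :] - methyl_xyz[None, :, :], axis=2)
        if np.sum(np.sum(d < 5.0, axis=1) >= 2) >= 3:
            break
    else:
        raise GenerationError("no informative geometry found for this spec")

    ilv_cycle = itertools.cycle(_ILV_TEMPLATES)
    methyls = []
    for k, (cls, xyz) in enumerate(zip(spec.residue_classes, methyl_xyz)):
        resname, atom = _CLASS_TEMPLATES.get(cls) or next(ilv_cycle)
        resnum = 101 + k
        methyls.append(
            MethylGroup(
                id=f"{resname}{resnum}:{atom}",
                residue_number=resnum,
                residue_name=resname,
                atom_name=atom,
                residue_class=cls,
                coord=tuple(float(v) for v in xyz),
            )
        )
    receptor = ReceptorModel(
        elements=tuple("C" for _ in methyls),
        atom_names=tuple(m.atom_name for m in methyls),
        residue_numbers=tuple(m.residue_number for m in methyls),
        residue_names=tuple(m.residue_name for m in methyls),
        coords=methyl_xyz,
        methyl_groups=tuple(methyls),
        pocket_center=(0.0, 0.0, 0.0),
    )

    n_single = spec.n_ligand_protons - spec.n_ligand_methyls
    groups = []
    for k in range(spec.n_ligand_protons):
        is_methyl = k >= n_single
        groups.append(
            LigandProtonGroup(id=f"L{k + 1}", atom_indices=(k,), multiplicity=3 if is_methyl else 1)
        )
    ligand = LigandModel(
        atom_names=tuple(f"C{k + 1}" for k in range(spec.n_ligand_protons)),
        elements=tuple("C" for _ in range(spec.n_ligand_protons)),
        coords=ligand_xyz,
        proton_groups=tuple(groups),
    )

    group_ids = tuple(g.id for g in groups) + tuple(m.id for m in methyls)
    all_xyz = np.vstack([ligand_xyz, methyl_xyz])
    dist = np.linalg.norm(all_xyz[:, None, :] - all_xyz[None, :, :], axis=2)
    truth = GroundTruth(
        assignment={},
        pose=ligand_xyz.copy(),
        group_ids=group_ids,
        distance_matrix=dist,
    )
    return receptor, ligand, truth


# ---------------------------------------------------------------------------
# Full relaxation-matrix NOESY simulation
# ---------------------------------------------------------------------------


def relaxation_matrix(distance_matrix: np.ndarray, ctx: RelaxationContext, leak_rate: float) -> np.ndarray:
    """Rate matrix R: off-diagonals sigma(r_ij), diagonals sum|sigma| + leak."""
    d = np.asarray(distance_matrix, dtype=float)
    n = d.shape[0]
    r = np.zeros((n, n))
    for i in range(n):
        for j in range(i + 1, n):
            r[i, j] = r[j, i] = sigma_from_distance(d[i, j], ctx)
    np.fill_diagonal(r, np.sum(np.abs(r), axis=1) + leak_rate)
    return r


def magnetization_series(rate_matrix: np.ndarray, mixing_times: Sequence[float]) -> np.ndarray:
    """M(t) = expm(-R t) for each mixing time; shape (n_t, n, n).

    R is symmetric, so the exponential is computed by eigendecomposition.
    """
    r = np.asarray(rate_matrix, dtype=float)
    try:
        w, v = np.linalg.eigh(r)
    except np.linalg.LinAlgError as exc:
        raise RuntimeError(f"relaxation-matrix diagonalisation failed: {exc}") from exc
    out = np.empty((len(mixing_times), *r.shape))
    for k, t in enumerate(mixing_times):
        out[k] = (v * np.exp(-w * t)) @ v.T
    return out


def simulate_noesy(
    receptor: ReceptorModel,
    ligand: LigandModel,
    truth: GroundTruth,
    spec: SyntheticComplexSpec,
) -> tuple[pd.DataFrame, VisibilityTable]:
    """Simulate the NOESY mixing-time series for every proton-group pair.

    Cross peaks are emitted for both sides of the diagonal with
    independent Gaussian noise; peaks whose noise-free maximum falls
    below the detection threshold are suppressed.  The visibility table
    and the truth's visible/invisible pair lists are derived from the
    noise-free intensities.
    """
    rng = np.random.default_rng(np.random.SeedSequence([spec.seed, 7]))
    ctx = spec.context
    ids = truth.group_ids
    r = relaxation_matrix(truth.distance_matrix, ctx, spec.leak_rate)
    series = magnetization_series(r, spec.mixing_times)  # (n_t, n, n)
    n = len(ids)

    rows: list[tuple] = []
    visible: list[tuple[str, str]] = []
    invisible: list[tuple[str, str]] = []
    sd = spec.noise_sd

    for i in range(n):
        clean = series[:, i, i]
        noisy = clean + rng.normal(scale=sd, size=clean.shape) if sd > 0 else clean
        for t, y in zip(spec.mixing_times, noisy):
            rows.append((f"d_{ids[i]}", ids[i], ids[i], t, float(y), "above"))

    for i in range(n):
        for j in range(i + 1, n):
            clean = series[:, i, j]
            if float(np.max(np.abs(clean))) < spec.detection_threshold:
                invisible.append((ids[i], ids[j]))
                continue
            visible.append((ids[i], ids[j]))
            for side in ("above", "below"):
                noisy = clean + rng.normal(scale=sd, size=clean.shape) if sd > 0 else clean
                pid = f"x_{ids[i]}_{ids[j]}"
                for t, y in zip(spec.mixing_times, noisy):
                    rows.append((pid, ids[i], ids[j], t, float(y), side))

    truth.visible_pairs = visible
    truth.invisible_pairs = invisible
    df = pd.DataFrame(rows, columns=PEAK_TABLE_COLUMNS)
    return df, VisibilityTable(visible)


def make_relay_system(
    r12: float = 2.6,
    r23: float = 2.6,
    ctx: RelaxationContext | None = None,
    mixing_times: Sequence[float] = (0.05, 0.10, 0.15, 0.20),
    leak_rate: float = 1.0,
) -> tuple[np.ndarray, np.ndarray]:
    """Three collinear spins with a strong relay pathway 1-2-3.

    Returns (mixing_times, M(t) series).  The (1,3) cross peak grows by
    spin diffusion through spin 2; its two-spin fit must be rejected.
    """
    ctx = ctx or RelaxationContext.from_field(10.1e-9, 800.0)
    d = np.zeros((3, 3))
    d[0, 1] = d[1, 0] = r12
    d[1, 2] = d[2, 1] = r23
    d[0, 2] = d[2, 0] = r12 + r23
    r = relaxation_matrix(d, ctx, leak_rate)
    t = np.asarray(mixing_times, dtype=float)
    return t, magnetization_series(r, t)


# ---------------------------------------------------------------------------
# Blinding
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class BlindInputs:
    """What the engine is allowed to see."""

    resonances: tuple[str, ...]  # M1..Mn, randomised order
    proton_groups: tuple[ProtonGroup, ...]  # receptor resonances + ligand groups
    classes: Mapping[str, str]  # resonance -> residue class
    anchors: Mapping[str, str]  # resonance -> methyl id (fixed a priori)
    peak_table: pd.DataFrame  # methyl ids replaced by resonance labels
    visibility: VisibilityTable
    label_of_methyl: Mapping[str, str]  # methyl id -> resonance label (bijection)


def blind_inputs(
    truth: GroundTruth,
    receptor: ReceptorModel,
    ligand: LigandModel,
    peak_table: pd.DataFrame,
    *,
    n_anchors: int = 2,
    seed: int = 0,
) -> BlindInputs:
    """Strip assignments: relabel methyl resonances M1..Mn in seeded random order.

    Residue classes are carried over from the true methyls (class
    annotation is an experimental input, not something inferred here);
    anchors are taken from Met- then Thr-classed resonances, emulating
    the easily assigned anchor methyls.  The true mapping is written to
    ``truth.assignment`` for later scoring.
    """
    rng = np.random.default_rng(np.random.SeedSequence([seed, 13]))
    methyl_ids = [m.id for m in receptor.methyl_groups]
    order = rng.permutation(len(methyl_ids))
    label_of = {methyl_ids[k]: f"M{i + 1}" for i, k in enumerate(order)}
    truth.assignment = {label: mid for mid, label in label_of.items()}

    class_of = {
        label_of[m.id]: m.residue_class for m in receptor.methyl_groups
    }
    anchors: dict[str, str] = {}
    for wanted in ("Met", "Thr"):
        if len(anchors) >= n_anchors:
            break
        for label in sorted(class_of, key=lambda s: int(s[1:])):
            if class_of[label] == wanted and label not in anchors:
                anchors[label] = truth.assignment[label]
                break
    while len(anchors) < n_anchors:
        for label in sorted(class_of, key=lambda s: int(s[1:])):
            if label not in anchors:
                anchors[label] = truth.assignment[label]
                break

    relabel = lambda g: label_of.get(g, g)  # noqa: E731
    table = peak_table.copy()
    table["group_i"] = table["group_i"].map(relabel)
    table["group_j"] = table["group_j"].map(relabel)
    table["peak_id"] = [
        f"{'d' if gi == gj else 'x'}_{gi}" + ("" if gi == gj else f"_{gj}")
        for gi, gj in zip(table["group_i"], table["group_j"])
    ]

    visible = [
        (relabel(a), relabel(b)) for a, b in truth.visible_pairs
    ]
    groups: list[ProtonGroup] = [
        ProtonGroup(
            id=label,
            kind="receptor-methyl",
            multiplicity=3,
            residue_class=class_of[label],
            assigned_to=anchors.get(label),
        )
        for label in sorted(class_of, key=lambda s: int(s[1:]))
    ]
    for g in ligand.proton_groups:
        groups.append(
            ProtonGroup(
                id=g.id,
                kind="ligand-methyl" if g.multiplicity >= 3 else "ligand-proton",
                multiplicity=g.multiplicity,
            )
        )
    resonances = tuple(sorted(class_of, key=lambda s: int(s[1:])))
    return BlindInputs(
        resonances=resonances,
        proton_groups=tuple(groups),
        classes=class_of,
        anchors=anchors,
        peak_table=table,
        visibility=VisibilityTable(visible),
        label_of_methyl=label_of,
    )


# ---------------------------------------------------------------------------
# Restraints-from-truth benchmark (the engine's default synthetic benchmark)
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class Benchmark:
    receptor: ReceptorModel
    ligand: LigandModel
    truth: GroundTruth
    restraints: tuple[DistanceRestraint, ...]
    resonances: tuple[str, ...]
    candidate_sets: Mapping[str, frozenset]
    anchors: Mapping[str, str]


def make_benchmark(
    seed: int = 0,
    *,
    n_resonances: int = 10,
    n_noes: int = 25,
    n_anti_noes: int = 15,
    n_anchors: int = 2,
    upper_slack: float = 0.4,
    anti_noe_margin: float = 0.2,
    include_anti_noes: bool = True,
    spec: SyntheticComplexSpec | None = None,
) -> Benchmark:
    """Default synthetic benchmark built directly from ground-truth geometry.

    The ``n_resonances`` methyls closest to the ligand are treated as
    observed; the ``n_noes`` shortest ligand-methyl distances among them
    become upper limits (true distance + ``upper_slack``), and
    ``n_anti_noes`` absent pairs whose true distance clears the
    anti-NOE limit by ``anti_noe_margin`` become lower limits via the
    standard conservative rule.
    """
    spec = spec or SyntheticComplexSpec(seed=seed)
    if spec.seed != seed:
        spec = replace(spec, seed=seed)
    receptor, ligand, truth = make_toy_complex(spec)
    rng = np.random.default_rng(np.random.SeedSequence([seed, 29]))

    lig_groups = [g.id for g in ligand.proton_groups]
    lig_xyz = ligand.group_coords()
    met_ids = [m.id for m in receptor.methyl_groups]
    met_xyz = receptor.methyl_coords
    d = np.linalg.norm(lig_xyz[:, None, :] - met_xyz[None, :, :], axis=2)

    closest = np.min(d, axis=0)
    observed_idx = sorted(np.argsort(closest)[:n_resonances])
    observed = [met_ids[k] for k in observed_idx]

    # blinded labels for the observed methyls
    order = rng.permutation(len(observed))
    label_of = {observed[k]: f"M{i + 1}" for i, k in enumerate(order)}
    truth.assignment = {label: mid for mid, label in label_of.items()}
    class_of_methyl = {m.id: m.residue_class for m in receptor.methyl_groups}
    classes = {label: class_of_methyl[mid] for mid, label in label_of.items()}

    anchors: dict[str, str] = {}
    for wanted in ("Met", "Thr", "Ala"):
        if len(anchors) >= n_anchors:
            break
        for label in sorted(classes, key=lambda s: int(s[1:])):
            if classes[label] == wanted and label not in anchors:
                anchors[label] = truth.assignment[label]
                break

    inventory = {m.id: m.residue_class for m in receptor.methyl_groups}
    candidate_sets = {
        label: frozenset(
            mid for mid, cls in inventory.items() if cls == classes[label]
        )
        if classes[label] != "unknown"
        else frozenset(inventory)
        for label in classes
    }

    # NOEs: shortest observed ligand-methyl distances
    pairs = sorted(
        ((float(d[i, k]), lig_groups[i], met_ids[k]) for i in range(len(lig_groups))
         for k in observed_idx),
        key=lambda x: (x[0], x[1], x[2]),
    )
    noes = pairs[:n_noes]
    group_by_id = ligand.group_by_id
    restraints = [
        DistanceRestraint(
            ligand_group=lg,
            candidate_receptor_groups=candidate_sets[label_of[mid]],
            bound_type="upper",
            bound=max(dist + upper_slack, 1.8),
            source="NOE",
            resonance=label_of[mid],
        )
        for dist, lg, mid in noes
    ]

    if include_anti_noes:
        visibility = VisibilityTable(
            [(lg, label_of[mid]) for _, lg, mid in noes]
        )
        eligible = []
        noe_set = {(lg, mid) for _, lg, mid in noes}
        for dist, lg, mid in pairs[n_noes:]:
            if (lg, mid) in noe_set:
                continue
            both_methyl = group_by_id[lg].multiplicity >= 3
            limit = (
                BRD4_PROTOCOL.anti_noe_two_methyl if both_methyl
                else BRD4_PROTOCOL.anti_noe_one_methyl
            )
            if dist >= limit + anti_noe_margin:
                eligible.append((dist, lg, mid))
        anti = []
        for dist, lg, mid in eligible[:n_anti_noes]:
            label = label_of[mid]
            pg_l = ProtonGroup(
                id=lg,
                kind="ligand-methyl" if group_by_id[lg].multiplicity >= 3 else "ligand-proton",
                multiplicity=group_by_id[lg].multiplicity,
            )
            pg_r = ProtonGroup(id=label, kind="receptor-methyl", multiplicity=3)
            r = build_anti_noe(
                pg_l, pg_r, visibility, candidate_receptor_groups=candidate_sets[label]
            )
            if r is not None:
                anti.append(r)
        restraints.extend(anti)

    resonances = tuple(sorted(classes, key=lambda s: int(s[1:])))
    return Benchmark(
        receptor=receptor,
        ligand=ligand,
        truth=truth,
        restraints=tuple(restraints),
        resonances=resonances,
        candidate_sets=candidate_sets,
        anchors=anchors,
    )


def benchmark_engine_config():
    """Lean engine configuration sized for the default benchmark."""
    from .engine import AnnealingSchedule, EngineConfig

    return EngineConfig(
        schedule=AnnealingSchedule(n_restarts=4, n_steps=250),
        max_full_opt=12,
    )
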