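"""Molecular-replacement core.

Enumerates resonance -> receptor-methyl assignment hypotheses consistent
with residue-class candidate sets and anchors, optimises the ligand pose
against the rigid receptor under each hypothesis by seeded simulated
annealing, scores poses with a CYANA-style target function (squared
upper-/lower-limit violations plus hard-sphere repulsion), and returns
the ranked ensemble together with the assignment inferred from the
lowest-target hypothesis.
"""

from __future__ import annotations

import itertools
import logging
import math
from dataclasses import dataclass, field, replace
from typing import Iterable, Iterator, Mapping, Sequence

import numpy as np
from scipy.optimize import minimize
from scipy.spatial.transform import Rotation

from .models import LigandModel, ReceptorModel
from .restraints import DistanceRestraint

__all__ = [
    "AssignmentHypothesis",
    "ComplexPose",
    "TargetFunctionReport",
    "AnnealingSchedule",
    "EngineConfig",
    "HypothesisResult",
    "Nmr2Result",
    "TooManyHypothesesError",
    "enumerate_assignments",
    "count_assignments",
    "target_function",
    "optimize_pose",
    "run_nmr2",
    "refine_backbone_restrained",
    "ligand_rmsd",
    "HARD_SPHERE_RADII",
    "OVERLAP_FACTOR",
]

logger = logging.getLogger(__name__)

#: Per-element hard-sphere radii (Angstrom); pair minimum distance is
#: ``OVERLAP_FACTOR * (r_a + r_b)``.
HARD_SPHERE_RADII = {"H": 1.0, "C": 1.5, "N": 1.4, "O": 1.3, "S": 1.7}
OVERLAP_FACTOR = 0.8
_DEFAULT_RADIUS = 1.5


class TooManyHypothesesError(RuntimeError):
    """Hypothesis count exceeds the configured cap; tighten classes or radius."""


@dataclass(frozen=True)
class AssignmentHypothesis:
    """Injective mapping of unassigned resonances to receptor methyl groups."""

    mapping: tuple[tuple[str, str], ...]  # sorted (resonance, methyl_id) pairs
    fixed_anchors: frozenset = field(default_factory=frozenset)

    def __post_init__(self) -> None:
        targets = [m for _, m in self.mapping]
        if len(set(targets)) != len(targets):
            raise ValueError("assignment must be injective")

    @classmethod
    def from_dict(
        cls, mapping: Mapping[str, str], anchors: Iterable[str] = ()
    ) -> "AssignmentHypothesis":
        return cls(
            mapping=tuple(sorted(mapping.items())), fixed_anchors=frozenset(anchors)
        )

    @property
    def as_dict(self) -> dict[str, str]:
        return dict(self.mapping)

    def serialization(self) -> str:
        return ";".join(f"{r}->{m}" for r, m in self.mapping)


@dataclass(frozen=True)
class TargetFunctionReport:
    upper_violation_sum: float
    lower_violation_sum: float
    clash_sum: float
    per_restraint: tuple[float, ...]  # violation in A per restraint, 0 if satisfied
    weights: tuple[float, float, float] = (1.0, 1.0, 1.0)

    @property
    def total(self) -> float:
        wu, wl, wc = self.weights
        return wu * self.upper_violation_sum + wl * self.lower_violation_sum + wc * self.clash_sum


@dataclass(frozen=True)
class ComplexPose:
    """Ligand placement (rigid-body + torsions) with its target value."""

    params: tuple[float, ...]  # tx,ty,tz, rx,ry,rz (rotation vector), torsions...
    ligand_coords: np.ndarray  # (n_atoms, 3)
    target_value: float
    report: TargetFunctionReport | None = None

    def __post_init__(self) -> None:
        object.__setattr__(self, "ligand_coords", np.asarray(self.ligand_coords, dtype=float))


@dataclass(frozen=True)
class AnnealingSchedule:
    """Geometric-cooling simulated annealing parameters."""

    n_restarts: int = 8
    n_steps: int = 400
    temp_start: float = 5.0
    temp_end: float = 1e-3
    translation_step: float = 1.0  # A
    rotation_step: float = 0.35  # rad
    torsion_step: float = 0.5  # rad
    init_radius: float = 3.0  # A around the pocket center
    polish: bool = True


@dataclass(frozen=True)
class EngineConfig:
    schedule: AnnealingSchedule = field(default_factory=AnnealingSchedule)
    weights: tuple[float, float, float] = (1.0, 1.0, 1.0)
    max_hypotheses: int = 200_000
    max_full_opt: int = 40  # hypotheses fully optimised after pre-screening
    tie_tolerance: float = 1e-4
    keep_top: int = 10  # ensemble size retained in the result
    prescreen: bool = True


# ---------------------------------------------------------------------------
# Assignment enumeration
# ---------------------------------------------------------------------------


def _prepared_candidates(
    resonances: Sequence[str],
    candidate_sets: Mapping[str, Iterable[str]],
    anchors: Mapping[str, str],
) -> list[tuple[str, tuple[str, ...]]]:
    prepared = []
    for r in resonances:
        if r in anchors:
            cands: tuple[str, ...] = (anchors[r],)
        else:
            cands = tuple(sorted(candidate_sets[r]))
            if not cands:
                raise ValueError(f"resonance {r} has an empty candidate set")
        prepared.append((r, cands))
    # fewest candidates first: cheap pruning, deterministic order
    prepared.sort(key=lambda x: (len(x[1]), x[0]))
    return prepared


def count_assignments(
    resonances: Sequence[str],
    candidate_sets: Mapping[str, Iterable[str]],
    anchors: Mapping[str, str] | None = None,
    *,
    cap: int | None = None,
) -> int:
    """Number of injective assignments (the permanent of the candidate matrix).

    Counts by depth-first search; stops with :class:`TooManyHypothesesError`
    when ``cap`` is exceeded.
    """
    anchors = anchors or {}
    prepared = _prepared_candidates(resonances, candidate_sets, anchors)

    def rec(i: int, used: frozenset) -> int:
        if i == len(prepared):
            return 1
        total = 0
        for m in prepared[i][1]:
            if m not in used:
                total += rec(i + 1, used | {m})
                if cap is not None and total > cap:
                    raise TooManyHypothesesError(
                        f"more than {cap} assignment hypotheses; tighten residue "
                        f"classes or the pocket radius"
                    )
        return total

    return rec(0, frozenset())


def enumerate_assignments(
    resonances: Sequence[str],
    candidate_sets: Mapping[str, Iterable[str]],
    anchors: Mapping[str, str] | None = None,
    *,
    cap: int | None = None,
) -> Iterator[AssignmentHypothesis]:
    """Lazily yield all injective assignments consistent with the inputs.

    Anchors are honoured as fixed singleton choices.  When ``cap`` is
    given the total count is checked first and an error raised if it is
    exceeded (combinatorial blow-up guard).
    """
    anchors = anchors or {}
    if cap is not None:
        count_assignments(resonances, candidate_sets, anchors, cap=cap)
    prepared = _prepared_candidates(resonances, candidate_sets, anchors)
    anchor_set = frozenset(anchors)

    def rec(i: int, used: frozenset, acc: dict) -> Iterator[AssignmentHypothesis]:
        if i == len(prepared):
            yield AssignmentHypothesis.from_dict(acc, anchors=anchor_set)
            return
        r, cands = prepared[i]
        for m in cands:
            if m not in used:
                acc[r] = m
                yield from rec(i + 1, used | {m}, acc)
                del acc[r]

    return rec(0, frozenset(), {})


# ---------------------------------------------------------------------------
# Target function
# ---------------------------------------------------------------------------


def _pair_rmin(elements_a: Sequence[str], elements_b: Sequence[str]) -> np.ndarray:
    ra = np.array([HARD_SPHERE_RADII.get(e, _DEFAULT_RADIUS) for e in elements_a])
    rb = np.array([HARD_SPHERE_RADII.get(e, _DEFAULT_RADIUS) for e in elements_b])
    return OVERLAP_FACTOR * (ra[:, None] + rb[None, :])


class TargetEvaluator:
    """Vectorised target function for a fixed hypothesis.

    Each protein-side restraint resolves to the methyl selected by the
    hypothesis (anchored/assigned resonances resolve to their singleton
    candidate); when a restraint still carries several candidates — e.g.
    a prochiral pseudo-group — the r^-6-summed effective distance over
    the alternatives is used.
    """

    def __init__(
        self,
        restraints: Sequence[DistanceRestraint],
        receptor: ReceptorModel,
        ligand: LigandModel,
        hypothesis: AssignmentHypothesis | None = None,
        weights: tuple[float, float, float] = (1.0, 1.0, 1.0),
    ):
        self.restraints = list(restraints)
        self.receptor = receptor
        self.ligand = ligand
        self.weights = weights
        hyp = hypothesis.as_dict if hypothesis is not None else {}
        methyl_by_id = receptor.methyl_by_id
        group_ids = {g.id: k for k, g in enumerate(ligand.proton_groups)}

        lig_idx: list[int] = []
        bounds: list[float] = []
        is_upper: list[bool] = []
        alt_coords: list[np.ndarray] = []
        self._intra: list[tuple[int, int, float, bool, int]] = []
        self._protein_restraint_pos: list[int] = []

        for pos, r in enumerate(self.restraints):
            if r.source == "intraligand":
                if r.ligand_group not in group_ids or r.ligand_partner not in group_ids:
                    raise KeyError(f"restraint references unknown ligand group: {r}")
                self._intra.append(
                    (
                        group_ids[r.ligand_group],
                        group_ids[r.ligand_partner],
                        r.bound,
                        r.bound_type == "upper",
                        pos,
                    )
                )
                continue
            if r.ligand_group not in group_ids:
                raise KeyError(f"restraint references unknown ligand group {r.ligand_group!r}")
            if r.resonance is not None and r.resonance in hyp:
                chosen = [hyp[r.resonance]]
            else:
                chosen = sorted(r.candidate_receptor_groups)
            try:
                coords = np.array([methyl_by_id[m].coord for m in chosen], dtype=float)
            except KeyError as exc:
                raise KeyError(f"restraint references unknown methyl group {exc}") from exc
            lig_idx.append(group_ids[r.ligand_group])
            bounds.append(r.bound)
            is_upper.append(r.bound_type == "upper")
            alt_coords.append(coords)
            self._protein_restraint_pos.append(pos)

        self._lig_idx = np.array(lig_idx, dtype=int)
        self._bounds = np.array(bounds, dtype=float)
        self._is_upper = np.array(is_upper, dtype=bool)
        n = len(alt_coords)
        kmax = max((c.shape[0] for c in alt_coords), default=1)
        self._alt = np.full((n, kmax, 3), 1e6, dtype=float)
        self._alt_mask = np.zeros((n, kmax), dtype=bool)
        for i, c in enumerate(alt_coords):
            self._alt[i, : c.shape[0]] = c
            self._alt_mask[i, : c.shape[0]] = True

        # group coordinates = mean over member atoms, as a sparse gather
        self._group_members = [np.array(g.atom_indices, dtype=int) for g in ligand.proton_groups]
        self._single_atom_groups = all(len(m) == 1 for m in self._group_members)
        if self._single_atom_groups:
            self._member_idx = np.array([m[0] for m in self._group_members], dtype=int)

        self._rmin = _pair_rmin(ligand.elements, receptor.elements)
        self._receptor_coords = receptor.coords

    def group_coords(self, ligand_coords: np.ndarray) -> np.ndarray:
        if self._single_atom_groups:
            return ligand_coords[self._member_idx]
        return np.array([ligand_coords[m].mean(axis=0) for m in self._group_members])

    def effective_distances(self, ligand_coords: np.ndarray) -> np.ndarray:
        """r^-6-summed effective distance per protein-side restraint."""
        g = self.group_coords(ligand_coords)
        diff = self._alt - g[self._lig_idx][:, None, :]
        d2 = np.einsum("ijk,ijk->ij", diff, diff)
        inv6 = np.where(self._alt_mask, d2 ** (-3.0), 0.0)
        return np.sum(inv6, axis=1) ** (-1.0 / 6.0)

    def report(self, ligand_coords: np.ndarray) -> TargetFunctionReport:
        per = np.zeros(len(self.restraints))
        if self._lig_idx.size:
            d = self.effective_distances(ligand_coords)
            up = np.where(self._is_upper, np.maximum(d - self._bounds, 0.0), 0.0)
            lo = np.where(~self._is_upper, np.maximum(self._bounds - d, 0.0), 0.0)
            upper_sum = float(np.sum(up**2))
            lower_sum = float(np.sum(lo**2))
            per[self._protein_restraint_pos] = up + lo
        else:
            upper_sum = lower_sum = 0.0

        g = self.group_coords(ligand_coords)
        for i, j, bound, upper, pos in self._intra:
            d_ij = float(np.linalg.norm(g[i] - g[j]))
            v = max(d_ij - bound, 0.0) if upper else max(bound - d_ij, 0.0)
            per[pos] = v
            if upper:
                upper_sum += v * v
            else:
                lower_sum += v * v

        diff = ligand_coords[:, None, :] - self._receptor_coords[None, :, :]
        dist = np.sqrt(np.einsum("ijk,ijk->ij", diff, diff))
        overlap = np.maximum(self._rmin - dist, 0.0)
        clash = float(np.sum(overlap**2))

        return TargetFunctionReport(
            upper_violation_sum=upper_sum,
            lower_violation_sum=lower_sum,
            clash_sum=clash,
            per_restraint=tuple(per),
            weights=self.weights,
        )

    def total(self, ligand_coords: np.ndarray) -> float:
        # fast path: identical maths to report(), no per-restraint bookkeeping
        if self._lig_idx.size:
            d = self.effective_distances(ligand_coords)
            viol = np.where(
                self._is_upper,
                np.maximum(d - self._bounds, 0.0),
                np.maximum(self._bounds - d, 0.0),
            )
            wu, wl, _ = self.weights
            w = np.where(self._is_upper, wu, wl)
            total = float(np.sum(w * viol**2))
        else:
            total = 0.0
        g = self.group_coords(ligand_coords)
        wu, wl, wc = self.weights
        for i, j, bound, upper, _ in self._intra:
            d_ij = float(np.linalg.norm(g[i] - g[j]))
            v = max(d_ij - bound, 0.0) if upper else max(bound - d_ij, 0.0)
            total += (wu if upper else wl) * v * v
        diff = ligand_coords[:, None, :] - self._receptor_coords[None, :, :]
        dist2 = np.einsum("ijk,ijk->ij", diff, diff)
        close = dist2 < self._rmin**2
        if np.any(close):
            overlap = self._rmin[close] - np.sqrt(dist2[close])
            total += wc * float(np.sum(overlap**2))
        return total


def target_function(
    pose: ComplexPose,
    restraints: Sequence[DistanceRestraint],
    receptor: ReceptorModel,
    ligand: LigandModel,
    hypothesis: AssignmentHypothesis | None = None,
    weights: tuple[float, float, float] = (1.0, 1.0, 1.0),
) -> TargetFunctionReport:
    """CYANA-style target function of a pose.

    Sum of squared upper-limit violations ``(d-u)^2`` for d > u, squared
    lower-limit violations ``(l-d)^2`` for d < l, and a hard-sphere
    penalty ``(r_min - d)^2`` over ligand-receptor atom pairs closer
    than their element-pair minimum distance.
    """
    ev = TargetEvaluator(restraints, receptor, ligand, hypothesis, weights)
    return ev.report(pose.ligand_coords)


# ---------------------------------------------------------------------------
# Pose parametrisation and optimisation
# ---------------------------------------------------------------------------


def place_ligand(ligand: LigandModel, params: np.ndarray) -> np.ndarray:
    """Apply torsions, then a rigid rotation about the centroid, then translation.

    ``params = [tx, ty, tz, rx, ry, rz, torsion_angles...]`` with the
    rotation given as a rotation vector (radians).
    """
    params = np.asarray(params, dtype=float)
    coords = np.array(ligand.coords, dtype=float)
    for angle, tor in zip(params[6:], ligand.torsions):
        axis = coords[tor.atom_j] - coords[tor.atom_i]
        norm = np.linalg.norm(axis)
        if norm < 1e-12:
            continue
        rot = Rotation.from_rotvec(axis / norm * angle)
        moving = list(tor.moving)
        coords[moving] = rot.apply(coords[moving] - coords[tor.atom_j]) + coords[tor.atom_j]
    centroid = coords.mean(axis=0)
    rot = Rotation.from_rotvec(params[3:6])
    return rot.apply(coords - centroid) + centroid + params[:3]


def _initial_params(
    ligand: LigandModel, pocket_center: np.ndarray, rng: np.random.Generator, radius: float
) -> np.ndarray:
    n_tor = len(ligand.torsions)
    centroid = ligand.coords.mean(axis=0)
    offset = rng.normal(size=3)
    offset *= rng.uniform(0.0, radius) / max(np.linalg.norm(offset), 1e-12)
    t = pocket_center - centroid + offset
    rotvec = Rotation.random(random_state=np.random.RandomState(rng.integers(2**31 - 1))).as_rotvec()
    tors = rng.uniform(-math.pi, math.pi, size=n_tor)
    return np.concatenate([t, rotvec, tors])


def optimize_pose(
    hypothesis: AssignmentHypothesis | None,
    restraints: Sequence[DistanceRestraint],
    receptor: ReceptorModel,
    ligand: LigandModel,
    schedule: AnnealingSchedule | None = None,
    seed: int = 0,
    *,
    weights: tuple[float, float, float] = (1.0, 1.0, 1.0),
    _evaluator: "TargetEvaluator | None" = None,
) -> ComplexPose:
    """Multi-start simulated annealing over rigid-body + torsion parameters.

    Deterministic given ``seed``: the master seed fans out to one
    ``SeedSequence([seed, restart])`` per restart.  The best pose over
    all restarts is polished with a derivative-free local minimisation.
    """
    schedule = schedule or AnnealingSchedule()
    ev = _evaluator or TargetEvaluator(restraints, receptor, ligand, hypothesis, weights)
    pocket = np.asarray(receptor.pocket_center, dtype=float)
    n_tor = len(ligand.torsions)
    cooling = (
        (schedule.temp_end / schedule.temp_start) ** (1.0 / max(schedule.n_steps - 1, 1))
        if schedule.n_steps > 1
        else 1.0
    )

    best_params: np.ndarray | None = None
    best_value = math.inf
    for restart in range(schedule.n_restarts):
        rng = np.random.default_rng(np.random.SeedSequence([seed, restart]))
        params = _initial_params(ligand, pocket, rng, schedule.init_radius)
        value = ev.total(place_ligand(ligand, params))
        cur_params, cur_value = params, value
        temp = schedule.temp_start
        for _ in range(schedule.n_steps):
            trial = cur_params.copy()
            kind = rng.integers(3 if n_tor else 2)
            if kind == 0:
                trial[:3] += rng.normal(scale=schedule.translation_step, size=3)
            elif kind == 1:
                trial[3:6] = (
                    Rotation.from_rotvec(rng.normal(scale=schedule.rotation_step, size=3))
                    * Rotation.from_rotvec(trial[3:6])
                ).as_rotvec()
            else:
                k = 6 + rng.integers(n_tor)
                trial[k] += rng.normal(scale=schedule.torsion_step)
            trial_value = ev.total(place_ligand(ligand, trial))
            if trial_value <= cur_value or rng.random() < math.exp(
                -(trial_value - cur_value) / max(temp, 1e-300)
            ):
                cur_params, cur_value = trial, trial_value
                if cur_value < best_value:
                    best_params, best_value = cur_params.copy(), cur_value
            temp *= cooling
        if cur_value < best_value:
            best_params, best_value = cur_params.copy(), cur_value

    assert best_params is not None
    if schedule.polish:
        res = minimize(
            lambda p: ev.total(place_ligand(ligand, p)),
            best_params,
            method="Powell",
            options={"xtol": 1e-8, "ftol": 1e-12, "maxiter": 4000},
        )
        if res.fun <= best_value:
            best_params, best_value = np.asarray(res.x), float(res.fun)

    coords = place_ligand(ligand, best_params)
    return ComplexPose(
        params=tuple(float(v) for v in best_params),
        ligand_coords=coords,
        target_value=float(best_value),
        report=ev.report(coords),
    )


# ---------------------------------------------------------------------------
# Hypothesis pre-screening and the full run
# ---------------------------------------------------------------------------


def _prescreen_score(
    hypothesis: AssignmentHypothesis,
    restraints: Sequence[DistanceRestraint],
    receptor: ReceptorModel,
    ligand: LigandModel,
) -> float:
    """Pose-free lower bound on the target from pairwise triangle inequalities.

    For two satisfied upper limits (g1,m1,u1), (g2,m2,u2) the methyl
    separation obeys ``d(m1,m2) <= u1 + d(g1,g2) + u2``; any excess is a
    certified violation floor.  Sound only for a rigid ligand, so the
    score is 0 whenever the ligand has rotatable torsions.
    """
    if ligand.torsions:
        return 0.0
    hyp = hypothesis.as_dict
    methyl_by_id = receptor.methyl_by_id
    group_coords = {g.id: c for g, c in zip(ligand.proton_groups, ligand.group_coords())}
    uppers = []
    for r in restraints:
        if r.source != "NOE" or r.bound_type != "upper" or r.resonance is None:
            continue
        m = hyp.get(r.resonance)
        if m is None:
            if len(r.candidate_receptor_groups) != 1:
                continue
            (m,) = r.candidate_receptor_groups
        uppers.append((group_coords[r.ligand_group], methyl_by_id[m].xyz, r.bound))
    score = 0.0
    for (g1, m1, u1), (g2, m2, u2) in itertools.combinations(uppers, 2):
        excess = np.linalg.norm(m1 - m2) - np.linalg.norm(g1 - g2) - u1 - u2
        if excess > 0.0:
            score += float(excess) ** 2
    return score


def _batch_prescreen(
    hyps: Sequence[AssignmentHypothesis],
    restraints: Sequence[DistanceRestraint],
    receptor: ReceptorModel,
    ligand: LigandModel,
) -> np.ndarray:
    """Vectorised :func:`_prescreen_score` over many hypotheses."""
    if ligand.torsions:
        return np.zeros(len(hyps))
    methyl_index = {m.id: k for k, m in enumerate(receptor.methyl_groups)}
    mx = receptor.methyl_coords
    methyl_dist = np.linalg.norm(mx[:, None, :] - mx[None, :, :], axis=2)
    group_coords = {g.id: c for g, c in zip(ligand.proton_groups, ligand.group_coords())}

    mapped = set(hyps[0].as_dict) if hyps else set()
    uppers: list[tuple[np.ndarray, str | None, int, float]] = []
    for r in restraints:
        if r.source != "NOE" or r.bound_type != "upper" or r.resonance is None:
            continue
        if r.resonance in mapped:
            uppers.append((group_coords[r.ligand_group], r.resonance, -1, r.bound))
        elif len(r.candidate_receptor_groups) == 1:
            (m,) = r.candidate_receptor_groups
            uppers.append((group_coords[r.ligand_group], None, methyl_index[m], r.bound))
    if len(uppers) < 2:
        return np.zeros(len(hyps))

    chosen = np.empty((len(hyps), len(uppers)), dtype=int)
    for h, hyp in enumerate(hyps):
        d = hyp.as_dict
        for k, (_, res, fixed, _) in enumerate(uppers):
            chosen[h, k] = fixed if res is None else methyl_index[d[res]]

    scores = np.zeros(len(hyps))
    for p, q in itertools.combinations(range(len(uppers)), 2):
        gp, _, _, up = uppers[p]
        gq, _, _, uq = uppers[q]
        slack = float(np.linalg.norm(gp - gq)) + up + uq
        excess = methyl_dist[chosen[:, p], chosen[:, q]] - slack
        np.maximum(excess, 0.0, out=excess)
        scores += excess**2
    return scores


@dataclass(frozen=True)
class HypothesisResult:
    hypothesis: AssignmentHypothesis
    pose: ComplexPose | None  # None when only pre-screened
    screen_score: float
    fully_optimized: bool

    @property
    def best_target(self) -> float:
        return self.pose.target_value if self.pose is not None else math.inf


@dataclass(frozen=True)
class Nmr2Result:
    ranked: tuple[HypothesisResult, ...]
    assignment: dict[str, str]  # winner's mapping
    ties: tuple[AssignmentHypothesis, ...]  # hypotheses within tie tolerance of the winner
    n_hypotheses: int

    @property
    def winner(self) -> HypothesisResult:
        return self.ranked[0]

    @property
    def ensemble(self) -> tuple[ComplexPose, ...]:
        return tuple(h.pose for h in self.ranked if h.pose is not None)


def run_nmr2(
    restraints: Sequence[DistanceRestraint],
    receptor: ReceptorModel,
    ligand: LigandModel,
    resonances: Sequence[str],
    candidate_sets: Mapping[str, Iterable[str]],
    anchors: Mapping[str, str] | None = None,
    config: EngineConfig | None = None,
    seed: int = 0,
) -> Nmr2Result:
    """Full molecular-replacement run.

    Hypotheses are enumerated, cheaply pre-screened by a pose-free
    violation lower bound, and the most promising ``max_full_opt`` (all
    zero-score ones at minimum, up to the cap) fully optimised.  The
    ranking is by best pose target value, ties broken by the hypothesis
    serialization for reproducibility; the winner's mapping is reported
    as the inferred methyl assignment.
    """
    config = config or EngineConfig()
    anchors = dict(anchors or {})
    hyps = list(
        enumerate_assignments(resonances, candidate_sets, anchors, cap=config.max_hypotheses)
    )
    if not hyps:
        raise ValueError("no assignment hypothesis is consistent with the candidate sets")

    if config.prescreen and len(hyps) > config.max_full_opt:
        batch = _batch_prescreen(hyps, restraints, receptor, ligand)
        scored = [
            (float(s), h.serialization(), h) for s, h in zip(batch, hyps)
        ]
        scored.sort(key=lambda x: (x[0], x[1]))
        n_zero = sum(1 for s, _, _ in scored if s == 0.0)
        n_opt = min(max(config.max_full_opt, n_zero), len(scored))
        if n_zero > config.max_full_opt:
            logger.warning(
                "%d hypotheses pass the pre-screen (cap %d); optimising all of them",
                n_zero,
                config.max_full_opt,
            )
    else:
        scored = [(0.0, h.serialization(), h) for h in hyps]
        scored.sort(key=lambda x: x[1])
        n_opt = len(scored)

    results: list[HypothesisResult] = []
    for idx, (score, _, hyp) in enumerate(scored):
        if idx < n_opt:
            ev = TargetEvaluator(restraints, receptor, ligand, hyp, config.weights)
            pose = optimize_pose(
                hyp,
                restraints,
                receptor,
                ligand,
                config.schedule,
                seed=int(np.random.SeedSequence([seed, idx]).generate_state(1)[0]),
                weights=config.weights,
                _evaluator=ev,
            )
            results.append(HypothesisResult(hyp, pose, score, True))
        else:
            results.append(HypothesisResult(hyp, None, score, False))

    results.sort(key=lambda h: (h.best_target, h.screen_score, h.hypothesis.serialization()))
    if not results[0].fully_optimized:
        raise RuntimeError("all hypotheses failed optimisation")
    best = results[0].best_target
    ties = tuple(
        r.hypothesis
        for r in results
        if r.fully_optimized and abs(r.best_target - best) <= config.tie_tolerance
    )
    if len(ties) > 1:
        logger.info("%d hypotheses tie at target %.3g", len(ties), best)
    kept = tuple(results[: max(config.keep_top, 1)]) + tuple(
        r for r in results[max(config.keep_top, 1):] if not r.fully_optimized
    )
    return Nmr2Result(
        ranked=kept,
        assignment=results[0].hypothesis.as_dict,
        ties=ties,
        n_hypotheses=len(hyps),
    )


# ---------------------------------------------------------------------------
# Backbone-restrained refinement
# ---------------------------------------------------------------------------


def refine_backbone_restrained(
    pose: ComplexPose,
    receptor: ReceptorModel,
    restraints: Sequence[DistanceRestraint],
    ligand: LigandModel,
    hypothesis: AssignmentHypothesis | None = None,
    *,
    loop_residues: Sequence[int] = (),
    force_constant: float = 10.0,
    weights: tuple[float, float, float] = (1.0, 1.0, 1.0),
) -> tuple[ReceptorModel, TargetFunctionReport]:
    """Cartesian minimisation allowing limited receptor-loop motion.

    Minimises the restraint target (ligand fixed at ``pose``) plus
    harmonic positional terms ``k |x - x0|^2`` on the atoms of the
    selected loop residues; all other receptor atoms stay fixed.  A
    simplified vacuum analog of an explicit-solvent refinement.  If the
    minimisation fails to improve the objective, the input receptor is
    returned unchanged with a warning.
    """
    if not loop_residues:
        ev = TargetEvaluator(restraints, receptor, ligand, hypothesis, weights)
        return receptor, ev.report(pose.ligand_coords)
    loop_set = set(loop_residues)
    movable = [i for i, rn in enumerate(receptor.residue_numbers) if rn in loop_set]
    if not movable:
        raise ValueError(f"no receptor atoms in loop residues {sorted(loop_set)}")
    x0 = receptor.coords[movable].copy()
    methyl_res = [m.residue_number for m in receptor.methyl_groups]
    # toy receptors carry one atom per methyl; map moved atoms onto methyls by residue
    atom_of_methyl = {}
    for k, m in enumerate(receptor.methyl_groups):
        for i in movable:
            if (
                receptor.residue_numbers[i] == m.residue_number
                and receptor.atom_names[i] == m.atom_name
            ):
                atom_of_methyl[k] = i

    def rebuild(flat: np.ndarray) -> ReceptorModel:
        coords = receptor.coords.copy()
        coords[movable] = flat.reshape(-1, 3)
        mcoords = receptor.methyl_coords
        for k, i in atom_of_methyl.items():
            mcoords[k] = coords[i]
        return receptor.with_coords(coords, mcoords)

    def objective(flat: np.ndarray) -> float:
        rec = rebuild(flat)
        ev = TargetEvaluator(restraints, rec, ligand, hypothesis, weights)
        restraint_term = ev.total(pose.ligand_coords)
        harmonic = force_constant * float(np.sum((flat.reshape(-1, 3) - x0) ** 2))
        return restraint_term + harmonic

    start = x0.ravel().copy()
    f0 = objective(start)
    res = minimize(objective, start, method="L-BFGS-B", options={"maxiter": 500})
    if not np.all(np.isfinite(res.x)) or res.fun > f0 + 1e-12:
        logger.warning("backbone refinement failed to improve (%.3g -> %.3g); reverting", f0, res.fun)
        ev = TargetEvaluator(restraints, receptor, ligand, hypothesis, weights)
        return receptor, ev.report(pose.ligand_coords)
    refined = rebuild(np.asarray(res.x))
    ev = TargetEvaluator(restraints, refined, ligand, hypothesis, weights)
    return refined, ev.report(pose.ligand_coords)


def ligand_rmsd(coords_a: np.ndarray, coords_b: np.ndarray, heavy_only_elements: Sequence[str] | None = None) -> float:
    """RMSD between two ligand coordinate sets in the receptor frame (no fit)."""
    a = np.asarray(coords_a, dtype=float)
    b = np.asarray(coords_b, dtype=float)
    if heavy_only_elements is not None:
        keep = np.array([e != "H" for e in heavy_only_elements], dtype=bool)
        a, b = a[keep], b[keep]
    if a.shape != b.shape:
        raise ValueError("coordinate sets differ in shape")
    return float(np.sqrt(np.mean(np.sum((a - b) ** 2, axis=1))))
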