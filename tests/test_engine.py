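import itertools
import math

import numpy as np
import pytest

from nmr2kit.engine import (
    HARD_SPHERE_RADII,
    OVERLAP_FACTOR,
    AnnealingSchedule,
    AssignmentHypothesis,
    ComplexPose,
    EngineConfig,
    TooManyHypothesesError,
    count_assignments,
    enumerate_assignments,
    ligand_rmsd,
    optimize_pose,
    place_ligand,
    refine_backbone_restrained,
    run_nmr2,
    target_function,
)
from nmr2kit.models import LigandModel, LigandProtonGroup, MethylGroup, ReceptorModel
from nmr2kit.restraints import DistanceRestraint
from nmr2kit.synthetic import benchmark_engine_config


def brute_force_count(resonances, candidate_sets, anchors=None):
    anchors = anchors or {}
    methyls = sorted({m for s in candidate_sets.values() for m in s} | set(anchors.values()))
    n = 0
    for perm in itertools.permutations(methyls, len(resonances)):
        ok = True
        for r, m in zip(resonances, perm):
            if r in anchors:
                if anchors[r] != m:
                    ok = False
                    break
            elif m not in candidate_sets[r]:
                ok = False
                break
        if ok:
            n += 1
    return n


class TestEnumeration:
    def test_single_resonance_single_candidate(self):
        hyps = list(enumerate_assignments(["R1"], {"R1": {"m1"}}))
        assert len(hyps) == 1
        assert hyps[0].as_dict == {"R1": "m1"}

    def test_three_over_four_shared(self):
        cands = {f"R{i}": {"a", "b", "c", "d"} for i in range(3)}
        hyps = list(enumerate_assignments([f"R{i}" for i in range(3)], cands))
        assert len(hyps) == 24  # 4*3*2

    def test_anchor_fixes_one(self):
        cands = {f"R{i}": {"a", "b", "c", "d"} for i in range(3)}
        hyps = list(
            enumerate_assignments([f"R{i}" for i in range(3)], cands, anchors={"R0": "a"})
        )
        assert len(hyps) == 6  # anchored, remaining 2 resonances over 3 free methyls
        assert all(h.as_dict["R0"] == "a" for h in hyps)

    def test_injectivity(self):
        cands = {"R1": {"a", "b"}, "R2": {"a", "b"}}
        for h in enumerate_assignments(["R1", "R2"], cands):
            assert len(set(h.as_dict.values())) == 2

    @pytest.mark.parametrize("n_res,n_met", [(2, 3), (3, 3), (4, 5), (6, 6)])
    def test_count_matches_brute_force(self, n_res, n_met, rng):
        resonances = [f"R{i}" for i in range(n_res)]
        methyls = [f"m{i}" for i in range(n_met)]
        cands = {
            r: set(rng.choice(methyls, size=rng.integers(1, n_met + 1), replace=False))
            for r in resonances
        }
        expect = brute_force_count(resonances, cands)
        if expect == 0:
            return
        assert count_assignments(resonances, cands) == expect
        assert len(list(enumerate_assignments(resonances, cands))) == expect

    def test_cap_raises(self):
        cands = {f"R{i}": set(f"m{j}" for j in range(8)) for i in range(6)}
        with pytest.raises(TooManyHypothesesError):
            count_assignments([f"R{i}" for i in range(6)], cands, cap=100)

    def test_non_injective_rejected(self):
        with pytest.raises(ValueError):
            AssignmentHypothesis(mapping=(("R1", "m1"), ("R2", "m1")))


def tiny_system(methyl_positions, ligand_positions, classes=None):
    methyls = tuple(
        MethylGroup(
            id=f"LEU{101 + k}:CD1",
            residue_number=101 + k,
            residue_name="LEU",
            atom_name="CD1",
            residue_class=(classes or ["ILV"] * len(methyl_positions))[k],
            coord=tuple(p),
        )
        for k, p in enumerate(methyl_positions)
    )
    receptor = ReceptorModel(
        elements=tuple("C" for _ in methyls),
        atom_names=tuple(m.atom_name for m in methyls),
        residue_numbers=tuple(m.residue_number for m in methyls),
        residue_names=tuple(m.residue_name for m in methyls),
        coords=np.asarray(methyl_positions, dtype=float),
        methyl_groups=methyls,
        pocket_center=(0.0, 0.0, 0.0),
    )
    ligand = LigandModel(
        atom_names=tuple(f"C{k + 1}" for k in range(len(ligand_positions))),
        elements=tuple("C" for _ in ligand_positions),
        coords=np.asarray(ligand_positions, dtype=float),
        proton_groups=tuple(
            LigandProtonGroup(id=f"L{k + 1}", atom_indices=(k,))
            for k in range(len(ligand_positions))
        ),
    )
    return receptor, ligand


def naive_target(pose_coords, restraints, receptor, ligand, hypothesis):
    """Independent straightforward re-implementation, term by term."""
    hyp = hypothesis.as_dict if hypothesis else {}
    methyl = {m.id: np.asarray(m.coord) for m in receptor.methyl_groups}
    gxyz = {
        g.id: np.mean([pose_coords[i] for i in g.atom_indices], axis=0)
        for g in ligand.proton_groups
    }
    total = 0.0
    for r in restraints:
        if r.source == "intraligand":
            d = np.linalg.norm(gxyz[r.ligand_group] - gxyz[r.ligand_partner])
        else:
            if r.resonance in hyp:
                cands = [hyp[r.resonance]]
            else:
                cands = sorted(r.candidate_receptor_groups)
            inv6 = sum(np.linalg.norm(gxyz[r.ligand_group] - methyl[m]) ** -6 for m in cands)
            d = inv6 ** (-1 / 6)
        if r.bound_type == "upper" and d > r.bound:
            total += (d - r.bound) ** 2
        if r.bound_type == "lower" and d < r.bound:
            total += (r.bound - d) ** 2
    for i, ei in enumerate(ligand.elements):
        for j, ej in enumerate(receptor.elements):
            rmin = OVERLAP_FACTOR * (HARD_SPHERE_RADII[ei] + HARD_SPHERE_RADII[ej])
            d = np.linalg.norm(pose_coords[i] - receptor.coords[j])
            if d < rmin:
                total += (rmin - d) ** 2
    return total


class TestTargetFunction:
    def setup_method(self):
        self.receptor, self.ligand = tiny_system(
            [(6, 0, 0), (0, 6, 0), (0, 0, 6), (-6, 0, 0)],
            [(1, 0, 0), (0, 1.8, 0), (0, 0, 2.2)],
        )
        self.hyp = AssignmentHypothesis.from_dict(
            {"R1": "LEU101:CD1", "R2": "LEU102:CD1"}
        )

    def upper(self, lig, res, bound):
        return DistanceRestraint(
            ligand_group=lig,
            candidate_receptor_groups=frozenset({"LEU101:CD1", "LEU102:CD1"}),
            bound_type="upper",
            bound=bound,
            source="NOE",
            resonance=res,
        )

    def test_satisfied_is_zero(self):
        pose = ComplexPose((0.0,) * 6, self.ligand.coords, 0.0)
        rep = target_function(
            pose, [self.upper("L1", "R1", 12.0)], self.receptor, self.ligand, self.hyp
        )
        assert rep.total == 0.0

    def test_single_violation_squared(self):
        # methyl at (6,0,0), ligand group L1 at (1,0,0): d = 5.0, u = 4.0 -> 1.0
        pose = ComplexPose((0.0,) * 6, self.ligand.coords, 0.0)
        rep = target_function(
            pose, [self.upper("L1", "R1", 4.0)], self.receptor, self.ligand, self.hyp
        )
        assert rep.total == pytest.approx(1.0, abs=1e-12)
        assert rep.upper_violation_sum == pytest.approx(1.0, abs=1e-12)

    def test_matches_naive_oracle_on_random_poses(self, rng):
        restraints = [
            self.upper("L1", "R1", 4.0),
            self.upper("L2", "R2", 3.5),
            DistanceRestraint(
                ligand_group="L3",
                candidate_receptor_groups=frozenset({"LEU103:CD1"}),
                bound_type="lower",
                bound=3.0,
                source="anti-NOE",
                resonance="R3",
            ),
            DistanceRestraint(
                ligand_group="L1",
                bound_type="upper",
                bound=2.0,
                source="intraligand",
                ligand_partner="L2",
            ),
        ]
        hyp = AssignmentHypothesis.from_dict(
            {"R1": "LEU101:CD1", "R2": "LEU102:CD1", "R3": "LEU103:CD1"}
        )
        for _ in range(100):
            coords = self.ligand.coords + rng.normal(scale=2.0, size=(3, 3))
            pose = ComplexPose((0.0,) * 6, coords, 0.0)
            rep = target_function(pose, restraints, self.receptor, self.ligand, hyp)
            expect = naive_target(coords, restraints, self.receptor, self.ligand, hyp)
            assert rep.total == pytest.approx(expect, abs=1e-9)

    def test_unknown_group_raises(self):
        pose = ComplexPose((0.0,) * 6, self.ligand.coords, 0.0)
        bad = DistanceRestraint(
            ligand_group="NOPE",
            candidate_receptor_groups=frozenset({"LEU101:CD1"}),
            bound_type="upper",
            bound=5.0,
            source="NOE",
            resonance="R1",
        )
        with pytest.raises(KeyError):
            target_function(pose, [bad], self.receptor, self.ligand, self.hyp)

    def test_ambiguous_r6_sum_shortens_effective_distance(self):
        pose = ComplexPose((0.0,) * 6, self.ligand.coords, 0.0)
        amb = DistanceRestraint(
            ligand_group="L1",
            candidate_receptor_groups=frozenset({"LEU101:CD1", "LEU104:CD1"}),
            bound_type="upper",
            bound=4.0,
            source="NOE",
            resonance="RX",  # not in hypothesis -> r^-6 sum over both candidates
        )
        rep = target_function(pose, [amb], self.receptor, self.ligand, None)
        d_eff = (5.0**-6 + 7.0**-6) ** (-1 / 6)
        assert rep.per_restraint[0] == pytest.approx(d_eff - 4.0, abs=1e-9)


class TestPlaceLigand:
    def test_identity_params(self):
        _, ligand = tiny_system([(6, 0, 0)], [(0, 0, 0), (1.5, 0, 0)])
        assert np.allclose(place_ligand(ligand, np.zeros(6)), ligand.coords)

    def test_rigid_motion_preserves_internal_distances(self, rng):
        _, ligand = tiny_system([(6, 0, 0)], [(0, 0, 0), (1.5, 0, 0), (0, 1.5, 1.0)])
        params = rng.normal(size=6)
        moved = place_ligand(ligand, params)
        d0 = np.linalg.norm(ligand.coords[0] - ligand.coords[2])
        d1 = np.linalg.norm(moved[0] - moved[2])
        assert d1 == pytest.approx(d0, rel=1e-12)


class TestOptimizePose:
    def make_problem(self):
        rng = np.random.default_rng(99)
        methyls = rng.normal(size=(6, 3))
        methyls = 6.0 * methyls / np.linalg.norm(methyls, axis=1, keepdims=True)
        lig = np.array([(0.5, 0, 0), (0, 1.6, 0), (-1.2, -0.4, 0.8), (0.6, 0.2, -1.4)])
        receptor, ligand = tiny_system(methyls, lig)
        restraints = []
        for i, g in enumerate(ligand.proton_groups):
            for m in receptor.methyl_groups:
                d = np.linalg.norm(lig[i] - np.asarray(m.coord))
                if d < 6.5:
                    restraints.append(
                        DistanceRestraint(
                            ligand_group=g.id,
                            candidate_receptor_groups=frozenset({m.id}),
                            bound_type="upper",
                            bound=max(d + 0.1, 1.8),
                            source="NOE",
                            resonance=m.id,
                        )
                    )
                elif d > 3.8:
                    restraints.append(
                        DistanceRestraint(
                            ligand_group=g.id,
                            candidate_receptor_groups=frozenset({m.id}),
                            bound_type="lower",
                            bound=3.6,
                            source="anti-NOE",
                            resonance=m.id,
                        )
                    )
        return receptor, ligand, restraints, lig

    def test_recovers_known_pose(self):
        receptor, ligand, restraints, true_coords = self.make_problem()
        pose = optimize_pose(None, restraints, receptor, ligand, seed=7)
        assert pose.target_value < 1e-6
        assert ligand_rmsd(pose.ligand_coords, true_coords) < 1.0

    def test_empty_restraints_scores_zero(self):
        receptor, ligand, _, _ = self.make_problem()
        schedule = AnnealingSchedule(n_restarts=2, n_steps=50)
        pose = optimize_pose(None, [], receptor, ligand, schedule, seed=1)
        assert pose.target_value == 0.0

    def test_infeasible_restraints_positive_floor(self):
        # two methyls 12 A apart, both demanded within 2.0 A of the same
        # ligand proton: infeasible since 12 > 2 + 0 + 2 (triangle bound)
        receptor, ligand = tiny_system([(6, 0, 0), (-6, 0, 0)], [(0, 0, 0)])
        restraints = [
            DistanceRestraint(
                ligand_group="L1",
                candidate_receptor_groups=frozenset({m.id}),
                bound_type="upper",
                bound=2.0,
                source="NOE",
                resonance=m.id,
            )
            for m in receptor.methyl_groups
        ]
        pose = optimize_pose(None, restraints, receptor, ligand, seed=0)
        # exhaustive grid certificate: the best achievable violation occurs on
        # the axis; min over x of (|6-x|-2)^2 + (|6+x|-2)^2 clipped = 2*(4-2)^2... wait
        floor = min(
            max(abs(6 - x) - 2.0, 0.0) ** 2 + max(abs(-6 - x) - 2.0, 0.0) ** 2
            for x in np.linspace(-8, 8, 1601)
        )
        assert pose.target_value >= floor - 1e-9
        assert pose.target_value > 1.0

    def test_deterministic_given_seed(self):
        receptor, ligand, restraints, _ = self.make_problem()
        schedule = AnnealingSchedule(n_restarts=2, n_steps=100)
        a = optimize_pose(None, restraints, receptor, ligand, schedule, seed=5)
        b = optimize_pose(None, restraints, receptor, ligand, schedule, seed=5)
        assert a.params == b.params
        assert a.target_value == b.target_value

    def test_adding_satisfied_restraint_never_worsens(self):
        receptor, ligand, restraints, true_coords = self.make_problem()
        schedule = AnnealingSchedule(n_restarts=3, n_steps=150)
        base = optimize_pose(None, restraints, receptor, ligand, schedule, seed=2)
        extra = DistanceRestraint(
            ligand_group="L1",
            candidate_receptor_groups=frozenset({receptor.methyl_groups[0].id}),
            bound_type="upper",
            bound=50.0,  # satisfied everywhere in the pocket
            source="NOE",
            resonance="EXTRA",
        )
        augmented = optimize_pose(
            None, restraints + [extra], receptor, ligand, schedule, seed=2
        )
        assert augmented.target_value <= base.target_value + 1e-6


class TestRunNmr2:
    def test_benchmark_recovery(self, benchmark):
        res = run_nmr2(
            benchmark.restraints,
            benchmark.receptor,
            benchmark.ligand,
            benchmark.resonances,
            benchmark.candidate_sets,
            benchmark.anchors,
            benchmark_engine_config(),
            seed=0,
        )
        assert res.assignment == benchmark.truth.assignment
        assert ligand_rmsd(res.winner.pose.ligand_coords, benchmark.truth.pose) < 1.0
        assert res.winner.best_target < 1e-3  # noise-free by construction

    def test_ranking_deterministic(self, benchmark):
        cfg = benchmark_engine_config()
        a = run_nmr2(
            benchmark.restraints, benchmark.receptor, benchmark.ligand,
            benchmark.resonances, benchmark.candidate_sets, benchmark.anchors, cfg, seed=11,
        )
        b = run_nmr2(
            benchmark.restraints, benchmark.receptor, benchmark.ligand,
            benchmark.resonances, benchmark.candidate_sets, benchmark.anchors, cfg, seed=11,
        )
        assert [r.hypothesis.serialization() for r in a.ranked] == [
            r.hypothesis.serialization() for r in b.ranked
        ]
        assert a.winner.pose.params == b.winner.pose.params

    def test_symmetric_methyls_tie(self):
        # two geometrically equivalent candidates -> explicit tie
        receptor, ligand = tiny_system(
            [(6, 0, 0), (-6, 0, 0)], [(0, 0, 0)], classes=["ILV", "ILV"]
        )
        restraints = [
            DistanceRestraint(
                ligand_group="L1",
                candidate_receptor_groups=frozenset(m.id for m in receptor.methyl_groups),
                bound_type="upper",
                bound=7.0,
                source="NOE",
                resonance="R1",
            )
        ]
        cfg = EngineConfig(schedule=AnnealingSchedule(n_restarts=2, n_steps=100))
        res = run_nmr2(
            restraints,
            receptor,
            ligand,
            ["R1"],
            {"R1": {m.id for m in receptor.methyl_groups}},
            {},
            cfg,
            seed=0,
        )
        assert len(res.ties) == 2

    def test_all_infeasible_still_reports(self):
        receptor, ligand = tiny_system([(6, 0, 0), (-6, 0, 0)], [(0, 0, 0)])
        restraints = [
            DistanceRestraint(
                ligand_group="L1",
                candidate_receptor_groups=frozenset({m.id}),
                bound_type="upper",
                bound=2.0,
                source="NOE",
                resonance=f"R{k}",
            )
            for k, m in enumerate(receptor.methyl_groups)
        ]
        cfg = EngineConfig(schedule=AnnealingSchedule(n_restarts=2, n_steps=80))
        res = run_nmr2(
            restraints,
            receptor,
            ligand,
            ["R0", "R1"],
            {"R0": {receptor.methyl_groups[0].id}, "R1": {receptor.methyl_groups[1].id}},
            {},
            cfg,
            seed=0,
        )
        assert res.winner.best_target > 1.0  # flagged by strictly positive floor


class TestBackboneRefinement:
    def make_refinement_problem(self, displace=0.0):
        receptor, ligand = tiny_system(
            [(4, 0, 0), (0, 4, 0), (0, 0, 4), (-4, 0, 0)], [(1, 0, 0), (0, 1, 0)]
        )
        # restraint satisfied exactly at the undisplaced geometry
        restraints = [
            DistanceRestraint(
                ligand_group="L1",
                candidate_receptor_groups=frozenset({"LEU101:CD1"}),
                bound_type="upper",
                bound=3.0,
                source="NOE",
                resonance="R1",
            )
        ]
        hyp = AssignmentHypothesis.from_dict({"R1": "LEU101:CD1"})
        if displace:
            coords = receptor.coords.copy()
            coords[0, 0] += displace  # move loop methyl away from the ligand
            mcoords = receptor.methyl_coords
            mcoords[0, 0] += displace
            receptor = receptor.with_coords(coords, mcoords)
        pose = ComplexPose((0.0,) * 6, ligand.coords, 0.0)
        return receptor, ligand, restraints, hyp, pose

    def test_no_violations_no_motion(self):
        receptor, ligand, restraints, hyp, pose = self.make_refinement_problem()
        refined, rep = refine_backbone_restrained(
            pose, receptor, restraints, ligand, hyp, loop_residues=[101], force_constant=1.0
        )
        assert np.max(np.abs(refined.coords - receptor.coords)) < 0.05
        assert rep.total == pytest.approx(0.0, abs=1e-9)

    def test_displaced_loop_moves_toward_truth(self):
        receptor, ligand, restraints, hyp, pose = self.make_refinement_problem(displace=2.0)
        before = target_function(pose, restraints, receptor, ligand, hyp).total
        refined, rep = refine_backbone_restrained(
            pose, receptor, restraints, ligand, hyp, loop_residues=[101], force_constant=0.05
        )
        assert rep.total < before
        # loop methyl moved back toward the restraint-satisfying position
        assert refined.coords[0, 0] < receptor.coords[0, 0]

    def test_stiff_spring_limit_freezes_backbone(self):
        receptor, ligand, restraints, hyp, pose = self.make_refinement_problem(displace=2.0)
        refined, _ = refine_backbone_restrained(
            pose, receptor, restraints, ligand, hyp, loop_residues=[101], force_constant=1e9
        )
        assert np.max(np.abs(refined.coords - receptor.coords)) < 1e-4

    def test_unknown_loop_rejected(self):
        receptor, ligand, restraints, hyp, pose = self.make_refinement_problem()
        with pytest.raises(ValueError):
            refine_backbone_restrained(
                pose, receptor, restraints, ligand, hyp, loop_residues=[999]
            )
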