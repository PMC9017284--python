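import itertools
import logging

import pytest

from nmr2kit.buildup import CrossRelaxFit
from nmr2kit.relaxation import sigma_from_distance
from nmr2kit.restraints import (
    BRD4_PROTOCOL,
    TRIM24_PROTOCOL,
    DistanceRestraint,
    InfeasibleClassError,
    NotAntiNoeError,
    ProtonGroup,
    VisibilityTable,
    apply_residue_classes,
    build_anti_noe,
    build_restraint_set,
    calibrate_upper_limit,
    count_protein_ligand,
    make_intraligand_restraint,
    pair_prochirals,
    strong_sigma_threshold,
)


def accepted_fit(distance, gi="L1", gj="M1"):
    return CrossRelaxFit(gi, gj, sigma=-0.1, fit_quality=0.01, accepted=True, distance=distance)


LIG_H = ProtonGroup("L1", "ligand-proton", 1)
LIG_ME = ProtonGroup("L2", "ligand-methyl", 3)
REC_ME = ProtonGroup("M1", "receptor-methyl", 3)


class TestUpperLimitCalibration:
    def test_single_ligand_proton_floor_5p5(self):
        r = calibrate_upper_limit(accepted_fit(3.1), ligand_is_methyl=False, receptor_is_methyl=True)
        assert r.bound == 5.5
        assert r.bound_type == "upper" and r.source == "NOE"

    def test_two_methyls_floor_6p5(self):
        r = calibrate_upper_limit(accepted_fit(4.0), ligand_is_methyl=True, receptor_is_methyl=True)
        assert r.bound == 6.5

    def test_fitted_distance_beyond_floor_kept(self):
        r = calibrate_upper_limit(accepted_fit(7.0), ligand_is_methyl=False, receptor_is_methyl=True)
        assert r.bound == 7.0

    def test_no_lower_limit_emitted(self):
        r = calibrate_upper_limit(accepted_fit(3.1), False, True)
        assert r.bound_type == "upper"

    def test_rejected_fit_refused(self):
        bad = CrossRelaxFit("L1", "M1", -0.1, fit_quality=0.9, accepted=False)
        with pytest.raises(ValueError, match="rejected"):
            calibrate_upper_limit(bad, False, True)

    def test_tight_protocol_scales_distance(self):
        r = calibrate_upper_limit(
            accepted_fit(4.0), False, True, protocol=TRIM24_PROTOCOL
        )
        assert r.bound == pytest.approx(4.0 * 1.125 + 0.3)

    def test_multiplicity_correction_via_context(self, ctx):
        # dividing sigma by 3 before conversion lengthens the distance by 3^(1/6)
        sigma = sigma_from_distance(3.0, ctx)
        fit = CrossRelaxFit("L1", "M1", sigma, 0.01, accepted=True, distance=3.0)
        r = calibrate_upper_limit(
            fit, False, True, protocol=TRIM24_PROTOCOL, ctx=ctx, source_multiplicity=3
        )
        assert r.bound == pytest.approx(3.0 * 3 ** (1 / 6) * 1.125 + 0.3, rel=1e-9)


class TestAntiNoe:
    vis = VisibilityTable([("L1", "M2"), ("L2", "M3"), ("M1", "L3")])

    def test_one_methyl_gives_3p0(self):
        r = build_anti_noe(LIG_H, REC_ME, self.vis)
        assert r is not None
        assert r.bound == 3.0 and r.bound_type == "lower" and r.source == "anti-NOE"

    def test_two_methyls_gives_3p6(self):
        r = build_anti_noe(LIG_ME, REC_ME, self.vis)
        assert r.bound == 3.6

    def test_partner_without_other_noes_gives_none(self):
        lonely = ProtonGroup("M9", "receptor-methyl", 3)
        assert build_anti_noe(LIG_H, lonely, self.vis) is None

    def test_visible_pair_rejected(self):
        lig = ProtonGroup("L1", "ligand-proton", 1)
        partner = ProtonGroup("M2", "receptor-methyl", 3)
        with pytest.raises(NotAntiNoeError):
            build_anti_noe(lig, partner, self.vis)

    def test_protocol_without_anti_noes(self):
        assert build_anti_noe(LIG_H, REC_ME, self.vis, protocol=TRIM24_PROTOCOL) is None

    def test_receptor_side_becomes_resonance(self):
        r = build_anti_noe(REC_ME, LIG_H, self.vis)
        assert r.ligand_group == "L1" and r.resonance == "M1"


class TestProchiralPairing:
    def test_single_mutual_pair(self):
        pairing = pair_prochirals([("A", "B", 5.0)], strong_threshold=1.0)
        assert pairing.pairs == frozenset({frozenset({"A", "B"})})

    def test_empty(self):
        assert pair_prochirals([], strong_threshold=1.0).pairs == frozenset()

    def test_three_geminal_pairs_recovered(self, ctx):
        # 6 resonances from 3 geminal pairs (~1.8 A apart) plus weaker
        # inter-residue contacts; generating pairs must be recovered exactly
        geminal = abs(sigma_from_distance(1.8, ctx))
        weak = abs(sigma_from_distance(3.8, ctx))
        peaks = [
            ("A1", "A2", geminal),
            ("B1", "B2", geminal * 1.1),
            ("C1", "C2", geminal * 0.9),
            ("A1", "B1", weak),
            ("B2", "C1", weak * 1.2),
            ("A2", "C2", weak),
        ]
        pairing = pair_prochirals(peaks, strong_threshold=strong_sigma_threshold(ctx))
        assert pairing.pairs == frozenset(
            {frozenset({"A1", "A2"}), frozenset({"B1", "B2"}), frozenset({"C1", "C2"})}
        )

    def test_each_resonance_at_most_once(self):
        peaks = [("A", "B", 5.0), ("B", "C", 4.0), ("C", "D", 3.0)]
        pairing = pair_prochirals(peaks, strong_threshold=1.0)
        assert pairing.pairs == frozenset({frozenset({"A", "B"}), frozenset({"C", "D"})})
        assert pairing.partner_of("B") == "A"
        assert pairing.partner_of("Z") is None


class TestResidueClasses:
    inventory = {
        "ALA101:CB": "Ala",
        "ALA102:CB": "Ala",
        "THR103:CG2": "Thr",
        "LEU104:CD1": "ILV",
        "LEU104:CD2": "ILV",
        "ILE105:CD1": "ILV",
    }

    def test_thr_anchor_becomes_singleton(self):
        groups = [ProtonGroup("M1", "receptor-methyl", 3, residue_class="Thr")]
        sets = apply_residue_classes(groups, self.inventory)
        assert sets["M1"] == frozenset({"THR103:CG2"})

    def test_unknown_class_keeps_everything(self):
        groups = [ProtonGroup("M1", "receptor-methyl", 3, residue_class="unknown")]
        sets = apply_residue_classes(groups, self.inventory)
        assert sets["M1"] == frozenset(self.inventory)

    def test_ala_class_matches_brute_force(self):
        groups = [ProtonGroup("M1", "receptor-methyl", 3, residue_class="Ala")]
        sets = apply_residue_classes(groups, self.inventory)
        brute = frozenset(m for m, c in self.inventory.items() if c == "Ala")
        assert sets["M1"] == brute and len(sets["M1"]) == 2

    def test_infeasible_class_names_resonance(self):
        groups = [ProtonGroup("M7", "receptor-methyl", 3, residue_class="Met")]
        with pytest.raises(InfeasibleClassError, match="M7"):
            apply_residue_classes(groups, self.inventory)

    def test_explicit_assignment_wins(self):
        groups = [
            ProtonGroup(
                "M1", "receptor-methyl", 3, residue_class="ILV", assigned_to="LEU104:CD1"
            )
        ]
        sets = apply_residue_classes(groups, self.inventory)
        assert sets["M1"] == frozenset({"LEU104:CD1"})


def upper(lig, res, bound=5.5, cands=None):
    return DistanceRestraint(
        ligand_group=lig,
        candidate_receptor_groups=frozenset(cands or {res}),
        bound_type="upper",
        bound=bound,
        source="NOE",
        resonance=res,
    )


def lower(lig, res, bound=3.0):
    return DistanceRestraint(
        ligand_group=lig,
        candidate_receptor_groups=frozenset({res}),
        bound_type="lower",
        bound=bound,
        source="anti-NOE",
        resonance=res,
    )


class TestRestraintSet:
    def test_brd4_counts_39_plus_37_is_76(self):
        noes = [upper(f"L{i % 8 + 1}", f"M{i + 1}") for i in range(39)]
        antis = [lower(f"L{i % 8 + 1}", f"A{i + 1}") for i in range(37)]
        rs = build_restraint_set(noes, antis)
        assert count_protein_ligand(rs) == 76

    def test_empty(self):
        assert build_restraint_set([], [], []) == []

    def test_duplicates_deduplicated_with_warning(self, caplog):
        noes = [
            upper("L1", "M1"),
            upper("L2", "M2"),
            upper("L3", "M3"),
            upper("L1", "M1"),
            upper("L2", "M2", bound=6.0),
        ]
        with caplog.at_level(logging.WARNING):
            rs = build_restraint_set(noes, [])
        assert len(rs) == 3
        assert "duplicate" in caplog.text
        # tighter upper bound wins
        kept = {r.resonance: r.bound for r in rs}
        assert kept["M2"] == 5.5

    def test_count_conservation(self):
        noes = [upper(f"L{i}", f"M{i}") for i in range(5)]
        antis = [lower(f"L{i}", f"A{i}") for i in range(3)]
        intra = [
            make_intraligand_restraint(
                CrossRelaxFit("L1", "L2", -0.2, 0.01, accepted=True, distance=3.0)
            )
        ]
        rs = build_restraint_set(noes, antis, intra)
        assert len(rs) == 5 + 3 + 1

    def test_anti_noe_bounds_are_exact(self):
        for r in build_restraint_set([], [lower("L1", "M1", 3.0), lower("L2", "M2", 3.6)]):
            assert r.bound in (3.0, 3.6)


class TestRestraintValidation:
    def test_upper_bound_floor(self):
        with pytest.raises(ValueError):
            DistanceRestraint(
                ligand_group="L1",
                candidate_receptor_groups=frozenset({"M1"}),
                bound_type="upper",
                bound=1.0,
            )

    def test_protein_restraint_needs_candidates(self):
        with pytest.raises(ValueError):
            DistanceRestraint(ligand_group="L1", bound_type="upper", bound=5.5)

    def test_prochiral_multiplicities(self):
        for mult in (1, 3, 6):
            ProtonGroup("X", "receptor-methyl", mult)
        with pytest.raises(ValueError):
            ProtonGroup("X", "receptor-methyl", 2)
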