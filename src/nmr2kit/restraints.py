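"""Conversion of fitted NOEs and absent-peak evidence into distance restraints.

Implements the two calibration protocols used for bromodomain systems:

* ``brd4``-style: generous upper-limit tolerance floors (5.5 A when a
  single ligand proton is involved, 6.5 A when two methyl groups are
  involved), no lower limit from visible NOEs, and conservative
  anti-NOE lower limits (3.0 / 3.6 A for one / two methyls).
* ``trim24``-style: tight calibration (fitted distance plus a small
  tolerance), no anti-NOEs.

Also covers prochiral methyl pairing from strong intraresidue
methyl-methyl NOEs and residue-type class constraints on the candidate
receptor methyls of each unassigned resonance.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace
from typing import Iterable, Mapping, Sequence

from .buildup import CrossRelaxFit
from .relaxation import RelaxationContext, distance_from_sigma, sigma_from_distance

__all__ = [
    "ProtonGroup",
    "DistanceRestraint",
    "ProchiralPairing",
    "VisibilityTable",
    "CalibrationProtocol",
    "BRD4_PROTOCOL",
    "TRIM24_PROTOCOL",
    "calibrate_upper_limit",
    "build_anti_noe",
    "pair_prochirals",
    "apply_residue_classes",
    "build_restraint_set",
    "make_intraligand_restraint",
    "strong_sigma_threshold",
    "NotAntiNoeError",
    "InfeasibleClassError",
]

logger = logging.getLogger(__name__)

RESIDUE_TO_CLASS = {
    "ALA": "Ala",
    "THR": "Thr",
    "MET": "Met",
    "ILE": "ILV",
    "LEU": "ILV",
    "VAL": "ILV",
}

#: Hard physical floor for any upper-limit restraint (van der Waals contact).
MIN_UPPER_BOUND = 1.8


class NotAntiNoeError(ValueError):
    """The requested pair has a visible cross peak and is not an anti-NOE."""


class InfeasibleClassError(ValueError):
    """A residue class constraint leaves a resonance with no candidates."""


@dataclass(frozen=True)
class ProtonGroup:
    """A proton or group of equivalent protons referenced by restraints."""

    id: str
    kind: str  # ligand-proton | ligand-methyl | receptor-methyl
    multiplicity: int = 1  # 1, 3, or 6 for a paired prochiral pseudo-group
    residue_class: str = "unknown"  # Met | Thr | Ala | ILV | unknown
    assigned_to: str | None = None  # receptor methyl-group id, anchors only

    def __post_init__(self) -> None:
        if self.kind not in ("ligand-proton", "ligand-methyl", "receptor-methyl"):
            raise ValueError(f"unknown proton-group kind {self.kind!r}")
        if self.multiplicity not in (1, 3, 6):
            raise ValueError(f"multiplicity must be 1, 3 or 6, got {self.multiplicity}")
        if self.assigned_to is not None and self.kind != "receptor-methyl":
            raise ValueError("assigned_to may only be set on receptor methyl groups")

    @property
    def is_methyl(self) -> bool:
        return self.multiplicity >= 3


@dataclass(frozen=True)
class DistanceRestraint:
    """Ambiguous upper- or lower-limit restraint.

    ``resonance`` names the (possibly unassigned) receptor-side
    resonance; ``candidate_receptor_groups`` is the set of receptor
    methyls it may map to (a singleton when assigned).  Intraligand
    restraints have ``ligand_partner`` set instead and an empty
    candidate set.
    """

    ligand_group: str
    candidate_receptor_groups: frozenset = field(default_factory=frozenset)
    bound_type: str = "upper"  # upper | lower
    bound: float = 0.0
    source: str = "NOE"  # NOE | anti-NOE | intraligand
    resonance: str | None = None
    ligand_partner: str | None = None

    def __post_init__(self) -> None:
        if self.bound_type not in ("upper", "lower"):
            raise ValueError(f"bound_type must be upper/lower, got {self.bound_type!r}")
        if self.source not in ("NOE", "anti-NOE", "intraligand"):
            raise ValueError(f"unknown restraint source {self.source!r}")
        if self.source == "intraligand":
            if self.ligand_partner is None:
                raise ValueError("intraligand restraint needs a ligand partner")
        else:
            if not self.candidate_receptor_groups:
                raise ValueError("protein-side restraint needs >= 1 candidate methyl")
        if self.bound_type == "upper" and self.bound < MIN_UPPER_BOUND:
            raise ValueError(f"upper bound {self.bound} below {MIN_UPPER_BOUND} A")

    @property
    def is_ambiguous(self) -> bool:
        return len(self.candidate_receptor_groups) > 1

    def dedup_key(self) -> tuple:
        partner = self.ligand_partner or self.resonance
        return (
            self.ligand_group,
            partner,
            tuple(sorted(self.candidate_receptor_groups)),
            self.bound_type,
        )


@dataclass(frozen=True)
class ProchiralPairing:
    """Unordered resonance-id pairs grouped as geminal methyls."""

    pairs: frozenset  # of frozenset({a, b})

    def __post_init__(self) -> None:
        seen: set[str] = set()
        for pair in self.pairs:
            for member in pair:
                if member in seen:
                    raise ValueError(f"resonance {member} appears in more than one pair")
                seen.add(member)

    def partner_of(self, resonance: str) -> str | None:
        for pair in self.pairs:
            if resonance in pair:
                (other,) = pair - {resonance}
                return other
        return None


class VisibilityTable:
    """Which unordered proton-group pairs yielded visible NOE cross peaks."""

    def __init__(self, visible_pairs: Iterable[tuple[str, str]]):
        self._pairs = {frozenset(p) for p in visible_pairs}

    def is_visible(self, i: str, j: str) -> bool:
        return frozenset((i, j)) in self._pairs

    def has_other_partners(self, group: str, excluding: str) -> bool:
        return any(
            group in pair and excluding not in pair for pair in self._pairs
        )

    def __len__(self) -> int:
        return len(self._pairs)


@dataclass(frozen=True)
class CalibrationProtocol:
    """Protocol variant selecting the calibration and anti-NOE rules."""

    name: str
    single_proton_floor: float = 5.5  # A, one side a single ligand proton
    two_methyl_floor: float = 6.5  # A, both sides methyl groups
    anti_noe_one_methyl: float = 3.0  # A lower limit
    anti_noe_two_methyl: float = 3.6  # A lower limit
    use_floors: bool = True
    use_anti_noes: bool = True
    rel_tolerance: float = 0.125  # tight protocol: bound = d * (1 + rel) + abs
    abs_tolerance: float = 0.3  # A
    intraligand_tolerance: float = 0.5  # A added to intraligand upper limits


BRD4_PROTOCOL = CalibrationProtocol(name="brd4")
TRIM24_PROTOCOL = CalibrationProtocol(name="trim24", use_floors=False, use_anti_noes=False)


def _calibrated_distance(
    fit: CrossRelaxFit,
    ctx: RelaxationContext | None,
    source_multiplicity: int,
) -> float:
    """Distance with the per-group multiplicity correction applied.

    The fitted sigma is divided by the number of equivalent source
    protons before conversion (pseudoatom treatment; a CH3 group pumps
    magnetisation ~3x faster than a single proton at equal distance).
    """
    if ctx is not None:
        return distance_from_sigma(fit.sigma / max(1, source_multiplicity), ctx)
    if fit.distance is None:
        raise ValueError(
            f"fit {fit.group_i}-{fit.group_j} carries no distance and no context was given"
        )
    return fit.distance * max(1, source_multiplicity) ** (1.0 / 6.0)


def calibrate_upper_limit(
    fit: CrossRelaxFit,
    ligand_is_methyl: bool,
    receptor_is_methyl: bool,
    *,
    protocol: CalibrationProtocol = BRD4_PROTOCOL,
    ctx: RelaxationContext | None = None,
    ligand_group: str | None = None,
    resonance: str | None = None,
    candidate_receptor_groups: Iterable[str] | None = None,
    source_multiplicity: int = 1,
) -> DistanceRestraint:
    """Upper-limit restraint from an accepted intermolecular NOE fit.

    With tolerance floors active (brd4-style) the bound is
    ``max(fitted distance, floor)``: 6.5 A when both sides are methyl
    groups, 5.5 A otherwise (single ligand proton involved).  No lower
    limit is ever emitted for a visible NOE.

    ``source_multiplicity`` divides the fitted sigma before conversion
    when peak integrals were *not* normalised per source proton (pass 3
    for a raw CH3-source integral; the default of 1 matches per-group
    normalised integrals such as those from the bundled simulator).
    """
    if not fit.accepted:
        raise ValueError(
            f"fit {fit.group_i}-{fit.group_j} was rejected "
            f"(quality {fit.fit_quality:.3f}); refusing to calibrate"
        )
    d = _calibrated_distance(fit, ctx, source_multiplicity)
    if protocol.use_floors:
        floor = (
            protocol.two_methyl_floor
            if (ligand_is_methyl and receptor_is_methyl)
            else protocol.single_proton_floor
        )
        bound = max(d, floor)
    else:
        bound = max(d * (1.0 + protocol.rel_tolerance) + protocol.abs_tolerance, MIN_UPPER_BOUND)
    lig = ligand_group if ligand_group is not None else fit.group_i
    res = resonance if resonance is not None else fit.group_j
    cands = frozenset(candidate_receptor_groups) if candidate_receptor_groups else frozenset({res})
    return DistanceRestraint(
        ligand_group=lig,
        candidate_receptor_groups=cands,
        bound_type="upper",
        bound=float(bound),
        source="NOE",
        resonance=res,
    )


def build_anti_noe(
    group_i: ProtonGroup,
    group_j: ProtonGroup,
    visibility: VisibilityTable,
    *,
    protocol: CalibrationProtocol = BRD4_PROTOCOL,
    candidate_receptor_groups: Iterable[str] | None = None,
) -> DistanceRestraint | None:
    """Lower-limit restraint from a confidently absent cross peak.

    A missing peak is accepted as an anti-NOE only when both resonances
    show visible NOEs to *other* partners (so absence cannot be blamed
    on broadening or artefacts).  The limit is 3.0 A when one methyl is
    involved and 3.6 A when both sides are methyls.  Returns ``None``
    when the conservative acceptance rule is not met.
    """
    if visibility.is_visible(group_i.id, group_j.id):
        raise NotAntiNoeError(f"pair ({group_i.id}, {group_j.id}) has a visible cross peak")
    if not protocol.use_anti_noes:
        return None
    if not (
        visibility.has_other_partners(group_i.id, excluding=group_j.id)
        and visibility.has_other_partners(group_j.id, excluding=group_i.id)
    ):
        return None
    n_methyl = int(group_i.is_methyl) + int(group_j.is_methyl)
    bound = protocol.anti_noe_two_methyl if n_methyl == 2 else protocol.anti_noe_one_methyl
    lig, rec = (group_i, group_j) if group_j.kind == "receptor-methyl" else (group_j, group_i)
    cands = (
        frozenset(candidate_receptor_groups)
        if candidate_receptor_groups
        else frozenset({rec.id})
    )
    return DistanceRestraint(
        ligand_group=lig.id,
        candidate_receptor_groups=cands,
        bound_type="lower",
        bound=float(bound),
        source="anti-NOE",
        resonance=rec.id,
    )


def strong_sigma_threshold(ctx: RelaxationContext, distance: float = 3.0) -> float:
    """|sigma| of a geminal-range contact; default 3.0 A at the working tau_c."""
    return abs(sigma_from_distance(distance, ctx))


def pair_prochirals(
    protein_protein_peaks: Iterable[tuple[str, str, float]],
    strong_threshold: float,
) -> ProchiralPairing:
    """Group geminal Leu/Val methyls from strong intraresidue NOEs.

    ``protein_protein_peaks`` are ``(resonance_a, resonance_b, strength)``
    records from the protein-protein NOESY (strength = |sigma| or peak
    intensity, consistently with ``strong_threshold``).  Mutually
    strongest partners above the threshold are paired greedily; each
    resonance ends up in at most one pair.
    """
    best: dict[frozenset, float] = {}
    for a, b, strength in protein_protein_peaks:
        if a == b:
            continue
        key = frozenset((a, b))
        best[key] = max(best.get(key, 0.0), abs(strength))
    candidates = sorted(
        ((s, tuple(sorted(k))) for k, s in best.items() if s >= strong_threshold),
        key=lambda x: (-x[0], x[1]),
    )
    used: set[str] = set()
    pairs: set[frozenset] = set()
    for _, (a, b) in candidates:
        if a in used or b in used:
            continue
        pairs.add(frozenset((a, b)))
        used.update((a, b))
    return ProchiralPairing(pairs=frozenset(pairs))


def apply_residue_classes(
    groups: Sequence[ProtonGroup],
    receptor_methyls: Mapping[str, str],
) -> dict[str, frozenset]:
    """Restrict each resonance's candidate methyls by residue-type class.

    ``receptor_methyls`` maps methyl-group id -> residue class (one of
    Met/Thr/Ala/ILV).  Resonances classed ``unknown`` keep the full
    inventory.  A Met- or Thr-classed resonance whose class has exactly
    one member becomes a fixed assignment (singleton candidate set).
    """
    all_methyls = frozenset(receptor_methyls)
    out: dict[str, frozenset] = {}
    for g in groups:
        if g.kind != "receptor-methyl":
            continue
        if g.assigned_to is not None:
            out[g.id] = frozenset({g.assigned_to})
            continue
        if g.residue_class == "unknown":
            out[g.id] = all_methyls
            continue
        cands = frozenset(
            m for m, cls in receptor_methyls.items() if cls == g.residue_class
        )
        if not cands:
            raise InfeasibleClassError(
                f"resonance {g.id} is classed {g.residue_class} but the receptor "
                f"inventory has no methyl of that class"
            )
        out[g.id] = cands
    return out


def make_intraligand_restraint(
    fit: CrossRelaxFit,
    *,
    protocol: CalibrationProtocol = BRD4_PROTOCOL,
    ctx: RelaxationContext | None = None,
    source_multiplicity: int = 1,
) -> DistanceRestraint:
    """Unambiguous upper limit between two ligand proton groups."""
    if not fit.accepted:
        raise ValueError(f"intraligand fit {fit.group_i}-{fit.group_j} was rejected")
    d = _calibrated_distance(fit, ctx, source_multiplicity)
    return DistanceRestraint(
        ligand_group=fit.group_i,
        bound_type="upper",
        bound=float(max(d + protocol.intraligand_tolerance, MIN_UPPER_BOUND)),
        source="intraligand",
        ligand_partner=fit.group_j,
    )


def build_restraint_set(
    noe_restraints: Sequence[DistanceRestraint],
    anti_noe_restraints: Sequence[DistanceRestraint],
    intraligand_restraints: Sequence[DistanceRestraint] = (),
) -> list[DistanceRestraint]:
    """Merge calibrated restraints into the full set, deduplicating.

    One upper limit per accepted intermolecular NOE, one lower limit per
    accepted anti-NOE, one upper limit per intraligand NOE.  Duplicate
    (ligand group, partner, candidate set, bound type) entries are
    dropped with a warning; for duplicates the tighter bound wins.
    """
    merged: dict[tuple, DistanceRestraint] = {}
    n_dropped = 0
    for r in (*noe_restraints, *anti_noe_restraints, *intraligand_restraints):
        key = r.dedup_key()
        if key in merged:
            n_dropped += 1
            prev = merged[key]
            tighter = (
                min(prev.bound, r.bound) if r.bound_type == "upper" else max(prev.bound, r.bound)
            )
            merged[key] = replace(prev, bound=tighter)
            logger.warning("duplicate restraint %s; keeping bound %.2f A", key, tighter)
        else:
            merged[key] = r
    if n_dropped:
        logger.warning("dropped %d duplicate restraint(s)", n_dropped)
    return list(merged.values())


def count_protein_ligand(restraints: Iterable[DistanceRestraint]) -> int:
    """Number of protein-ligand restraints (intraligand excluded)."""
    return sum(1 for r in restraints if r.source in ("NOE", "anti-NOE"))
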