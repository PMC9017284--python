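"""End-to-end orchestration: simulate -> fit -> restraints -> dock.

Each stage reads and writes the documented text formats, so the stages
can be run separately from the CLI or chained in one call.
"""

from __future__ import annotations

import json
import logging
from dataclasses import asdict
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from . import __version__
from .buildup import (
    BuildUpCurve,
    CrossRelaxFit,
    average_diagonal_sides,
    curves_from_table,
    fit_autorelaxation,
    fit_crossrelaxation,
    quality_filter,
    read_peak_table,
    write_peak_table,
)
from .engine import (
    AnnealingSchedule,
    EngineConfig,
    ligand_rmsd,
    run_nmr2,
)
from .io import (
    RunConfig,
    config_hash,
    read_ligand_pdb,
    read_receptor_pdb,
    read_restraints,
    write_ligand_pdb,
    write_pose_ensemble,
    write_receptor_pdb,
    write_restraints,
)
from .relaxation import RelaxationContext
from .restraints import (
    DistanceRestraint,
    ProtonGroup,
    VisibilityTable,
    apply_residue_classes,
    build_anti_noe,
    build_restraint_set,
    calibrate_upper_limit,
    make_intraligand_restraint,
)
from .synthetic import SyntheticComplexSpec, blind_inputs, make_toy_complex, simulate_noesy

logger = logging.getLogger(__name__)


def _write_log(outdir: Path, stage: str, config: RunConfig, seed: int) -> None:
    log = {
        "stage": stage,
        "config_hash": config_hash(config),
        "config": asdict(config),
        "seed": seed,
        "version": __version__,
    }
    (outdir / f"{stage}.log.json").write_text(json.dumps(log, indent=1, default=str))


def simulate_stage(
    spec: SyntheticComplexSpec, outdir, *, n_anchors: int = 2, config: RunConfig | None = None
) -> dict:
    """Generate a toy complex + blinded NOESY tables into ``outdir``."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    receptor, ligand, truth = make_toy_complex(spec)
    peaks, _ = simulate_noesy(receptor, ligand, truth, spec)
    blind = blind_inputs(truth, receptor, ligand, peaks, n_anchors=n_anchors, seed=spec.seed)

    write_receptor_pdb(receptor, outdir / "receptor.pdb")
    write_ligand_pdb(ligand, outdir / "ligand.pdb")
    write_peak_table(blind.peak_table, outdir / "peaks.csv")
    annotations = {
        "resonances": list(blind.resonances),
        "classes": dict(blind.classes),
        "anchors": dict(blind.anchors),
        "ligand_groups": {g.id: g.multiplicity for g in ligand.proton_groups},
        "tau_c": spec.tau_c,
        "field_mhz": spec.field_mhz,
    }
    (outdir / "annotations.json").write_text(json.dumps(annotations, indent=1))
    truth_payload = {
        "assignment": truth.assignment,
        "pose": truth.pose.tolist(),
        "ligand_elements": list(ligand.elements),
        "group_ids": list(truth.group_ids),
        "visible_pairs": [list(p) for p in truth.visible_pairs],
        "invisible_pairs": [list(p) for p in truth.invisible_pairs],
    }
    (outdir / "truth.json").write_text(json.dumps(truth_payload, indent=1))
    if config is not None:
        _write_log(outdir, "simulate", config, spec.seed)
    return annotations


def _paired_curves(curves: Sequence[BuildUpCurve]) -> list[BuildUpCurve]:
    """Average above/below sides of each cross peak when both are present."""
    by_pair: dict[tuple, dict[str, BuildUpCurve]] = {}
    for c in curves:
        if c.is_diagonal:
            continue
        by_pair.setdefault((c.group_i, c.group_j), {})[c.side] = c
    out = []
    for sides in by_pair.values():
        if "above" in sides and "below" in sides:
            out.append(average_diagonal_sides(sides["above"], sides["below"]))
        else:
            out.append(next(iter(sides.values())))
    return out


def fit_stage(
    peaks_path, outdir, *, ctx: RelaxationContext, quality_threshold: float = 0.15,
    config: RunConfig | None = None,
) -> pd.DataFrame:
    """Fit diagonal decays and cross build-ups from a peak table.

    Writes ``autos.csv`` (rho per group) and ``fits.csv`` (sigma,
    quality, distance per cross peak, both sides averaged).
    """
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    df = read_peak_table(peaks_path)
    curves = curves_from_table(df)

    autos = {}
    for c in curves:
        if c.is_diagonal:
            fit = fit_autorelaxation(c)
            autos[c.group_i] = fit
    pd.DataFrame(
        [
            {"group_id": g, "rho": f.rho, "m0": f.m0, "residual_rms": f.residual_rms, "ok": f.ok}
            for g, f in sorted(autos.items())
        ]
    ).to_csv(outdir / "autos.csv", index=False)

    rows = []
    for c in _paired_curves(curves):
        ri = autos.get(c.group_i)
        rj = autos.get(c.group_j)
        rho_i = ri.rho if ri is not None and ri.ok else None
        rho_j = rj.rho if rj is not None and rj.ok else None
        if rho_i is None and rho_j is None:
            logger.warning("no diagonal rate for pair %s-%s; skipped", c.group_i, c.group_j)
            continue
        fit = fit_crossrelaxation(
            c,
            rho_i if rho_i is not None else rho_j,
            rho_j if rho_j is not None else rho_i,
            ctx=ctx,
            threshold=quality_threshold,
        )
        rows.append(
            {
                "group_i": fit.group_i,
                "group_j": fit.group_j,
                "sigma": fit.sigma,
                "fit_quality": fit.fit_quality,
                "accepted": fit.accepted,
                "distance": fit.distance if fit.distance is not None else np.nan,
                "rho_bar": fit.rho_bar,
            }
        )
    fits = pd.DataFrame(rows)
    fits.to_csv(outdir / "fits.csv", index=False)
    if config is not None:
        _write_log(outdir, "fit", config, -1)
    return fits


def _fits_from_frame(fits: pd.DataFrame) -> list[CrossRelaxFit]:
    out = []
    for row in fits.itertuples(index=False):
        dist = None if pd.isna(row.distance) else float(row.distance)
        out.append(
            CrossRelaxFit(
                group_i=row.group_i,
                group_j=row.group_j,
                sigma=float(row.sigma),
                fit_quality=float(row.fit_quality),
                accepted=bool(row.accepted) and dist is not None,
                distance=dist,
                rho_bar=float(row.rho_bar),
            )
        )
    return out


def restraints_stage(
    fits_path,
    peaks_path,
    annotations_path,
    receptor_path,
    outdir,
    *,
    config: RunConfig,
) -> list[DistanceRestraint]:
    """Calibrate restraints from fits + absent-peak evidence; write .upl/.lol."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    fits = _fits_from_frame(pd.read_csv(fits_path))
    annotations = json.loads(Path(annotations_path).read_text())
    receptor = read_receptor_pdb(receptor_path)
    protocol = config.calibration_protocol()
    ctx = RelaxationContext.from_field(config.tau_c, config.field_mhz)

    lig_mult: Mapping[str, int] = annotations["ligand_groups"]
    resonances: Sequence[str] = annotations["resonances"]
    classes: Mapping[str, str] = annotations["classes"]
    anchors: Mapping[str, str] = annotations["anchors"]

    groups: dict[str, ProtonGroup] = {}
    for gid, mult in lig_mult.items():
        groups[gid] = ProtonGroup(
            id=gid, kind="ligand-methyl" if mult >= 3 else "ligand-proton", multiplicity=mult
        )
    for res in resonances:
        groups[res] = ProtonGroup(
            id=res,
            kind="receptor-methyl",
            multiplicity=3,
            residue_class=classes.get(res, "unknown"),
            assigned_to=anchors.get(res),
        )

    inventory = {m.id: m.residue_class for m in receptor.methyl_groups}
    candidate_sets = apply_residue_classes(
        [g for g in groups.values() if g.kind == "receptor-methyl"], inventory
    )

    accepted, _ = quality_filter(fits, config.quality_threshold)
    noe_restraints, intraligand = [], []
    for f in accepted:
        in_i, in_j = f.group_i in lig_mult, f.group_j in lig_mult
        if in_i and in_j:
            intraligand.append(make_intraligand_restraint(f, protocol=protocol, ctx=ctx))
        elif in_i or in_j:
            lig, res = (f.group_i, f.group_j) if in_i else (f.group_j, f.group_i)
            if res not in candidate_sets:
                logger.warning("skipping NOE to unannotated resonance %s", res)
                continue
            noe_restraints.append(
                calibrate_upper_limit(
                    f,
                    ligand_is_methyl=groups[lig].is_methyl,
                    receptor_is_methyl=True,
                    protocol=protocol,
                    ctx=ctx,
                    ligand_group=lig,
                    resonance=res,
                    candidate_receptor_groups=candidate_sets[res],
                )
            )
        # receptor-receptor peaks feed prochiral pairing, not restraints

    peaks = read_peak_table(peaks_path)
    cross = peaks[peaks["group_i"] != peaks["group_j"]]
    visibility = VisibilityTable(
        {(a, b) for a, b in zip(cross["group_i"], cross["group_j"])}
    )
    anti = []
    if protocol.use_anti_noes:
        for lig_id in sorted(lig_mult):
            for res in resonances:
                if visibility.is_visible(lig_id, res):
                    continue
                r = build_anti_noe(
                    groups[lig_id],
                    groups[res],
                    visibility,
                    protocol=protocol,
                    candidate_receptor_groups=candidate_sets.get(res),
                )
                if r is not None:
                    anti.append(r)

    restraint_set = build_restraint_set(noe_restraints, anti, intraligand)
    write_restraints(restraint_set, outdir / "restraints.upl", outdir / "restraints.lol")
    _write_log(outdir, "restraints", config, -1)
    return restraint_set


def dock_stage(
    receptor_path,
    ligand_path,
    upl_path,
    lol_path,
    annotations_path,
    outdir,
    *,
    config: RunConfig,
    truth_path=None,
) -> dict:
    """Run the molecular-replacement engine on calibrated restraints."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    receptor = read_receptor_pdb(
        receptor_path, pocket_center=config.pocket_center, pocket_radius=config.pocket_radius
    ) if config.pocket_center is not None else read_receptor_pdb(receptor_path)
    ligand = read_ligand_pdb(ligand_path)
    restraints = read_restraints(upl_path, lol_path)
    annotations = json.loads(Path(annotations_path).read_text())
    anchors: Mapping[str, str] = annotations["anchors"]

    # only resonances that actually constrain anything are enumerated
    resonances = sorted(
        {r.resonance for r in restraints if r.resonance is not None}
    )
    candidate_sets = {}
    for r in restraints:
        if r.resonance is not None:
            candidate_sets.setdefault(r.resonance, frozenset())
            candidate_sets[r.resonance] = candidate_sets[r.resonance] | r.candidate_receptor_groups

    engine_config = EngineConfig(
        schedule=AnnealingSchedule(n_restarts=config.n_restarts, n_steps=config.n_steps),
        max_full_opt=config.max_full_opt,
    )
    result = run_nmr2(
        restraints,
        receptor,
        ligand,
        resonances,
        candidate_sets,
        {k: v for k, v in anchors.items() if k in set(resonances)},
        engine_config,
        seed=config.seed,
    )

    poses = [h.pose.ligand_coords for h in result.ranked if h.pose is not None]
    write_pose_ensemble(ligand, poses, outdir / "ensemble.pdb")
    report = {
        "assignment": result.assignment,
        "best_target": result.winner.best_target,
        "n_hypotheses": result.n_hypotheses,
        "n_ties": len(result.ties),
        "hypotheses": [
            {
                "mapping": dict(h.hypothesis.mapping),
                "target": h.best_target if h.fully_optimized else None,
                "screen_score": h.screen_score,
            }
            for h in result.ranked
        ],
    }
    if truth_path is not None and Path(truth_path).exists():
        truth = json.loads(Path(truth_path).read_text())
        true_pose = np.asarray(truth["pose"], dtype=float)
        report["rmsd_to_truth"] = ligand_rmsd(
            result.winner.pose.ligand_coords, true_pose, truth.get("ligand_elements")
        )
        restricted_truth = {k: v for k, v in truth["assignment"].items() if k in set(resonances)}
        report["assignment_correct"] = result.assignment == restricted_truth
    (outdir / "result.json").write_text(json.dumps(report, indent=1, default=float))
    _write_log(outdir, "dock", config, config.seed)
    return report


def run_all(
    spec: SyntheticComplexSpec, outdir, *, config: RunConfig | None = None
) -> dict:
    """Full chain on synthetic data; returns the dock report."""
    config = config or RunConfig(tau_c=spec.tau_c, field_mhz=spec.field_mhz, seed=spec.seed)
    outdir = Path(outdir)
    simulate_stage(spec, outdir, config=config)
    ctx = RelaxationContext.from_field(config.tau_c, config.field_mhz)
    fit_stage(
        outdir / "peaks.csv", outdir, ctx=ctx,
        quality_threshold=config.quality_threshold, config=config,
    )
    restraints_stage(
        outdir / "fits.csv",
        outdir / "peaks.csv",
        outdir / "annotations.json",
        outdir / "receptor.pdb",
        outdir,
        config=config,
    )
    return dock_stage(
        outdir / "receptor.pdb",
        outdir / "ligand.pdb",
        outdir / "restraints.upl",
        outdir / "restraints.lol",
        outdir / "annotations.json",
        outdir,
        config=config,
        truth_path=outdir / "truth.json",
    )


def flagship_spec(seed: int = 0) -> SyntheticComplexSpec:
    """Acquisition settings of the flagship end-to-end round trip.

    Short mixing times keep spin-diffusion bias low so the tight
    calibration below stays consistent with the generating geometry.
    """
    return SyntheticComplexSpec(
        seed=seed,
        mixing_times=(0.01, 0.02, 0.03, 0.04, 0.05, 0.06, 0.08, 0.09, 0.10, 0.12),
        detection_threshold=0.003,
    )


def flagship_config(seed: int = 0) -> RunConfig:
    """Protocol + engine settings of the flagship end-to-end round trip."""
    return RunConfig(
        protocol="trim24",
        seed=seed,
        n_restarts=4,
        n_steps=250,
        max_full_opt=12,
        quality_threshold=0.05,
        rel_tolerance=0.0,
        abs_tolerance=0.25,
        use_anti_noes=True,
    )
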