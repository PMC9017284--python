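# nmr2kit

Ligand-pose determination against a known receptor structure from
**unassigned** methyl NOE data, in the molecular-replacement style: every
intermolecular NOE is treated as an ambiguous distance restraint, the
resonance-to-methyl assignment is enumerated as hypotheses, and the
assignment emerges as a byproduct of ranking hypotheses by the target
function of their best ligand pose.

Components:

- `nmr2kit.relaxation` — two-spin dipolar cross-relaxation physics:
  Lorentzian spectral densities (`J(0) = tau_c`), sigma <-> distance
  conversion, isotropic tau_c estimation from 15N R1/R1rho.
- `nmr2kit.buildup` — NOESY build-up fitting: monoexponential diagonal
  decays, the two-spin cross-peak solution
  `-m0 (sigma/Delta) sinh(Delta t) exp(-rho_bar t)`, symmetric-peak
  averaging, and a normalised-residual quality filter that discards
  relay (spin-diffusion) peaks.
- `nmr2kit.restraints` — calibration of ambiguous upper limits
  (tolerance floors 5.5 A single ligand proton / 6.5 A methyl-methyl),
  conservative anti-NOE lower limits (3.0 / 3.6 A, emitted only when
  both resonances show NOEs to other partners), prochiral methyl
  pairing, residue-class candidate restriction.
- `nmr2kit.engine` — hypothesis enumeration (lazy, permanent-counted),
  CYANA-style target function (squared violations + hard-sphere
  repulsion), seeded simulated-annealing pose search, backbone-restrained
  loop refinement, full ranked runs.
- `nmr2kit.synthetic` — toy pocket/ligand generator and a full
  relaxation-matrix NOESY simulator (spin diffusion included) with
  blinding, plus the default ground-truth benchmark.
- `nmr2kit.io` / `nmr2kit.cli` — PDB reading/writing (methyl detection
  from residue templates), CYANA-dialect `.upl`/`.lol` restraint files,
  YAML run configs, and the command line.

## CLI

```sh
nmr2kit simulate --seed 7 --out run/          # synthetic blinded dataset
nmr2kit fit run/peaks.csv --out run/          # build-up fitting
nmr2kit restraints --fits run/fits.csv --peaks run/peaks.csv \
    --annotations run/annotations.json --receptor run/receptor.pdb --out run/
nmr2kit dock --receptor run/receptor.pdb --ligand run/ligand.pdb \
    --upl run/restraints.upl --lol run/restraints.lol \
    --annotations run/annotations.json --truth run/truth.json --out run/
nmr2kit run-all --seed 0 --out run/           # the full chain
```

Every stage writes a `*.log.json` with the config hash, seed and
package version; identical inputs and seeds reproduce bit-identically.

## Notes

- Internal units are SI; distances are Angstrom at API boundaries.
- The quality-filter default (normalised RMS residual <= 0.10 of the
  peak maximum) separates direct peaks (< ~0.03) from constructed
  3-spin relay peaks (> ~0.12); it is configurable everywhere.
- The tau_c estimator treats R1rho as R2 (no exchange term) and assumes
  isotropic tumbling.
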