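# oligorient

Structural refinement machinery for **homo-oligomeric membrane proteins**
restrained by oriented solid-state NMR data, built around the pentameric
state of phospholamban (PLN) as the reference system.

Oriented ssNMR on mechanically aligned membranes measures, per residue, the
¹⁵N chemical shift anisotropy (CSA) and the ¹⁵N–¹H dipolar coupling (DC) —
both functions of how each peptide plane is oriented with respect to the
magnetic field **B₀** (here the lab +z axis, coinciding with the membrane
normal). For an oligomer these observables are intrinsically averaged over
the P identical protomers, and ensemble refinement additionally averages
them over M simulation replicas. This package provides:

* **Forward models.** CSA as `b·σ·bᵀ` with the ¹⁵N shift tensor
  σ = Σₖ δₖₖ eₖeₖᵀ anchored to the peptide plane (principal values
  64.0/76.0/216.9 ppm for non-glycine residues, 46.5/66.3/211.6 ppm for
  glycine; δ₃₃ in-plane, 17° from the N–H bond), and
  DC = ζ_DC (3cos²θ_NH − 1)/2 with ζ_DC = 10.52 kHz.
* **Restraints.** Flat-bottom harmonic penalties
  E = α(|Δ| − ε)² for |Δ| > ε (zero force within experimental error; default
  ε = ±5 ppm CSA, ±0.5 kHz DC), applied to observables averaged over the M
  replicas and, for the combined scheme, also over the P protomers.
  Calibrated force constants per (M, scheme) and a linear equilibration
  ramp are built in. Exact analytic coordinate gradients are provided.
* **A desk-scale restrained sampler.** Metropolis Monte Carlo over rigid
  per-protomer coordinates (TM tilt, azimuth, spin, cytoplasmic tilt,
  in-plane displacement) under a harmonic prior + the averaged restraints,
  sufficient to run the reference-ensemble calibration: a known
  heterogeneous truth generates synthetic data, and restrained sampling
  from a deliberately biased prior must recover the truth's mean topology
  and spread.
* **Ensemble analyses.** Topology angles τ/θ/γ/ω, amide N–H order
  parameters S², per-domain Cα RMSF, an axial pore-radius profiler with
  bottleneck detection, ω-percentile pore contrasts, and Cα PCA with
  porcupine export.
* **Fixtures.** An ideal-geometry pinwheel pentamer builder (α-helical
  protomers, controllable τ/θ, per-replica heterogeneity) used by the test
  suite and as a synthetic-data source.

## Worked example

```sh
# 8-replica heterogeneous pentamer fixture (tilt noise 3 deg, jitter 0.05 A)
oligorient fixtures --replicas 8 --tilt-sigma 3 --jitter 0.05 --seed 11 -o ensemble.pdb

# back-calculate combined (replica+internal) averaged observables
oligorient backcalc ensemble.pdb -o calc.tsv

# topology angles and pore profile
oligorient topology ensemble.pdb -o topo.tsv
oligorient pore ensemble.pdb -o pore.tsv

# scaled-down reference-ensemble calibration at M=16
oligorient calibrate --m-grid 16 --seed 1 -o calib.json
```

prints (among other lines):

```
INFO oligorient: tau 12.83 +- 0.97; theta 98.70 +- 0.94
INFO oligorient: mean pore radius 4.40 A; bottlenecks [(32, 7.71), ..., (50, 1.37)]
INFO oligorient: M16_replica_internal: mean tilt 13.83 (err 1.03), Q_CSA 0.0048
```

The fixture was built at τ = 12.8°, θ = 98.8°: the topology analysis
recovers both within the heterogeneity that was injected. The pore numbers
come from a backbone-only bundle, so they are wider than an all-atom pore;
they narrow monotonically toward the C-terminal end of the helix. The
calibration line says that a 16-replica combined-averaging run, started
from a prior biased at 25° tilt, recovered the 12.8° truth to ~1° with a
CSA Q factor of 0.005 on the synthetic data.

The first back-calculated rows look like

```
residue  kind  value                error
2        CSA   76.94417417764677    5.0
2        DC    -5.169950818873582   0.5
```

— a cytoplasmic residue whose helix lies nearly in the membrane plane:
the CSA sits near the δ₁₁/δ₂₂ edge of the tensor and the DC is negative
(N–H roughly perpendicular to B₀).

## Library use

```python
from oligorient import (PentamerBlueprint, build_ideal_pentamer,
                        ReplicaEnsemble, backcalc_table, average_observables,
                        ObservableTable, RestraintConfig, restraint_energy)

olig = build_ideal_pentamer(PentamerBlueprint(tau_deg=12.8, theta_deg=98.8))
avg = average_observables(backcalc_table(ReplicaEnsemble(replicas=[olig])))
obs = ObservableTable.from_records([(k[0], k[1], v) for k, v in avg.items()])
report = restraint_energy(avg, obs, RestraintConfig.from_table(16))
print(report.total_energy)   # 0.0 — data generated from this structure
```

## Acceptance script

`python scripts/acceptance.py --seed 1 --out results/acceptance.json`
rebuilds a seeded pentamer fixture, back-calculates a CSA observable from
it, configures the 16-replica combined-averaging restraint with its default
force constants, and evaluates the flat-bottom energy for an averaged
deviation exactly 1 ppm past the error bound, writing the resulting energy
(J/mol) to the JSON file.

## Layout

```
src/oligorient/structures.py    ensembles, PDB I/O, pinwheel fixtures
src/oligorient/observables.py   CSA/DC forward models + exact gradients
src/oligorient/restraints.py    flat-bottom restraints, averaging, Q factors
src/oligorient/sampler.py       coarse MC sampler, reference-ensemble calibration
src/oligorient/analysis.py      topology angles, S2, RMSF, pore, PCA
src/oligorient/config.py        YAML config + JSON reports
src/oligorient/cli.py           `oligorient` subcommands
docs/methods.md                 model, conventions, design choices, limits
```
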