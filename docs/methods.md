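# Methods

## Scope and model

The package implements the computational core of oriented-ssNMR ensemble
refinement for homo-oligomeric membrane proteins: forward calculation of
¹⁵N CSA and ¹⁵N–¹H DC from backbone coordinates, flat-bottom harmonic
restraints under two-layer (replica + internal) averaging, a coarse-grained
restrained sampler, and the standard ensemble analyses. The production
setting for this methodology is restrained all-atom MD in an explicit
bilayer; everything here is designed to run on one CPU in minutes, so the
molecular force field and bilayer are replaced by a rigid-helix coarse
model with a harmonic prior. What carries over unchanged is the restraint
machinery itself — the forward models, the averaging, the flat-bottom
potential, its published force constants and the equilibration ramp.

## Conventions

* Lab frame: B₀ ≡ +z ≡ membrane normal. Samples are assumed mechanically
  aligned; the convention is global and fixed.
* Chains map to protomers in order of first appearance; MODEL records map
  to replicas in file order. Observables are matched on residue number
  only, which must be identical across chains (homo-oligomer); a mismatch
  is an error, not a warning.
* Prolines and chain-initial residues carry no observables (no amide H).
  The phospholamban default sequence has P21 and no glycine; the glycine
  tensor branch exists and is tested on synthetic residues.

## Forward models

**CSA.** The ¹⁵N shift tensor is diagonal in a principal-axis frame
anchored to the peptide plane through C′(i−1), N(i), H(i): the δ₂₂ axis is
the plane normal, the δ₃₃ axis lies in-plane at `pas_tilt_deg` (default
17°) from the N–H bond, rotated toward N→C′, and δ₁₁ completes the
right-handed frame. The observed shift is b·σ·bᵀ = Σₖ δₖₖ (eₖ·b)².
Principal values default to 64.0/76.0/216.9 ppm (non-Gly) and
46.5/66.3/211.6 ppm (Gly). No Euler angles are ever constructed — the
frame vectors are used directly, which makes the implementation
convention-proof; both the tilt and the axis assignment are configurable
because the literature convention for the in-plane tilt varies by a few
degrees.

**DC.** DC = ζ_DC (3cos²θ_NH − 1)/2 with ζ_DC = 10.52 kHz, θ_NH the angle
between the N→H unit vector and the field. The bond-length dependence is
not modelled separately: ζ_DC already encodes the standard 1.02 Å bond.
Values are signed by default (the flat-bottom comparison uses the signed
convention); an unsigned report is available in the CLI since PISEMA
magnitudes are commonly tabulated unsigned.

**Gradients.** Exact derivatives of both observables with respect to the
contributing atoms (C′, N, H) are computed by forward-mode Jacobian
propagation through the frame construction (unit-vector and cross-product
differentials), not by finite differences. Central differences serve only
as the independent test oracle; agreement is at the 1e-9 relative level.

## Restraints and averaging

Per observable, E = ramp · α · (|Δ| − ε)² when |Δ| > ε, else 0, where Δ is
the deviation of the *averaged* back-calculated value from the record and
ε its error (defaults ±5 ppm / ±0.5 kHz when a table carries none). The
combined scheme averages over all M·P protomer copies; the pure replica
scheme averages over M per protomer, each protomer compared to the same
record (this keeps the scheme usable on oligomers for calibration
comparisons). The two-layer mean is algebraically the flat mean over M·P,
which the tests verify to 1e-12. Force constants default to the calibrated
table keyed by (M, scheme) — e.g. 25.0 J/(mol·ppm²) and 1000 J/(mol·kHz²)
at M = 16 — and rise linearly from zero over `ramp_steps` sweeps, the
coarse-model analogue of a 20 ns equilibration ramp. The Q factor is
RMS(calc − obs)/RMS(obs) per observable kind (the Cornilescu-style
definition; reports also carry the RMSD and the SD of deviations about
their mean, since "standard deviation" is ambiguous between the two).

## Coarse sampler

Degrees of freedom per protomer per replica: TM tilt, azimuthal placement,
spin about the own helix axis, cytoplasmic tilt, and an in-plane
displacement. Each maps deterministically onto ideal-geometry atoms via
the pinwheel builder (α-helix from ideal internal coordinates φ=−57°,
ψ=−47°, rise ≈1.5 Å, ≈100°/residue). The prior is harmonic per coordinate
(E = ½k(x−c)²) plus an optional harmonic on nearest-neighbour nominal axis
distances (packing). Sampling is Metropolis: one sweep proposes a Gaussian
move for every coordinate of every replica in seeded random order;
restraint energy updates are incremental (only the touched protomer's
observables are recomputed). Monte Carlo was chosen over force-based
dynamics because it avoids committing to masses and thermostats the
production method delegates to the MD engine; the analytic gradients
remain available and tested but are not used for propagation.

With restraints off, each harmonic coordinate samples its Boltzmann
distribution (variance kT/k, verified within 15%).

## Reference-ensemble calibration

The calibration experiment asks: given data generated from a known
heterogeneous ensemble, does restrained sampling started from a wrong
prior recover the truth? Protocol: (1) draw per-protomer TM tilts from
N(τ_truth, σ_het) for M_ref replicas of the ideal pentamer; (2) average
the forward-calculated observables over all copies (combined scheme) to
form the synthetic table; (3) for each (M, scheme) on the grid, run the
ramped restrained sampler from a prior centred 12° away (25° vs 12.8°);
(4) report the recovered mean tilt, the pooled tilt spread, and final Q
factors.

Design choices that required judgement, fixed a priori and then frozen:

* **Synthetic data carry zero error.** Reference data are computed, not
  measured. With the experimental ±5 ppm/±0.5 kHz bounds the restraint
  would exert no force anywhere inside a ≈2°-wide tilt window (the DC
  slope is ≈0.23 kHz/deg), and a one-sided biased prior would always park
  the recovered mean at the window edge — the calibration could not
  resolve anything finer, defeating its purpose. The flat bottom exists to
  absorb experimental error; noise-free data get ε = 0 (pure harmonic).
* **kT = 50 J/mol for calibration.** The coarse prior has no physical
  time or mass, so only k/kT (the 5° tilt fluctuation) is physically
  pinned; the absolute stiffness is free. It is set soft enough that the
  published restraint constants dominate the prior's collective-tilt bias,
  mirroring the production observation that restrained ensembles converge
  to the data regardless of the force field employed. The general-purpose
  sampler default remains kT = 2494 J/mol (300 K).
* **M_ref = 64.** The reference ensemble must itself be converged: with
  16×5 tilt draws the truth's sample mean wanders by ±0.6° (SD), which
  would be confounded with method error.

Under these conditions the M = 16 combined-averaging run recovers the mean
tilt within ~1–1.5° across seeds, with Q_CSA ≈ 0.005 and a retained pooled
tilt spread of ≈0.8 of the prior's 5°. Restraining the replica mean does
not collapse replica diversity — the maximum-entropy property the
averaging scheme is designed to preserve.

## Analyses

* **Topology.** Helix axes are the principal direction of the domain's Cα
  cloud, signed toward increasing residue number. τ and γ are folded to
  [0°, 90°]; θ is reported unfolded in [0°, 180°] because surface-adsorbed
  cytoplasmic helices sit near 99–104°. ω = angle(TM axis, bundle axis) is
  computed in the internal frame and is invariant under any global
  rotation (tested).
* **S².** Standard second-rank tensor average
  S² = (3 Σ_ab ⟨μ_a μ_b⟩² − 1)/2 over frames, computed per
  (residue, protomer) and then averaged over protomers (averaging the
  pooled vectors instead would conflate C5 symmetry with dynamics and
  report S² < 1 for a rigid pentamer).
* **RMSF.** Per domain and protomer, iterative least-squares superposition
  (Kabsch) of the domain Cα onto the refined ensemble mean (≤50
  iterations, 1e-6 Å tolerance), then per-residue fluctuation; computing
  domains independently removes inter-domain rigid motion.
* **Pore.** Axial-slab scan, not a Voronoi channel finder: on a 0.5 Å
  grid along the fitted bundle axis, radius(z) = min over atoms within a
  ±1.5 Å slab of (axial distance − vdW radius), floored at 0. vdW radii:
  N 1.55, C 1.70, O 1.52, H 1.10 Å; hydrogens excluded by default.
  Bottlenecks are local minima of the ensemble-mean profile mapped to the
  residue with the nearest mean Cα height (ties to the lower index).
  Backbone-only fixtures have no side chains, so absolute radii are
  larger than an all-atom pore; profiles and bottleneck ordering are the
  meaningful outputs.
* **PCA.** Frames superposed on the analysed range's Cα, eigendecomposition
  of the 3N×3N covariance, eigenvalues clipped at 0 beyond the rank the
  frame count supports; porcupine vectors are the per-Cα components of a
  chosen eigenvector.

## Synthetic fixtures: what they are and are not

The fixture generator produces ideal-geometry α-helices in an exact C5
pinwheel with controllable τ, θ, per-replica rigid tilt noise and per-atom
jitter. It emulates the topology and averaging structure of the real
system — which is what the restraint and analysis code consumes — but not:
side chains, helix irregularity, termini fraying, the bilayer, or
experimental noise structure. A green test therefore establishes the
correctness of the mathematics and the recovery behaviour of the
restraint protocol within this model class, not the accuracy of any
specific published ensemble.

## Numerical notes

* Degenerate geometry (zero-length N–H, collinear peptide-plane atoms,
  coincident Cα) raises GeometryError rather than returning NaN.
* The flat-bottom energy is C¹ at the boundary (value and first derivative
  both 0); inside it, gradients are exactly zero.
* PDB round trips preserve coordinates to the format's 3-decimal
  precision (≤5e-4 Å); builders are bit-deterministic given a blueprint.
* All randomness flows from one top-level seed through numpy SeedSequence
  spawning; derived seeds stay below 2³¹.

## Known limitations

* The pure-replica averaging scheme on P > 1 oligomers restrains each
  protomer to the same record; whether the original engine implementation
  did this or refused the combination is not documented.
* The coarse sampler cannot bend helices; dynamics within a protomer
  beyond rigid-body motion are out of its model class.
* The pore profiler's axial method will underestimate radii of strongly
  kinked or off-axis channels; it is intentionally a transparent,
  testable approximation.
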