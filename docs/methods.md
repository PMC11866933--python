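# Methods

## The model

`cocomo2` implements a residue-level coarse-grained model for proteins
(disordered and folded) and single-stranded RNA, aimed at
concentration-dependent phase behavior: condensate formation, saturation
concentrations (c_sat), and the energetics that control them. Each amino
acid or nucleotide is a single spherical bead. The total potential is

    U = U_bond + U_ENM + U_angle + U_short-range + U_electrostatic

with, for beads i, j at minimum-image distance r:

- **Bonds** (consecutive beads): `U = 1/2 k_bond (l - l0)^2`, with
  `k_bond = 4184 kJ/(mol nm^2)`, `l0 = 0.38 nm` for proteins (mean
  Calpha-Calpha spacing) and `0.5 nm` for nucleotides.
- **Elastic network** (folded domains): `U = 1/2 k_ENM (r - r0)^2` with
  `k_ENM = 500 kJ/(mol nm^2)` over all intradomain pairs with `|i-j| >= 2`
  and reference distance `r0 <= 0.9 nm`; consecutive pairs are covered by
  the bond term, and no network spring crosses between domains.
- **Angles**: `U = 1/2 k_angle (theta - 180deg)^2`,
  `k_angle = 4.184 kJ/(mol rad^2)` (proteins) / `5.021` (nucleic acids).
- **Short range**: a 10-5 pair potential
  `U = 4 eps_ij [ (sigma_ij/r)^10 - (sigma_ij/r)^5 ]`, zero at
  `sigma_ij = (sigma_i + sigma_j)/2` and with well depth `eps_ij` at
  `r = 2^(1/5) sigma_ij`. Bead diameters come from residue partial
  volumes, `sigma_i = 2 r_i 2^(-1/6)`. The depth is
  `eps_ij = xi_i xi_j (combine(eps_i, eps_j) + eps_mod)` where `eps_i` is
  the category well depth (polar or hydrophobic; nucleotides reuse the
  polar value), `combine` is the geometric mean by default, and `eps_mod`
  adds 0.3 kJ/mol for cation(R/K)-aromatic(F/Y/W) pairs, 0.2 for
  cation-nucleotide pairs and 0.1 for aromatic-aromatic pairs (the last
  only in the second-generation parameter set). Plain truncation at 3 nm.
- **Electrostatics**: a screened (Debye-Hueckel) form
  `U = (A_i A_j + A0_i A0_j) exp(-r/kappa) / r` with `kappa = 1 nm`
  (~100 mM ionic strength). `A_i = q_i sqrt(ke / eps_r)` with
  `ke = 138.935 kJ nm/mol` and `eps_r = 80`, so the charge-charge part is
  the standard Debye-Hueckel energy in water and opposite charges
  attract. The `A0` amplitudes add a weak, always-repulsive solvation
  term per residue category. Charges: Arg/Lys +1, Asp/Glu -1, His and
  termini neutral, one -1 per nucleotide. Same 3 nm truncation;
  consecutive (bonded) bead pairs are excluded from all nonbonded terms.

Two parameter generations ship as defaults (`default_params(version)`):

| parameter            | gen 1 (cocomo) | gen 2 (cocomo2) |
|----------------------|---------------|-----------------|
| eps_polar            | 0.40 kJ/mol   | 0.176 kJ/mol    |
| eps_hydrophobic      | 0.41 kJ/mol   | 0.295 kJ/mol    |
| A0_polar             | 0.05          | 0               |
| A0_hydrophobic       | 0             | 0.0002          |
| lambda               | (none)        | 0.7             |
| eps_mod aromatic-aromatic | 0        | 0.1 kJ/mol      |

## Surface-exposure scaling (xi, lambda)

Folded domains are held together by the elastic network, so a residue's
burial never changes during a run. Each residue's interaction strength
`xi` is therefore computed once from the reference structure and frozen:

    xi = 1                          (disordered residues, always)
    xi = 1                          (folded, S_ratio >= lambda)
    xi = S_ratio / lambda           (folded, S_ratio < lambda)

`S_ratio = S_residue / S_ref`, the residue's solvent-accessible surface
area in the reference structure divided by an amino-acid-specific
reference area. Both areas are computed with the same Shrake-Rupley
implementation on the coarse-grained spheres (radius `r_i` + 0.14 nm
probe, 960 quasi-uniform points per sphere), so the ratio is internally
consistent. `S_ref(X)` is the central-residue area of an ideal
`A7-X-A7` alpha-helix (rise 0.15 nm/residue, 100 deg twist, 0.23 nm
radius): a 15-residue alanine host is long enough that the helix context
of the central residue is saturated. `S_ratio` is stored unclamped (it
can exceed 1 for convex, highly exposed residues); clamping would not
change `xi`. By default `xi` scales both the short-range well depth and
the electrostatic amplitudes (flag `xi_scales_electrostatics` restricts
it to the short-range term). Elastic-network pairs stay in the nonbonded
sum by default (`enm_excludes_nonbonded` flips this).

The threshold `lambda` (default 0.7) is the model's folded-domain dial:
small values let buried residues keep interacting (over-stable
condensates); values above ~0.7 start reshaping condensate morphology,
which breaks the frozen-ensemble assumption used in calibration, so the
optimizer caps lambda at 0.7.

## Residue parameters

Bead radii are spheres of equivalent residue volume, from the Zamyatnin
amino-acid partial-volume table and published RNA residue volumes
(Voss & Gerstein); both are user-overridable
(`residue_table(volume_overrides=...)`, or a full CSV via
`residue_table_from_csv`). Nucleotide codes are lowercase a/c/g/u
internally so RNA adenosine never collides with alanine.

## Dynamics

Langevin NVT dynamics with the BAOAB splitting, friction 0.01 ps^-1,
298 K, time step 10 fs (equilibration) to 20 fs (production), periodic
orthorhombic boxes (edges must exceed twice the 3 nm cutoff). Bead
masses are uniform per polymer class (110 amu amino acids, 330 amu
nucleotides); with a Langevin thermostat masses only rescale kinetics,
not configurational averages. Neighbor lists are periodic kd-trees with
a 0.6 nm skin rebuilt every 20 steps (thermal drift between rebuilds is
~0.1 nm, far below half the skin); coordinates are re-wrapped at each
rebuild so the single-fold minimum-image convention in the compiled
kernels is exact. Runs are bit-reproducible for a fixed seed. The force
kernels are numba-compiled; a cell-list path and an all-pairs path must
produce identical energies (tested), so the data structure is never a
source of error.

Note on thermostat coupling: at the model's weak friction the velocity
relaxation time is 100 ps. Systems started far from mechanical
equilibrium (e.g. collapsing random coils) transiently run hot because
potential energy is released faster than the thermostat drains it;
thermostat validation therefore minimizes first or discards the
transient.

`export_engine_system` writes the complete system (beads, constants,
exclusions, coordinates) as a documented JSON description in MD units
for handoff to production-scale engines; re-import reproduces
single-point energies exactly and is tested.

## Assembly and starting conditions

Three starting conditions: random dispersion, preformed droplet, and the
mixed phase (droplet plus dispersed monomers). The mixed start is the
recommended protocol for c_sat estimation because it avoids the
hysteresis of the extremes: nucleation from dispersion is stochastic and
slow near c_sat, melting a droplet is slower still. Droplets are packed
on a jittered lattice inside a central sphere at a target bead density
(default 0.4 beads/nm^3, exposed as `condensate_density`; the droplet
relaxes to its own equilibrium density during equilibration — compact
starts around 2 beads/nm^3 shorten that transient) and relaxed by
steepest-descent minimization (step halving, stop below max force
100 kJ/(mol nm) or 5000 steps). Placement enforces a 0.35 nm minimum
inter-chain bead distance and is a pure function of (spec, seed).

## Condensate analysis and c_sat

Chains are reduced to centers and radii of gyration (minimum-image
unwrapped along bonds). Two chains join a cluster when their
center-center distance is below `2.4 x (Rg_i + Rg_j)/2` (single-linkage;
a global-mean-Rg mode is provided since "average Rg" admits either
reading). Chains in clusters smaller than the monomer threshold
(default 5; 10 for high-concentration systems) form the dilute phase.
c_sat is the dilute concentration averaged over a trailing window of
frames, computed over the full box volume by default: the droplet-volume
bias is at most the droplet/box volume ratio, and a corrected-volume
mode (`volume_mode="exclude_condensate"`) is provided.
`detect_coexistence` classifies a run as dissolved / coexisting / fully
condensed; the reference condensate size (~150 chains in production
systems) must be scaled with total chain count on desk-scale systems.

## Calibration

Condensation theory gives `c_sat ~ exp(U / kB T)`, i.e. log10(c_sat)
linear in the per-residue condensate energy `U_total/N_beads`. The
package scores the tail frames (default 10) of condensate trajectories
under candidate parameters, fits `log10(c_sat) = a U + b` robustly with
RANSAC (scikit-learn; residual threshold 0.3 log10 units, 1000 trials,
seeded — the algorithm's standard knobs, exposed as arguments) and
refits inliers by least squares. Parameter optimization then minimizes
the weighted squared log10 deviation from experimental c_sat with
L-BFGS-B under bounds (lambda <= 0.7). Re-scoring frozen ensembles
instead of re-simulating per candidate is an approximation valid near
the reference ensemble; it is the step that makes optimization against
phase behavior tractable.

## Synthetic data and what passing tests show

Every test input is generated in-package: ideal helices (folded-domain
stand-ins), seeded self-avoiding random coils (disordered chains),
assembled droplets and dispersions, and short Langevin trajectories of
an aromatic-rich low-complexity 30-mer. These fixtures exercise every
code path without external structures. They emulate the geometry and
energetics of the real use case at reduced size; they do not reproduce
real condensate viscosities, multi-microsecond relaxation, sequence
specificity beyond the category level, or experimental c_sat magnitudes.
Desk-scale checks therefore target invariants (force-gradient
consistency, equipartition, clustering correctness, monotonicity of the
energy / dilute-concentration relation) rather than literal published
values, which require microsecond GPU campaigns on hundreds of chains.

Desk-scale problem sizes used by the test suite: 20 chains of a 30-mer
in a 30 nm box for phase-behavior checks (mixed start with 12-14 chains
in the droplet, up to 1.5x10^5 steps with early stopping on cluster
formation); 10^5-10^6 steps for equipartition on a dimer and an ideal
gas; 100 random 300-chain frames for clustering equivalence. The
interaction-scan check sits at a uniform well-depth scaling of 1.9,
chosen as the center of this system's coexistence window by the same
rule used in production calibration: keep only runs where the
condensate neither dissolves nor absorbs every monomer.

## Numerical choices

- Harmonic convention `1/2 k (delta)^2` for all harmonic terms; the
  printed force constants pass through unchanged.
- Plain truncation of both nonbonded terms at 3 nm; the discontinuity is
  at most |U(3 nm)| (negligible at these well depths); an energy-shifted
  10-5 variant is available (`shift_short_range`).
- The cross-category well-depth combination is the geometric mean
  (switchable to arithmetic), matching the reference distribution of the
  model family.
- Angle forces take the finite limit of `(theta - theta0)/sin(theta)` at
  straight angles, so 180-degree chains are force-free rather than
  singular.
- The steepest-descent minimizer is for clash removal, not for precise
  minima; it grows the step 1.2x on acceptance and halves on rejection.
- RANSAC inlier refit uses ordinary least squares; with no outliers the
  result equals plain least squares to machine precision (tested).

## Known limitations

- No pressure coupling, slab geometries, or lattice electrostatics (the
  model is NVT, droplet-based, and screened-cutoff by construction).
- Nucleotide well depths and solvation amplitudes reuse the polar
  values; protein-RNA balance has not been re-optimized here.
- SASA is computed on the coarse-grained spheres. Mixing the package's
  `S_ratio` with externally computed atomistic reference areas is
  inconsistent; if an external `S_ref` table is loaded, the
  corresponding `S_residue` should come from the same representation.
- The frozen-xi scheme cannot describe burial changes on binding or
  large domain rearrangements.
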