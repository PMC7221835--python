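# Methods

## The model system

`ligandpath` studies how a hydrophobic ligand enters and leaves the
buried binding pocket of a membrane receptor whose extracellular face is
occluded. The real systems motivating this geometry are lipid-binding
class-A GPCRs (cannabinoid, sphingosine-1-phosphate, lysophosphatidic
acid receptors): their orthosteric pocket is capped by an N-terminal
plug, so ligands must come and go laterally, through a crevice between
transmembrane helices — canonically between TM1 and TM7.

Because those questions hinge on *relative* barriers rather than on
chemical detail, the package works on a coarse-grained analog whose
ground truth is engineered and therefore known:

* **Helix ring.** `n_helices` (default 7) rigid vertical pillars of
  overlapping LJ beads (σ 5.0 Å, ε 0.25 kcal/mol, beads every 2 Å over
  z ∈ [−8, 8] Å) on a ring of radius 8 Å around the pocket at the
  origin.
* **Gates.** The ring circumference is divided among pillar
  cross-sections and the `gap_widths` weights; widening one weight
  strictly widens that gate's realized arc. The standard experiment
  widens the TM1–TM7 gate by 50% (realized arc 3.0 Å vs 2.0 Å
  elsewhere), making it the unique low-barrier lateral exit
  (static barriers ≈ 3.7 vs ≈ 15.6 kcal/mol).
* **Membrane.** Two planar bead sheets at z = ±6 Å with a cavity around
  the ring — enough to confine lateral exits to the slab without
  simulating lipids.
* **Plug.** A bead disc 2.5 Å above the pillar tops caps the vertical
  ("UP") exit; `up_plug=False` removes it.
* **Ligand.** A bead chain (default 4 beads, 2.2 Å bonds, 40 amu each):
  one charged head bead (−1 e, the phosphate-like pole) and a
  hydrophobic tail (ε 0.35 kcal/mol), mirroring the head/tail
  architecture of lipid agonists.
* **Restraints and container.** All non-ligand beads are tethered
  harmonically (5 kcal/mol/Å²) to their build positions — the scaffold
  breathes but cannot unfold — and a flat-bottom sphere (r = 26 Å,
  2 kcal/mol/Å²) keeps the system finite without periodic boundaries.

Units throughout: Å, ps, amu, kcal/mol, elementary charge; forces
reported in both kcal/mol/Å and pN via 1 kcal/mol/Å = 69.479 pN.

## Dynamics engine

Forces are Lennard-Jones (Lorentz–Berthelot mixing) plus Coulomb
(constant 332.0636 kcal·Å/mol·e²), both multiplied by the CHARMM
switching polynomial between 10 and 12 Å so the potential and its
gradient vanish smoothly at the cutoff; harmonic bonds, position
restraints and the container complete the field. Bonded pairs and
scaffold–scaffold pairs are excluded from the nonbonded sum — the
scaffold is deliberately built from overlapping beads and is held by
tethers, so its internal nonbonded energy is a meaningless constant
(and excluding it makes the force loop scale with ligand–environment
pairs). Forces are exact negative gradients of the reported energy;
the test suite verifies this to 1e−4 relative against central
differences, and exactly checks Newton's third law and the energy
decomposition.

The integrator is BAOAB Langevin splitting with one force evaluation per
step. At T = 0, γ = 0 it reduces exactly to velocity Verlet (energy
drift < 1e−4 kcal/mol per 1000 steps at dt = 0.002 ps on a bonded
pair); at finite temperature a 1e5-step run reproduces kT/2 per degree
of freedom within 5%. The noise stream is a seeded PCG64 generator
carried on the simulation state, so trajectories are bit-reproducible
and checkpoints (versioned JSON, storing positions, velocities, time,
step and the full generator state) resume the identical stream. Default
dt is 0.01 ps — comfortable for these masses and force constants; a
blow-up guard aborts with a suggestion to reduce dt if forces or
coordinates diverge.

## Steered pulling and work analysis

A virtual spring (default k = 70 pN/Å) connects the COM of selected
ligand beads to an anchor moving at constant speed v along a chosen exit
direction; the anchor position is computed in closed form at every step,
so the recorded anchor path is exact. Pull beads are chosen per
direction as the ligand beads with the largest projection onto the
pulling vector (ties by index) — pulling the leading end avoids rotating
the ligand in the pocket. Directions are the outward bisectors of the
inter-helix gates plus +z for UP; the five standard directions are
TM1–TM7, TM1–TM2, UP, TM4–TM5, TM5–TM6.

The pull-out work is the componentwise trapezoidal line integral of the
recorded spring force **against the pulled-COM displacement**, not the
anchor displacement — anchor distance would book spring stretch as
travelled path. The maximal force is the largest |F⃗| of a pull, a
friction/steric proxy. Replicates (≥3 per direction) are aggregated as
mean ± sample SD; directions are ranked by ascending mean work, and two
directions whose means lie within the larger of their SDs are treated as
statistically equivalent, with mean maximal force as the tie-break. The
verdict names the winning direction and whether the runner-up is
equivalent.

The reference all-atom protocol (k = 70 pN/Å, v = 0.3 m/s, 15 ns per
pull) is available via `reference_schedule()`, but at 0.3 m/s the anchor
travels only 6 Å in 2 ns — far short of the ~18 Å exit path of the toy
receptor — and explicit 15 ns runs are not desk-scale. The toy default
therefore keeps the spring constant and raises the speed to 15 m/s over
120 ps (18 Å of anchor travel). On this smooth coarse-grained landscape
the pull remains slow compared to ligand relaxation (the drag force at
this speed is ~4 pN against spring forces of hundreds of pN), so the
ranking, which is the object of interest, is preserved; absolute works
remain speed-inflated upper bounds, as in any finite-speed pull.

The ranking experiment is validated against a dynamics-free oracle:
`ground_truth_barriers` rigidly translates the ligand along each exit
line and records the maximum interaction energy. The acceptance check
asks that the *winner* of the dynamical ranking match the oracle's
argmin in ≥80% of seeded batches. The full five-way ordering is not
asserted: the three narrow gates are engineered nearly degenerate
(barriers within 0.1 kcal/mol of each other), so their mutual order
under 3-replicate noise is statistically meaningless — exactly the
situation the equivalence rule exists for.

## Supervised entrance (SuMD)

Supervision accelerates binding-event observation without biasing
forces. Unbiased dynamics runs in slices (default 100 steps = 1 ps);
after each slice the ligand-COM-to-site distance is compared with the
slice start. The slice is kept if it improved by at least ε (default
0.1 Å) or beat the best distance seen so far; otherwise the pre-slice
checkpoint is restored and the slice is retried with Maxwell–Boltzmann
velocities resampled under the next seed of the policy (base + attempt
counter), so no seed is ever repeated at a checkpoint (tabu). The run
terminates on arrival (distance ≤ arrival radius, default 4 Å), on a
cap of consecutive rejections (default 50), or on a total step budget.
Slice length, ε and the caps are package choices, exposed in
`SuMDConfig`; distance is evaluated at slice ends because restarts
happen between slices. Acceptance tests verify the bias-free property
constructively: replaying the logged seeds through plain unbiased
slices rebuilds the accepted trajectory bit for bit.

The paired benchmark runs supervised and plain dynamics from identical
initial states on a "binding funnel" (a restrained attractive site bead,
the ligand 20 Å away in a 24 Å container; beyond the 12 Å cutoff the
search is purely diffusive). Over 20 paired seeds the supervised median
steps-to-arrival is an order of magnitude below the plain-MD median.
`switch_to_plain_md` continues an arrived run without supervision — the
standard endgame showing the entered pose is held by the potential, not
by the supervisor.

## Interaction energetics and pose distances

Ligand–receptor interaction energy sums Coulomb and LJ terms across the
two groups only (no intra-group, bonded or restraint terms), with the
same cutoff/switching as the engine (an exact no-cutoff mode exists for
cross-checks). E_total is formed as E_elec + E_vdw in fixed order, so
the decomposition identity is exact at every sample; profiles along
trajectories expose a configurable running-mean window (default 50
samples) for plotting.

When a simulated final pose and a crystallographic ligand are different
molecules, RMSD is undefined; the COM–COM distance in the shared
receptor frame is the standard substitute. No superposition is
performed — poses must already share a frame — and per-ligand means are
rounded half-away-from-zero at one decimal, the convention of the
published table shipped with the package (means 3.4, 3.1, 3.5 and
8.0 Å for THC, AEA, LPA and S1P).

## What the synthetic system does and does not show

The generator reproduces the *structural logic* of lipid-receptor
entry: a buried pocket, lateral gates of unequal width, an occluded
vertical exit, a head/tail amphiphilic ligand. Passing tests show the
machinery — pulling, work integration, ranking, supervision,
energetics — recovers an engineered ground truth under realistic noise.
They do not show anything about real receptors: there is no lipid
chemistry, no water, no protein flexibility beyond harmonic breathing,
no rotameric gating, and the energy scale is set by a handful of LJ
parameters rather than a force field. Absolute works, forces and
energies are therefore toy-scale quantities; only their comparisons
carry meaning.

## Numerical choices and degenerate inputs

* Trapezoidal work integration is exact for constant and linear force
  profiles and matches dense-grid quadrature to <0.1% on smooth ones;
  splitting a record anywhere and summing segment works reproduces the
  total to double precision.
* Single-replicate aggregation reports SD = 0 with an explicit
  degenerate flag rather than NaN.
* Ligand placement resolves steric clashes by up to 100 seeded jitter
  retries, then fails loudly naming the offending pair.
* Checkpoint and topology files carry format tags; corrupted or
  untagged files raise specific errors rather than partial loads.
* CSV force records are written and re-read at full double precision
  (`float_precision="round_trip"`); the NAMD-style `SMD step cx cy cz
  fx fy fz` dialect uses repr formatting so shared fields round-trip
  losslessly.
* Problem sizes used by the shipped experiments: ~160 beads, 12 000
  steps per pull (5 directions × 3 replicates × 10 batches for the
  recovery rate), 2×10⁵-step budgets for the funnel runs — sizes chosen
  so the full analysis reruns in minutes on one CPU core while keeping
  the signal-to-noise needed for the statistical claims.
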