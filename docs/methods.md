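# Methods

`dyn2lattice` models, at desk scale, how the retrograde
intraflagellar-transport motor dynein-2 recognizes its track: the
tyrosinated tubulin lattice of the ciliary doublet's A-tubule.  The package has three layers — a coarse-grained
motor-on-lattice simulator, the trajectory statistics used to read the
simulations out (site-occupancy heatmaps, overflow proportions, residue
contact maps), and the non-simulation quantification arithmetic
(cryo-ET head densities and dimer-configuration classes,
mass-spectrometry tyrosination fractions and their protofilament
mapping, co-pelleting band statistics).  Every input can be generated
synthetically with known ground truth, so the whole pipeline is testable
offline.

## The coarse-grained system

**Lattice.**  An idealized microtubule-wall patch: `n_pf` straight,
parallel protofilaments (default 4) of `n_dimers_per_pf` αβ-tubulin
dimers (default 3), with 8.2 nm axial rise per dimer, 5.2 nm lateral PF
spacing and 0.92 nm B-lattice stagger (all overridable; no supertwist or
curvature).  Each tubulin monomer is a rigid 20-bead shell of radius
2 nm; monomer bodies are frozen during dynamics (the k→∞ limit of a
positional restraint).  Three acidic surface beads per α-tubulin stand
in for the binding-site glutamates E411/E420/E423.  The coordinate
convention is right-handed with +x the axial direction toward the minus
end (the direction of dynein movement), +y lateral, +z the outward
surface normal; residue indices are 1-based.

**E-hook tails.**  Every α-tubulin carries a flexible C-terminal tail —
by default the 12-residue E-hook proper, `AEGAGEGEGEEY` (residues
440–451, ending at the terminal tyrosine Tyr451).  The upstream
C-terminal residues belong to helix H12 and are considered part of the
rigid body.  Tails are fully flexible chains (harmonic bonds,
k = 100 kcal/mol/nm², plus a gentle cosine-harmonic angle term); they
carry the glutamate side-chain charges plus one extra −1 on the chain
terminus for the free carboxylate.  Detyrosination removes the terminal
Tyr, which moves the carboxylate charge onto the exposed glutamate
(−2 on one bead) without changing the net tail charge — the charge
*position*, not the total, is what changes.

**Motor.**  A two-headed toy: each head is a rigid quasi-spherical
20-bead shell (radius 1.5 nm) whose lattice-facing cap carries the basic
residues observed at the MTBD–tubulin interface (K2996, R3007, R3041,
R3044, K3077, K3080, R3081 at +1; the rest of the surface neutral,
matching dynein-2's comparatively neutral binding face).  The two heads
are joined by a soft tether (dimerization proxy, rest length 6 nm,
k = 0.2).  The high-affinity head is pinned by per-bead harmonic
restraints (k = 25) and never changes state; only the low-affinity
head's initial diffusional motion is simulated.

**Native interface.**  The docked complex is always defined on the
*tyrosinated* lattice.  `place_dimer` records Gaussian-well native
contacts between each head's beads and (i) nearby tubulin-body beads
(pairs at 0.7–1.5 nm) and (ii) the resolved terminal E-E-Y stretch of
the E-hook arched against the MTBD rim (pairs at 0.7–1.3 nm), at their
placed distances.  The terminal tyrosine therefore contributes native
contacts.  A detyrosinated system is produced by editing the assembled
complex: `set_tyrosination` deletes Tyr451 and every native contact it
participates in, and re-assigns charges.  This is how such models are
built in practice — the detyrosinated lattice is obtained from the
tyrosinated complex by removing the C-terminal tyrosine — and it is the
mechanism the simulations probe: detyrosination simultaneously (a) removes the
tyrosine-anchored part of the native interface and (b) exposes a
doubly-charged terminal glutamate that interacts transiently with the
MTBD's basic residues.

## Force field and dynamics

Engine units: length nm, energy kcal/mol, bead mass 5, time
τ = nm·√(mass/(kcal/mol)); kB T ≈ 0.596 kcal/mol at 300 K.

* **Native contacts** — Gaussian wells U = −ε·exp(−(r−r₀)²/2w²),
  uniform ε = 1.2 kcal/mol, width w = 0.25 nm.  This is the contact form
  of the published atomic-interaction-based CG force fields; its bounded
  force makes the integrator robust, and the hard core is supplied
  separately by excluded volume (native pairs keep their repulsion).
  The classic 12–10 Gō pair potential is provided as
  `go_contact_energy` for analysis and cross-checks.
* **Electrostatics** — Debye–Hückel screened Coulomb,
  U = kBT·λ_B·q₁q₂·exp(−r/λ_D)/r, with the Bjerrum and Debye lengths
  from their standard closed forms (λ_B ≈ 0.71 nm, λ_D ≈ 0.96 nm at
  0.1 M, 300 K, ε_r 78), truncated at 3 nm.
* **Excluded volume** — shifted purely repulsive ε_ev(σ/r)¹² with
  σ = 0.6 nm, ε_ev = 2.0 kcal/mol, cutoff 2σ.  ε_ev is set high enough
  that an oppositely charged bead pair equilibrates near 0.75 nm,
  outside the stiff part of the core (a stability requirement for the
  ±2/±1 charge pairs that detyrosination creates).
* **Bonded terms** — tail bonds k = 100 kcal/mol/nm² at 0.38 nm;
  angles U = ½k(cosθ − cos130°)², k = 2.

**Integrator.**  Underdamped Langevin dynamics via BAOAB splitting, one
force evaluation per step, dt = 0.05 τ.  Motor heads are integrated as
rigid bodies — translation of the center of mass plus rotation
(quaternion, isotropic-shell inertia I = ⅔Σm·r²) driven by the summed
force and torque on their beads, with matching Langevin friction and
noise on both — so no stiff internal springs are needed and the E-hook
can exert realistic torques on the bound head.  The protocol's friction
coefficient 2.0 is quoted in CafeMol units, whose physical mapping is
not published; it enters the engine as γ_eff = friction × friction_scale
with friction_scale = 0.15/τ, chosen so the free motor diffuses a few
site spacings within a reduced-scale run.  With friction and temperature
zero the integrator reduces to velocity Verlet (energy-conservation
sanity check); at T = 0 the electrostatic prefactor kBT·λ_B is taken to
its (finite) limit of zero.  Nonbonded terms use two Verlet neighbor
lists (electrostatic and excluded-volume) rebuilt on a half-skin
displacement trigger.  The random stream is a single seeded MT19937;
a trajectory is a bitwise-reproducible function of (system, parameters,
force field, seed).  Any bead leaving a box of 10× the lattice extent
aborts the run with the failing step index.

**Numerical guards.**  The angle force is skipped when a bond arm drops
below 0.12 nm (the gradient diverges as 1/r² there; a transiently
collapsed bond would otherwise inject energy), and native contacts are
only created for pairs placed at ≥ 0.7 nm (closer pairs stay EV-only).

## Protocols

The full-scale protocol is 300 K, ε_r 78, 0.1 M, friction 2.0,
3×10⁷ steps per run with the first 5×10⁶ excluded as burn-in, 20 seeds ×
3 initial positions per tail state.  The *reduced campaign* used by the
tests and the acceptance script keeps the protocol's structure at desk
scale: 10⁵ steps per run (burn-in 17,000 ≈ 1/6, frame stride 100),
10 seeds × 3 positions × 2 tail states = 60 runs, ~10 minutes on one
CPU.  Initial positions place the high-affinity head on the adjacent PF
one site backward (1), laterally aligned (2), or one site forward
toward the minus end (3) of the low-affinity head, matching the cryo-ET
configuration classes.

## Trajectory statistics

The low-affinity MTBD's center of geometry is assigned per frame to one
of the 3×3 binding sites: Voronoi cells of the site centers clipped to
the grid rectangle extended by half a site spacing per axis, plus a
detachment bound of 6 nm above the lattice surface (the tail-dragged
tethered states reach ≈5 nm, so 6 nm separates "held by an E-hook" from
"gone"; neither bound has a canonical published value).  Ties break
toward the
lower index.  Overflow is trajectory-level and absorbing: a trajectory
counts as overflow if any post-burn-in frame leaves the capture region,
and frames after the first exit carry no grid mass.  Heatmaps are
normalized per condition over retained frames; both per-position and
summed grids are emitted.  For the Y-vs-dY comparison the summary layer
also reports center *residence* — (1, 1) mass over all post-burn-in
frames, absorbed overflow frames included in the denominator — because
the non-overflow-normalized grid is survivor-biased (trajectories that
escape early stop contributing mass, which flatters the state that
escapes more).  Overflow proportions come with a percentile
bootstrap CI over trajectories, and the Y-vs-dY comparison uses a
one-sided bootstrap test on the difference of proportions (add-one
smoothed).

Contact maps count, per residue pair (MTBD × tubulin/E-hook), the
frames in which the minimum bead–bead distance is within 1.0 nm,
accumulated over the trajectory; differential maps subtract
per-frame-normalized tyrosinated frequencies from detyrosinated ones
after dropping the Tyr451 row/column absent in dY, so positive entries
mean more contact upon detyrosination.

## Quantification stage

* **Head densities** — heads per 100 nm of axis arc length per tubule;
  group comparison by two-sided unpaired Student t test (equal
  variance, Welch by flag), per doublet.
* **Configuration classes** — looking along the movement direction with
  the outward normal up, `right = axis × normal`; the head with the
  larger right-projection is the right head.  |axial offset| ≤ 4 nm
  (half a dimer repeat) → Configuration 2; otherwise right head leading
  → 1, trailing → 3; laterally coincident heads (≤ 1 nm) are
  degenerate → "other".  The classifier is rotation-equivariant and
  mirror-swaps 1↔3.
* **Peptide classes** — a peptide that is a suffix of the α-tubulin
  C-terminal reference ending at the terminal Tyr is tyrosinated; a
  suffix ending one residue short (at the penultimate Glu) is
  detyrosinated; anything else internal.  Fractions are
  spectral-count-weighted over C-terminal records (glutamylation over
  all records); percentages round half-up to one decimal.
* **Protofilament equivalents** — round-half-up(fraction × 23/100),
  with 23 = 13 A-tubule + 10 B-tubule protofilaments.
* **Co-pelleting** — bound fraction ppt/(ppt+sup) per replicate, then
  the same unpaired t test between constructs.

## Synthetic data and what it does (not) show

All generators are pure functions of (parameters, seed).  Tomogram
annotations draw per-tubule head counts from Poisson(rate×length/100)
(defaults: 24 doublets × 1000 nm, A-rate 3.0, B-rate 1.0 per 100 nm —
about 900 heads, emulating the experimental scale) and place dimer
pairs whose geometry realizes a configuration class sampled from known
probabilities, so the classifier recovers the labels exactly.  A
deterministic fixture realizes the observed 43-dimer composition
7:11:13:12.  PSM tables draw C-terminal records tyrosinated with
probability 0.337 and flag glutamylation at 0.0635, with internal decoy
peptides mixed in.  Analytic Gaussian random walks with a square
absorbing boundary provide overflow fixtures whose escape probability
is computable by a transition-matrix oracle (x/y independence makes 2-D
survival the square of 1-D survival).

A synthetic MTBD stand-in pair (`synthetic_mtbd_pair`) provides two Cα
traces, numbered with the dynein-2/dynein-1 construct ranges, whose
optimal superposition RMSD is engineered to 1.1 Å by construction (the
deformation field is projected orthogonal to all rigid-body modes).  It
exercises the full superposition path end-to-end; it is *not* real
dynein coordinates, and the structural comparison of the real PDB
entries requires downloading them and running `load_structure` +
`superpose_rmsd` with the default selections.

Passing tests on these inputs demonstrate that the estimators recover
known ground truth and that the simulation exhibits the claimed
direction of effect under the stated model assumptions.  They do not
validate the CG force field against experiment: real doublets have
13+10 curved protofilaments, inter-PF angle heterogeneity, β-tubulin
tails, and a motor with internal mechanics, none of which the toy
represents.

## Design choices on genuinely open points

* The MTBD selection for the structural superposition is not published;
  the default pairs construct ranges 2962–3125 ↔ 3266–3429 by the +304
  offset implied by the conserved pair E3002/E3306 (the last dynein-2
  construct residue would map past the dynein-1 construct and is
  dropped).
* Heatmap normalization is emitted both per initial position and summed
  (either normalization can plausibly precede the sum).
* Whether overflow is counted per frame or per trajectory is not
  stated; trajectory-level is used because the definition speaks of a
  percentage of trajectories.
* The t test flavor is Student (equal variance) to match common
  practice; Welch is a flag.
* PSM weighting is spectral counts by default; intensity weighting is a
  flag.

## Calibration and limitations

The single deliberately calibrated constant is the contact depth
ε = 1.2 kcal/mol: it places the tyrosinated bound state's lifetime on
the scale of a reduced run, so that escape is rare but observable —
the regime in which the detyrosination contrast is measurable.  At this
setting the reduced campaign gives overflow ≈ 25–35 % (Y) versus
≈ 55–70 % (dY) and center-site residence higher on Y — the full-scale
ordering and roughly a 2–3× rate ratio.  Absolute full-protocol
percentages belong to 300×-longer runs with a complete CG force field
and are out of desk-scale reach.  Direction-of-
effect statements are stochastic; they are tested over 10 seeds × 3
positions per state with a one-sided bootstrap at α = 0.05.
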