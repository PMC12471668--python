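# Methods

## The estimator

`tstperm` measures single-channel osmotic water permeability from
*equilibrium* trajectories by transition-state theory.  All geometry is
expressed in a per-monomer channel frame: +z points intracellular (IC) →
extracellular (EC), the dividing plane sits at the channel's most
constricted point, z = z_divide (default 0), and the bulk reservoirs
begin at the thresholds z_bulk_ic / z_bulk_ec (defaults ∓15 Å).  Inside
the slab between the thresholds a water belongs to a monomer's pore when
its lateral distance to that monomer's axis is within `radius_gate`
(default 6 Å); outside the slab it is bulk by definition.

The rate constant combines three measured pieces:

    k0 = kappa * sqrt(R*T / (2*pi*m_W)) * n(z0)

* `sqrt(RT/2πm_W)` is the mean positive axial Maxwell–Boltzmann speed —
  exact at equilibrium, no fitting;
* `n(z0)` is the linear water density at the plane, in molecules per nm
  of axis, read from the histogram bin containing z_divide (half-open
  bins [left, right), no interpolation or smoothing by default);
* `kappa` is the transmission correction measured by event-following.

The permeability is `p_f = 2 k0 ν_W / N_A` (cm³/s), the osmotic flux in
the dilute regime is `J = p_f (c_e − c_i)`, and a temperature pair gives
`E_a = R T1 ln(p1/p2) / (T1/T2 − 1)`.

### Linear density units

`n(z)` is reported in molecules per nm *of channel axis*.  A linear
density is dimensionally required for k0 to come out in 1/time; plots of
channel water density sometimes label this axis as a volume density, but
the quantity entering the rate constant here is strictly per unit
length.

### Event following and the two denominators

Crossings are detected as sign changes of z − z_divide between
consecutive stored frames (crossing time = the later frame; no sub-frame
interpolation — it cannot change any count).  Each crossing is followed
until it *succeeds* (reaches the destination bulk threshold) or *fails*
(crosses back over the plane, or exits the pore laterally inside the
slab, which is failure-equivalent: it did not end up in the destination
bulk).  While one event is open no new event opens for that particle;
the frame pair that resolves an event is consumed; events still open at
the trajectory end are reported `unresolved` and excluded from every
count (counting them as failures would bias κ downward at the end of
the observation window).

A success defined this way is provably the final leg of a complete
bulk-to-bulk traversal, so the success count equals the number of
complete permeation events — the test suite asserts this against an
independent region-scan oracle.  (One edge: a particle that *starts*
inside the channel can complete a half-passage the oracle does not see;
the identity is exact for particles that start in bulk.)

Two ratios can be formed from these counts and they are **not**
equivalent:

* `successes / state-machine attempts` — the per-attempt success ratio;
* `successes / raw plane crossings` — the transmission coefficient.

κ in this package is the second.  The reason is consistency of k0: the
Maxwell flux `sqrt(RT/2πm)·n(z0)` is by construction the rate of *all*
one-way plane crossings (the test suite verifies this identity directly
on flat-potential Langevin data), so the factor multiplying it must be
"fraction of crossings that complete", i.e. successes over raw
crossings.  With that choice, κ·√(RT/2πm)·n(z0) equals the one-way
complete-traversal rate exactly, and p_f = 2k0·ν_W/N_A agrees with
direct bidirectional traversal counting.  The state machine opens no
mirror-direction event at the crossing that resolves an open event, so
its attempt count is roughly (crossings + successes)/2; using it as
the denominator would inflate p_f by up to 2× in the recrossing-heavy
regime.  `EventSummary` reports both ratios (`kappa`, and
`success_ratio_attempts`) and records which denominator produced
`kappa`; when only a bare event list is summarized (no crossing counts
supplied), the attempts ratio is used and flagged as such.

### Per-monomer handling

Waters are represented by their oxygen; a water belongs to at most one
monomer per frame (nearest axis wins, ties to the first-listed
monomer).  Tetramer events are pooled for the per-channel estimate and
also summarized per monomer; the pooled-over-monomers κ and the
monomer-averaged n(z0) give a per-channel p_f directly, and the spread
of per-monomer estimates feeds `estimate_uncertainty` (standard error
of the mean over monomers by default; SEM over non-overlapping time
blocks is the labelled alternative — published error bars of this kind
rarely state their method, so ours records it in provenance).

### Uncertainties

The per-run `uncertainty_pf` uses the Poisson approximation on the
success count (p_f is proportional to the complete-traversal rate, and
traversals are rare, weakly correlated events).  SEM over monomers or
blocks is available when replicates exist.

## The synthetic generator

`tstperm.synthetic` integrates inertial Langevin dynamics,

    m dv = F(z) dt − m γ v dt + sqrt(2 m γ k_B T) dW,

with the BAOAB splitting, in units Å / ps / kcal/mol / g/mol.  The
default particle is water-mass (18.015 g/mol).  An inertial (not
overdamped) integrator is essential here: the TST prefactor is the
Maxwell–Boltzmann flux, which only exists if velocities are thermal.
BAOAB gives the exact Ornstein–Uhlenbeck velocity update and has O(dt²)
configurational bias.

Geometry: a Gaussian barrier of height `barrier_height` (kcal/mol) and
width `barrier_width` (Å, s.d.) at z = 0 (an arbitrary U(z) callable
may be supplied instead), flat reservoirs beyond ±`channel_halfwidth`,
reflecting walls at ±`box_z`/2 — emulating the bulk water layers that
flank a membrane in an MD box.  Optional extras: free lateral motion in
a reflecting cylinder (3-D mode), and a single-file mode imposing a
hard-core diameter σ via symmetric push-apart with velocity exchange
(elastic collision of equal masses), which preserves particle order
exactly.

Initial positions are drawn from the stationary Boltzmann law by
inverse-CDF sampling and velocities from the Maxwell distribution, so
the ensemble is stationary from the first frame — no equilibration
period is needed or discarded.

Numerical safeguards: the simulator refuses dt·γ > 1 or dt·ω_barrier >
1 (ω from the maximum curvature of U) and warns above 0.2/0.3.  Forces
come from a 0.02 Å grid with linear interpolation.

Seeding: one master seed; per-particle streams are spawned from
`numpy.random.SeedSequence`, so enlarging the ensemble never reshuffles
existing particles' noise, and every run is bit-reproducible.

### What the generator does and does not emulate

It reproduces the *statistical* structure the estimator relies on —
Maxwellian velocities, Boltzmann positions, barrier-controlled crossing
and recrossing, bulk reservoirs, optional no-passing order.  It does not
model hydrogen-bond networks, protein flexibility, lateral pore
structure, or water–water correlations other than hard-core exclusion.
Passing tests therefore demonstrate that the *estimator* is unbiased
and self-consistent on data satisfying its assumptions; they say
nothing about force-field or sampling adequacy of any particular MD
trajectory.

## Validation studies in the test suite (problem sizes)

Chosen once as the package's study conditions:

* **Flux identity** — 200 particles, 5×10⁶ steps of dt = 1 fs at
  γ = 10 ps⁻¹, flat potential, every step stored: the one-way crossing
  rate matches √(RT/2πm)·n(z0) within 3 SE (SE over independent
  particles, delta method).  Finite storage intervals miss crossing
  pairs that complete within one interval; at γ·dt = 0.01 this bias is
  ≈0.3%, well inside the band.
* **Boltzmann sampling** — 1500 particles, 200 ps, barriers 0/2/4
  kcal/mol; Kolmogorov–Smirnov against the analytic CDF at α = 0.01 on
  one final-frame snapshot per particle.  With i.i.d. stationary
  initialization those snapshots are exactly i.i.d. draws from the
  stationary law provided the integrator preserves it, so the KS
  independence assumption holds exactly; pooling many frames per
  particle would leave the slow reservoir-exchange mode correlated
  across samples and invalidate the test.  (The `init="stratified"`
  option removes the binomial reservoir-population noise of the
  *initial* ensemble for density studies, but cannot prevent in-run
  exchange fluctuations, which is why the test uses snapshots.)
* **Barrier recovery** — barriers {0, 1.5, 3} kcal/mol, temperature
  pair 278.15/298.15 K, 100 particles, run lengths scaled per barrier
  (1.2–9 ns) so the hardest case still collects several hundred
  traversals; each estimate is compared to a 10×-longer reference and
  the sequence must be monotone.  The zero-barrier baseline E_a
  (~0.4–0.5 kcal/mol) reflects the √T flux factor plus the weak
  temperature dependence of κ.

## Design choices where the design was open

* Frame of reference: optional per-frame recentring on a reference
  group is *not* applied by default; the channel frame is rigid.  For
  drifting proteins users should superpose upstream or supply per-frame
  origins.
* Storage interval: crossing detection degrades when the storage
  interval approaches the velocity decorrelation time 1/γ; a storage
  interval ≤ 1 ps is recommended for aqueous-channel analysis.
* Monomer averaging order: the pooled profile is the average of
  per-monomer profiles (not the re-normalized pooled histogram); the
  two coincide when monomers hold equally many frames.
* Periodic unwrapping is minimum-image per consecutive frame pair,
  which is exact whenever no molecule moves more than half a box
  between stored frames.
* ν_W is held at 18.0153 cm³/mol across 5–25 °C (<0.2% variation,
  below typical statistical error).
* Hydrogen bonds: geometric criterion, donor-heavy–acceptor ≤ 3.5 Å
  and D–H···A deviation ≤ 30° — the common MD convention; both
  parameters are configurable and recorded in outputs.  Water–water
  bonds are counted once per unordered molecule pair.  "Pore-lining
  residues" default to residues with a heavy atom within 4.5 Å of a
  single-file water in ≥1% of frames; an explicit list overrides.
* Single-file waters are selected per frame within a fixed z-interval
  (the sub-threshold density run around the plane, ≤2.5 molecules/nm by
  default).

## Known limitations

* κ and n(z0) estimates assume a stationary trajectory; no detection of
  drift or incomplete equilibration is attempted.
* The dividing plane is a fixed z-plane per monomer; strongly tilted or
  bent pores would need a curvilinear reaction coordinate.
* The Poisson uncertainty on p_f ignores correlations between
  traversals (single-file channels anti-correlate them); SEM over
  monomers or time blocks is the safer estimate when available.
* Real-trajectory hydrogen-bond analysis requires hydrogens in the
  topology; united-atom water models are not supported.
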