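# Methods

## The model

`hexfrac` simulates deformation and fracture of an enamel-like
apatite–collagen composite at the micrometre scale with a deliberately
minimal coarse-grained model.  The composite is divided into hexagonal
prismatic *building blocks*, each comprising one collagen triple-helix
embedded in 10×10×10 hydroxyapatite unit cells.  Block positions are
tracked only in the xy plane (the prism axis is treated as periodic), so
the model is two-dimensional: blocks occupy a triangular — hexagonally
packed — lattice in which every interior block has six nearest
neighbours.

Two block species encode the state of the material:

* **pristine (P)** — elastically intact composite;
* **damaged (D)** — composite that has undergone plastic deformation at
  the organic–inorganic interface, with a softer spring constant and a
  longer equilibrium spacing.

Bonded neighbours interact through a truncated harmonic pair potential

```
V(r) = k [ (r − r_o)² − (r_c − r_o)² ]    for r ≤ r_c
V(r) = 0                                  for r > r_c
```

which is continuous at the rupture cutoff `r_c` and has its minimum
`V(r_o) = −k (r_c − r_o)²` at the equilibrium spacing `r_o`.  The force
`−dV/dr = −2k (r − r_o)` drops discontinuously to zero at `r_c`: brittle
bond rupture is part of the force law itself.  Default parameters:

| pair | k (kJ mol⁻¹ nm⁻²) | r_o (nm) | r_c (nm) |
|------|------------------|----------|----------|
| P–P  | 1.77·10⁵         | 9.17     | 9.65     |
| D–D  | 1.10·10⁵         | 9.35     | 9.82     |
| P–D  | = D–D            | = D–D    | = D–D    |

Mixed P–D pairs use the damaged law: the softer medium governs any
contact that touches damaged material.  This choice is local, symmetric
in the two species and a pure function of (species, distance).  An
alternative reading — a pristine block bordering any damaged block uses
the damaged law even toward its other pristine neighbours — would make
the force on a bond depend on third blocks; we rejected it as non-local.

**Damage rule.**  A pristine block becomes damaged as soon as at least
one bonded neighbour (of either species) is separated from it by at
least the pristine cutoff `r_c^P = 9.65` nm (ties at exactly `r_c^P`
count as separated; the equality has measure zero in dynamics).  The
switch is irreversible — self-healing operates on far longer time scales
than damage accumulation and is neglected.  Switching is evaluated once
per time step, after the position update and before the force
evaluation, so all blocks crossing the threshold in the same step switch
together and every force evaluation sees one consistent species
assignment.

A bond whose length exceeds its cutoff stays in the topology for
bookkeeping (flagged broken, monotonically), exerts zero force, and can
transmit force again only if the pair re-enters the (by then
damaged-species) cutoff.  There is no excluded-volume repulsion between
blocks that were never bonded; the loading scenario is tensile and block
overlap does not occur at the strains considered.  Forces act only along
the initial bond topology: the cutoffs (9.65/9.82 nm) lie far below the
second-neighbour distance (√3 × 9.17 ≈ 15.9 nm), so for intact material
a distance criterion and the fixed topology coincide.

## Dynamics

Equations of motion are integrated with velocity Verlet (time step
350 fs by default) plus an exact Ornstein–Uhlenbeck velocity update —
a Langevin thermostat, default 300 K with friction 0.1 ps⁻¹.  At zero
friction the integrator reduces to plain velocity Verlet and conserves
energy to better than 10⁻⁴ relative over 10⁴ steps (tested); zero
temperature with positive friction gives pure damped relaxation.
Repeated calls of the single-`step` entry point derive a fresh noise
seed from the configured seed and the step index, so step-wise and
batched trajectories at finite temperature use different (individually
deterministic) noise streams.

Units are GROMACS-like and internally consistent: nm, ps, u (g/mol),
kJ/mol; force in kJ mol⁻¹ nm⁻¹; 2-D stress in kJ mol⁻¹ nm⁻².  The block
mass defaults to 10⁶ u — the order of magnitude of 10×10×10
hydroxyapatite unit cells plus one collagen helix — giving a bond
vibration period of 2π/√(4k_P/m) ≈ 10.6 ps, about thirty time steps,
which is why 350 fs is a stable step.  A per-step displacement larger
than one block size aborts the run with an instability error naming the
offending block.

**Loading protocol.**  The strain-and-hold experiment applies an
instantaneous affine strain — every coordinate along the loading axis
scaled by (1 + ε) about the sample's minimum edge — and then holds the
boundary while the interior relaxes.  The extreme block columns act as
displacement-controlled grips: their loading-axis coordinate is frozen
at the strained value, while their transverse coordinate remains free.
Rigid two-axis grips were tried first and rejected: they forbid Poisson
contraction at the grips, which produces a static stress concentration
where grip meets free surface strong enough to nucleate damage on a
defect-free lattice at 5% strain.  That artifact would mask the clean
sub-threshold property of the model — on a defect-free lattice, uniform
horizontal strain below (r_c^P − r_o^P)/r_o^P ≈ 5.234% can never bring a
bond to rupture, so 5% strain breaks nothing without a defect.  Periodic
horizontal boundaries are available as a config option for bulk-like
runs (the box length is then strained instead of clamping columns).

**Notch.**  Crack initiation is seeded by a rectangular notch cut into
the top (free) surface — by default 4 block columns wide and 2 rows
deep, centred on a configurable column.  The shape is a modelling
choice; only its role as a pre-existing imperfection matters, and the
observables below are insensitive to its exact geometry.

**Static relaxation.**  `relax` prepares unstrained reference states by
FIRE (fast inertial relaxation engine): damped zero-temperature dynamics
with adaptive time step, velocity–force alignment mixing and velocity
quenching on uphill power.  Plain friction-damped dynamics critically
damps only one band of modes — the slowest mode of a 30×30 lattice would
need >10⁵ steps to reach a 10⁻⁶ kJ mol⁻¹ nm⁻¹ force tolerance — whereas
FIRE converges the same problem in a few hundred iterations.  Per-step
displacement is capped at a tenth of the lattice spacing.

## Observables

**Stress.**  The 2-D virial stress over the current bounding-box area A:
σ_ab = (1/A)[Σ_bonds r_a F_b + Σ_blocks m v_a v_b], bond vector
r = x_i − x_j, F the force on block i; the kinetic sum excludes grip
blocks.  With this sign convention tension appears as negative σ_xx, so
relaxation analyses use magnitudes.  The residual shear component σ_xy
under axial strain is a staggered-free-surface boundary effect that
decays with lattice size (≈10⁻³ of σ_xx at 10×10).

**Micro-cracks.**  A broken bond is one whose length has reached the
rupture cutoff of its resolved (current-species) potential; the flag is
monotone (first step recorded, never unset).  Broken bonds are clustered
by union-find: two broken bonds connect when they share a block or their
midpoints lie within one lattice spacing — the proximity rule keeps a
bifurcated crack connected as a single branched cluster across one
intact bond.  Each cluster's bounding extents are compared against the
sample: a cluster whose transverse (y) extent covers the free
surface-to-surface height within one spacing spans the sample, and any
transverse-spanning cluster means percolation — material failure under
horizontal tension.  Spans along both axes are reported.

**Stress decay.**  σ(t) = offset + amplitude·exp(−t/τ) is fitted by
bounded least squares (τ > 0); R² is computed on the raw series, not a
log transform, because the offset can be near zero.  A constant series
returns a degenerate-fit flag with zero amplitude rather than an error.

## Parameterization machinery

The model-reduction step fits the three truncated-harmonic parameters to
a tabulated energy-vs-distance profile.  Because the objective is
non-differentiable in `r_c`, the cutoff is found by grid search; at each
candidate cutoff the model is linear in (k, k·r_o) with V(r_c) = 0 built
into the functional form, so k and r_o come from an exact linear
least-squares solve.  Points beyond a candidate cutoff contribute their
squared energies to the total residual (the model is zero there), which
is what lets the search locate the rupture distance; a winner at the top
of the grid is flagged as a boundary solution (no rupture signature in
range, e.g. a pure parabola).

The synthetic-profile generator samples the truncated-harmonic law on a
uniform distance grid with optional Gaussian noise (deterministic per
seed).  It emulates the *shape* of stretch-energy curves obtained from
resolved composite models, not their provenance: real profiles carry
anharmonicity, hysteresis and sampling noise that the generator does not
reproduce, so recovery tests validate the fitting machinery itself, not
any original atomistic reduction.  With zero noise all three parameters
are recovered to 0.1% whenever the true cutoff lies on the grid; with
500 kJ/mol noise (≈1% of the well depth) the spring constant is
recovered within 5% in ≥90 of 100 replicates (tested).

## Problem sizes and test conditions

The reference full-scale experiment — 300×300 blocks held at 5% strain
for 2·10⁷ steps (7 μs) — is replicated at reduced scale: the package's
benchmark uses a notched 100×100 lattice held for 3·10⁴ steps (10.5 ns).
This is sufficient because stress relaxation in the smaller sample
reaches its plateau within a few nanoseconds: the measured trace decays
exponentially (R² > 0.9) to below a tenth of the loading stress, through
a non-percolating population of >10³ broken bonds in hundreds of
micro-crack clusters, with damage counts monotone — the same qualitative
outcome as the full-scale run, at desk scale.  Unit and property tests
use 10×10 to 40×40 lattices; the time-step convergence check (halving
Δt leaves the final damage count unchanged and the final stress within
1%) uses a notched 10×10 lattice at zero temperature with friction
0.5 ps⁻¹, conditions under which the damage cascade is deterministic and
dt-robust.

## Known limitations

* Strictly 2-D: no prism stacking, plate bending or out-of-plane
  dynamics; no angular or many-body terms.
* No dynamic re-bonding and no excluded volume between never-bonded
  blocks; the model is meaningful for tensile loading at strains up to
  ~20% (larger strains warn).
* The damage cascade is chaotic at large system sizes: individual
  switching sequences depend on the noise seed (each run is bit-exactly
  reproducible for a fixed seed), while aggregate observables — stress
  ratio, crack statistics, percolation status — are stable across seeds.
* Stress in a 2-D model is force per length; comparison to experimental
  (3-D) stresses requires a through-thickness convention that the
  package deliberately does not impose.
* The conversion from per-area energies of resolved-model stretch curves
  to per-bond energies is accepted as a user-supplied scale factor; no
  automatic conversion is attempted.
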