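# Methods

## Charge scaling

The electronic continuum correction approximates electronic polarization in
a fixed-charge force field by uniformly scaling the charges of ionized
moieties by *q*, equivalent to screening their Coulomb interactions by an
electronic dielectric ε_el = 1/*q*². We implement the relation as
*q*² = 1/ε_el throughout: it is the form consistent both with the Born
electronic term −N_A z²e²/(8π ε₀ r₀)(1 − *q*²) and with the familiar
*q* = √(1/2) ≈ 0.7 for ε_el ≈ 2. (Statements equating *q* itself with 1/ε_r
appear in parts of the literature; they are inconsistent with the (1 − *q*²)
factor and we do not follow them.)

Two scaling conventions are provided because force-field ports localize
formal charge differently:

- **Group mode** multiplies the net-charge-carrying charge group by *q* and
  validates that each listed group sums to an integer formal charge within
  1e-4 e. A scaled topology records its `applied_scale`, so validation still
  works when a scaled topology is rescaled (including inversion with 1/*q*,
  which recovers the original charges to < 1e-9 e in memory).
- **Weighted mode** mixes per-atom charged- and neutral-form charges with
  weights *q* and 1 − *q*. By linearity the residue lands at *q*·formal, and
  whenever the two forms differ only inside the charge group the result
  coincides with group mode.

Charge-group membership per residue ships as an editable YAML file
(`eccperm/data/charged_groups.yaml`) with CHARMM-style atom names for Asp,
Glu, Lys, Arg, protonated His, charged termini and monatomic ions. The
defaults are illustrative: group membership is a force-field convention, not
a universal fact, and production use should supply the file matching the
actual topology.

Scaled charges are kept at full float precision in memory. Only at write
time are they rounded to 6 decimals, and any rounding residual (necessarily
< 1e-4 e per residue) is smeared in 1e-6 e steps over the edited atoms so
that the file-level residue sum equals *q*·formal exactly. Untouched lines
of the source topology are re-emitted byte-identically.

Ion Lennard-Jones sigmas for intermediate scaling factors are linearly
interpolated between anchors optimized per 0.05 step; epsilon is never
modified, and extrapolation outside the anchor range is refused. Anchor
tables are config input (CSV), not hard-coded, since they are
force-field-specific optimization results.

Constants are CODATA 2018: e = 1.602176634e-19 C, N_A = 6.02214076e23 /mol,
ε₀ = 8.8541878128e-12 F/m, R = 1.98720425864083e-3 kcal/(mol K).

## Solvation-shell measurement

The first-solvation-shell radius — the optimization target for
radius-corrected ion LJ parameters — is the center of a Gaussian
A·exp(−(r−μ)²/2σ²) least-squares fitted to the highest 7 bins of the
ion–water-oxygen RDF (0.002 nm bins by default). Decisions where the
procedure admits variants:

- The 7 points are the highest bins **contiguous with the first peak**
  (grown greedily around the first strict local maximum with g > 1 past the
  excluded-volume region), not the 7 globally highest bins; a tall second
  shell must not contaminate the fit.
- Ties at the peak break toward smaller r. Fit initialization:
  μ₀ = argmax bin, σ₀ = 2 bin widths, A₀ = max g.
- The fit is amplitude-free: rescaling g(r) leaves μ unchanged.

RDFs are computed from bare coordinate arrays with orthorhombic
minimum-image distances and ideal-gas shell normalization (uniform targets
give g → 1). Triclinic boxes are rejected rather than silently mis-imaged.

## Occupancy coding

The selectivity filter is modelled as five oxygen-layer planes (z ascending
toward the extracellular side) bounding sites S1–S4, an S0 cap above the top
plane and an SCav extension below the bottom one, all restricted to a
cylinder around the pore axis. Defaults — s0_cap = scav_depth = 0.4 nm,
axis_radius = 0.25 nm — are explicit, configurable choices of this package;
published analyses do not print their exact boundaries. z intervals are
half-open (lower-inclusive) so plane-sitting particles are assigned once;
lateral distances are minimum-imaged against the box so pore particles
wrapped across the boundary are still counted.

Per site the letter is K if ≥ 1 ion is present, else W if ≥ 1 water oxygen,
else 0; multiple ions in one site yield a single K plus a logged warning
(counts survive in the per-ion site labels). Geometry can be static or
recomputed per frame from the SF-oxygen layers (drifting filters).

## Permeation statistics

A permeation event is a complete traversal, detected with a two-gate
hysteresis: an ion whose last bath contact was below SCav and that is next
seen above S0 scores +1 (outward), and symmetrically −1. Boundary flicker at
site edges cannot double-count because only bath contacts flip the gate.
Under time reversal the outward and inward counts swap exactly; reversing
time *and* flipping the z-axis leaves them unchanged (the two inversions
cancel).

Currents use the one-ion-one-elementary-charge convention: charge scaling is
a mean-field description of electronic screening, while the physically
transported charge per K⁺ is the full e. So I = n_net·e/t and g = I/V, with
n_net the signed event sum (outward − inward). Replicas are aggregated as
mean ± SEM (sd/√N). State populations carry percentile-bootstrap 95% CIs
from frame resampling (default 1000 resamples; block resampling available
for correlated frames — frame-level bootstrap knowingly understates the
variance of strongly autocorrelated trajectories, so choose the block length
or the observation stride accordingly).

The salt-concentration utility uses the 55.5 mol/L molarity of pure water:
c = (n_cations/n_waters)·55.5.

## Mechanism graphs

The rate from state A to state B is the inverse of the mean first passage
time: the mean, over entries into A, of the time until the first subsequent
frame in B, with passages still pending at the trajectory end censored (a
pair with no completed passage has an *undefined* rate, never zero).
Replicas are pooled at the passage-time level — never spliced end to end,
and never averaged as rates, which would weight replicas incorrectly.

Lumping is progressive and trajectory-first: while the fastest inter-state
rate exceeds the cutoff, that pair is merged, the discrete trajectory is
relabeled, and all rates are re-estimated on the relabeled frames (not by
algebraic graph contraction — MFPTs are not additive under contraction).
Lumped nodes are named by joining member codes with "+" in lexicographic
order; their populations are exact sums of member populations, and lowering
the cutoff can only merge further.

The rate-limiting step is operationalized as: among undirected pairs whose
|net flux| is at least half (configurable) of the total permeation flux
measured on the same trajectories, the pair with the smallest forward rate
(in the direction of positive net flux). If no pair reaches the threshold —
including zero net flux — the maximal-flux pair is returned flagged with a
warning rather than an exception, since exploratory graphs frequently have
diffuse flux. Node "ion count" classes count K letters over all six sites by
default (the S1–S4 window is available), and a lumped node whose members
disagree gets class `None`.

## Synthetic generators

`simulate_ctmc` is an exact Gillespie simulation (exponential waiting times,
categorical jumps) observed at a uniform stride, returning both the observed
trajectory and the full jump log. It validates MFPT estimation (two-state
chain: MFPT = 1/k up to a discretization bias ≤ stride/2), stationary
distributions, and bootstrap population recovery.

`simulate_channel` emulates direct knock-on kinematics: ions hop single-file
between the six site centers with forward/backward rates (the bias playing
the role of voltage), enter from the baths and exit past the gates, under a
one-ion-per-site exclusion rule. Emitted coordinates sit at site centers
plus uniform jitter bounded to 25 % of the site half-width (and half the
pore radius laterally), so site assignment is unambiguous by construction
and discretization reproduces the generator's code sequence at 100 % of
frames. Waters fill ion-free sites with a configurable probability.

Two details make ground-truth event recovery a theorem rather than a
rate-dependent approximation: exited ions are returned to the entry-side
pool only at frame boundaries (every bath visit is observed at least once),
and a recycled ion re-enters under a fresh identity — a grand-canonical bath
swap — so no ion id ever jumps between baths and the two-gate detector sees
exactly the traversals the generator recorded.

Default demo rates (hops 20/ns with 10:1 outward bias, entry 10/ns, exit
20/ns) are chosen so desk-scale runs of tens of ns accumulate hundreds of
events; intra-filter hopping at tens per ns is realistic (lumping cutoffs in
the hundreds of /ns appear in published mechanism graphs), but the overall
event rate is then far above a real ~100 pS channel (~0.1 events/ns), so the
demo conductance is illustrative, not physiological. The demo mechanism
cycle (`demo_mechanism_ctmc_spec`) drives WKKKK0 → WKKK0K → WKK0KK → WKKKK0
with a designed 0.3/ns bottleneck on the WKKK0K → WKK0KK leg against 5/ns
elsewhere; the measured MFPT-inverse of the bottleneck comes out slightly
below 0.3 because an MFPT includes excursions through the third state.

What the generators do **not** model: energetics, electrostatics, water
co-permeation, multi-ion correlations beyond hard exclusion, and lateral
escape from the pore. Passing round-trip tests therefore demonstrates the
correctness of the discretization/counting/graph machinery, not force-field
realism.

## Problem sizes and numerics

Default test problem sizes (chosen as the package's own balance of
statistical power against runtime): 10 seeds × 500–1000 ns for two-state
MFPT checks; 600 ns at 0.01 ns stride for lumping hand-traces; 25–50 ns of
coordinate-level channel for round-trip checks; 50 seeds × 1000 frames for
bootstrap coverage; ~10⁴ jumps per seed for chi-square goodness-of-fit of
the embedded jump chain. Gaussian fits converge with scipy's
Levenberg–Marquardt at xtol = ftol = 1e-12; charge-group integrality uses a
1e-4 e tolerance; uniform-stride validation uses a 1e-6 relative tolerance.

## Known limitations

- Topology parsing covers the `[ atoms ]` block dialect (one or more
  blocks); directives such as `#include` are preserved verbatim but not
  expanded.
- The MDAnalysis-backed reader assigns SF-oxygen layers by sorting z and
  averaging five equal contiguous chunks; filters tilted enough for layers
  to interleave need explicit per-layer selections upstream.
- Weighted-state scaling expects formal charges of ±1 (the amino-acid case);
  multivalent residues would need the group route.
- Rates below ~1/duration are unobservable; the estimator reports them as
  absent rather than extrapolating.
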