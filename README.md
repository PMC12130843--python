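# eccperm

Charge-scaling (ECC) force-field preparation and ion-permeation analysis for
molecular-dynamics studies of potassium channels.

Classical fixed-charge force fields neglect electronic polarization, and MD
simulations of K⁺ channels built on them underestimate single-channel
conductance by an order of magnitude. The **electronic continuum correction
(ECC)** treats electronic screening as a mean field: the partial charges of
ions and ionized groups are scaled by a factor *q* < 1, related to the
electronic (high-frequency) dielectric constant by *q*² = 1/ε_el — for the
typical ε_el ≈ 2 of organic media, *q* ≈ √(1/2) ≈ 0.7. `eccperm` implements
the methodological layer of such a study for people who prepare and analyze
scaled-charge channel simulations:

**Force-field preparation** (`eccperm.topology`, `eccperm.solvation`)

- *Group scaling* (CHARMM-style): the charge group carrying the formal charge
  (e.g. –CH₂–CO₂⁻ of Asp, net −1 e) is multiplied by *q*; per-residue net
  charge becomes *q*·*z* and neutral systems stay neutral.
- *Weighted-state scaling* (AMBER-style, where the formal charge is spread
  over the backbone): each atom gets *q*·q_charged + (1−*q*)·q_neutral.
- *Radius-corrected ion LJ parameters*: linear interpolation of optimized
  sigma anchors on the 0.05 grid of scaling factors (epsilon untouched), and
  the measurement that anchors them — an ion–water-oxygen RDF (0.002 nm bins)
  whose first peak is located by fitting its 7 highest points with a Gaussian.
- *Born-model solvation targets*: with ΔG_ele = −N_A z²e²/(8π ε₀ r₀)(1 − q²),
  the scaled-charge simulation should reproduce ΔG_MD = ΔG_Exp · *q*².
- The Eyring relation ΔΔG = RT ln(k₁/k₂) between rate ratios and barrier
  differences (10:1 at 310 K ↔ 1.4 kcal/mol).

**Trajectory analysis** (`eccperm.sfstate`, `eccperm.permeation`,
`eccperm.mechgraph`)

- Selectivity-filter occupancy coding: sites S0–SCav bounded by the five
  oxygen-layer planes of the filter, each frame reduced to a 6-letter code
  over {K, W, 0} (e.g. `WKKK0K`).
- Permeation counting with a two-gate state machine (an ion must touch the
  intracellular bath and then the extracellular one), conversion to current
  and conductance with the one-ion-one-elementary-charge convention
  (I = n·e/t, g = I/V), replica aggregation (mean ± SEM), and state
  populations with frame-bootstrap confidence intervals.
- Mechanism graphs: per-pair rates defined as inverse mean first passage
  times (MFPT), net fluxes from direct transition counts, progressive lumping
  of state pairs whose exchange rate exceeds a cutoff, and identification of
  the rate-limiting step (the slowest transition carrying the dominant net
  flux).

**Synthetic generators** (`eccperm.synth`) provide ground-truth test beds:
an exact CTMC simulator over occupancy codes and a coordinate-level
single-file ion-hopping channel whose emitted trajectories are exactly
recoverable by the analysis layer.

## Worked example

Simulate a synthetic outward-driven channel, discretize it, count
permeations and get a conductance:

```python
from eccperm import (demo_channel_spec, simulate_channel, discretize_trajectory,
                     detect_permeation_events, conductance_from_events,
                     state_populations)

spec = demo_channel_spec(seed=11, duration=100.0)   # 100 ns, 0.05 ns stride
res = simulate_channel(spec)
traj = discretize_trajectory(res.frames, spec.geometry)
events = detect_permeation_events(traj)
net = sum(e.direction for e in events)
print(traj.n_frames, net)                            # 2001 510
print(conductance_from_events(net, spec.duration, 150.0))  # 5447.4 pS
```

2001 frames yield 510 net outward events; at +150 mV that is 5447 pS — the
demo generator hops deliberately fast so that desk-scale runs accumulate
statistics (a real K⁺ channel at ~110 pS produces ~0.1 events/ns). The
discretized codes and detected events equal the generator's ground truth
exactly; `state_populations(traj, n_boot=1000, seed=1)` adds bootstrap CIs
per occupancy code.

The same steps from the shell:

```sh
$ eccperm eyring --ratio 10 --temp 310
1.4
$ eccperm conduct --count 515 --voltage 150 --duration 5000
515 net events over 1 x 5000.0 ns at +150 mV: current 16.50 pA, conductance 110.0 +/- 0.0 pS (SEM, N=1)
$ eccperm scale-top --in system.itp --out system_q078.itp --factor 0.78 --scheme group
$ eccperm synth channel --seed 7 --out demo/
$ eccperm discretize --fixture demo/trajectory.csv --codes codes.csv --events ev.csv --axis-xy 2 2
$ eccperm graph --codes codes.csv --cutoff 50 --total-flux 100 --out graph.json --dot graph.dot
```

The first command converts a 10:1 rate ratio at 310 K into a 1.4 kcal/mol
barrier difference; the second converts 515 permeation events counted over
10 × 500 ns at +150 mV into 16.50 pA and 110.0 pS.

## Layout

| module | contents |
| --- | --- |
| `eccperm.topology` | charge scaling (group / weighted), LJ sigma interpolation, Born & Eyring utilities |
| `eccperm.solvation` | RDF computation, first-shell Gaussian fit |
| `eccperm.sfstate` | site geometry, occupancy codes, trajectory discretization |
| `eccperm.permeation` | event detection, conductance, replica SEM, bootstrap populations |
| `eccperm.mechgraph` | MFPT rates, mechanism graphs, lumping, rate-limiting step |
| `eccperm.synth` | CTMC and coordinate-level channel generators with ground truth |
| `eccperm.io` | GROMACS `[ atoms ]` dialect, fixture/interchange CSVs, MDAnalysis reader |
| `eccperm.cli` | `eccperm` command-line front end |

See `docs/methods.md` for the model details, parameter choices and known
limitations.
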