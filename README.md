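# dynmech

Analysis toolkit for the mechanics of the cytoplasmic dynein motor:
optical-trap stall-force analysis, structural trajectory geometry of the
microtubule-binding domain (MTBD), and kymograph-based motility
classification — with synthetic-data generators that make every stage
testable end to end.

## The problem

Dynein walks toward microtubule minus ends and works against load.  A
force-sensitive point mutation in the MTBD can leave unloaded motility
untouched while collapsing the motor's stall force — the resistive load
at which a motor-driven bead stops advancing before detaching.  Asking
whether a mutant is force-sensitive requires three quantitative
pipelines, each of which this package implements as a library with a
thin CLI:

1. **`dynmech.trap`** — analysis of trapped-bead force traces:
   block-mean downsampling (5 kHz → 250 Hz), trap calibration from the
   Lorentzian fit to the bead power spectrum
   `S(f) = D / (π² (f_c² + f²))` with stiffness `κ = 2πγ f_c`, stall
   detection (stationary periods at force > 2.5 pN lasting > 100 ms,
   terminated by a snap-back of the bead to the trap center; a 1 pN /
   150 ms variant admits the low-force pauses of a force-sensitive
   mutant), stall force (mean force over the last 20 % of the event),
   stall time (time spent at ≥ 80 % of the stall force), a 3-Gaussian
   fit to the pooled force-sampling histogram with subtraction of the
   unbound near-0 pN peak, and a double-exponential fit
   `w·e^(−t/τ₁) + (1−w)·e^(−t/τ₂)` to the stall-time survival curve.

2. **`dynmech.geometry`** — structural observables from coordinate
   trajectories of an MTBD + stalk fragment bound to the α/β-tubulin
   dimer: tubulin principal axes (PA1 longitudinal, PA2 radial toward
   the MTBD anchor Cα pair, PA3 tangential), MTBD and stalk vectors,
   signed projected angles with Gaussian peak fits, least-squares
   (Kabsch) superposition, per-residue RMSF relative to the
   microtubule, and contact detection — salt bridges (basic N to
   acidic O ≤ 4 Å), hydrophobic pairs (side-chain C ≤ 8 Å) and
   hydrogen bonds (donor–acceptor ≤ 3.5 Å, H–donor–acceptor
   angle ≤ 30°) — with per-frame indicator series and percentage
   frequencies.

3. **`dynmech.motility`** — single-particle tracks read off
   kymographs: binding events ≥ 1.5 s, processive if a window covers
   ≥ 500 nm at a sustained rate, static vs diffusive by an exact
   permutation test on MSD growth, piecewise-linear velocity segments
   whose unweighted mean is the run velocity, and count-based scoring
   percentages.

**`dynmech.synthetic`** generates every input with injectable ground
truth: an exact Ornstein–Uhlenbeck bead in a harmonic trap driven by a
phenomenological motor (`v(F) = v₀ max(0, 1 − F/F_d)^w`, stall dwell,
instantaneous snap-back, optional low-force pausing), a toy
motor–tubulin complex whose reference geometry is known analytically, a
trajectory generator with a controlled tilt-angle mixture, per-residue
noise and exact contact scheduling, and kymograph tracks with known
class labels.

## Worked example

```python
from dynmech.synthetic import TrapSimParams, MotorModelParams, simulate_bead_trace
from dynmech import trap

trace, truth = simulate_bead_trace(
    TrapSimParams(duration=10.0, seed=1),
    MotorModelParams(detachment_force_mean=4.0, detachment_force_sd=0.5),
)
analysis = trap.downsample(trace)          # 5 kHz -> 250 Hz block means
events = trap.detect_stalls(analysis, trap.wild_type_criteria())
summary = trap.summarize_stalls(events)
print(f"{summary.n} stalls, mean stall force {summary.mean_stall_force:.2f} "
      f"+/- {summary.sem:.2f} pN (SEM)")
for e in events[:3]:
    print(f"  stall {e.start:6.2f}-{e.end:6.2f} s  force {e.stall_force:.2f} pN  "
          f"stall time {e.stall_time*1e3:.0f} ms  snap-back: {e.detached}")
```

prints

```
6 stalls, mean stall force 4.39 +/- 0.22 pN (SEM)
  stall   0.12-  1.59 s  force 3.47 pN  stall time 1448 ms  snap-back: True
  stall   2.02-  3.25 s  force 4.71 pN  stall time 1140 ms  snap-back: True
  stall   4.15-  4.72 s  force 4.31 pN  stall time 516 ms  snap-back: True
```

The six detected stall forces track the six detachment forces the
simulated motor actually drew (3.50, 4.72, 4.32, 5.06, 4.41, 4.48 pN):
each event's stall force is the mean trap force over the event's final
fifth, and with a 0.5 pN spread in the detachment-force distribution
the sample mean lands at 4.39 ± 0.22 pN.  Simulating many traces with
the spread set to zero recovers the injected 4.0 pN to within 0.02 pN
(see the test suite).

The same flow runs from the shell:

```bash
dynmech simulate trap --seed 1 --out traces/ --n-traces 5
dynmech analyze trap --traces 'traces/*.tsv' --criteria wt --out analysis/
dynmech simulate trajectory --config traj.yaml --seed 3 --out sim/
dynmech analyze trajectory --structure sim/complex.pdb --frames sim/frames.csv --out geo/
dynmech simulate tracks --seed 2 --out kymo/
dynmech analyze tracks --input kymo/tracks.csv --out motility/
```

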