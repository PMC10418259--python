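# Methods

This note documents the models, conventions and numerical choices
behind `dynmech`, what the synthetic generators do and do not emulate,
and the limitations a user should know before applying the pipelines to
real data.

## 1. Bead-in-trap simulation (`dynmech.synthetic.trap`)

A bead of drag γ in a harmonic trap of stiffness κ attached to a motor
tether at position *m* obeys an Ornstein–Uhlenbeck (OU) process about
the tether.  Integration uses the *exact* discrete update

    x[i+1] = m + (x[i] − m)·a + √(k_B T/κ · (1 − a²))·ξ,   a = e^(−Δt/τ),  τ = γ/κ,

so there is no Euler step-size bias at any sampling rate; at zero
temperature the bead sits exactly at the tether.  Force is κ·x.

Defaults (units in parentheses): κ = 0.055 pN/nm (mid of the 0.05–0.06
operating band of a single-bead assay at fixed laser power), γ =
1.2×10⁻⁵ pN·s/nm (an 800-nm polystyrene bead with a surface-proximity
correction, corner frequency ≈ 730 Hz), T = 296 K (room temperature),
5 kHz acquisition, 30 s records.

The motor is phenomenological — the assays constrain only the
*behaviour* (ramps, stalls, snap-backs, low-force pausing), not the
kinetics — and is the simplest model producing that behaviour:

* force–velocity: v(F) = v₀ · max(0, 1 − F/F_d)^w, v₀ = 800 nm/s,
  w = 1; F_d is drawn per attachment from N(4.0, 0.5²) pN (floored at
  0.5 pN);
* when the tether load reaches 98 % of F_d the motor clamps at the
  stall plateau (tether force exactly F_d) for an exponential dwell
  (mean `stall_duration_mean` = 0.5 s), then detaches; the tether
  returns instantaneously to the trap center (snap-back).  With
  `snap_back_present=False` the motor never detaches, producing stalls
  without snap-backs;
* rebinding after an exponential unbound dwell (mean 0.5 s) at the
  current bead position;
* mutant mode: while moving with tether force inside
  `pause_force_band` (default 1–2 pN), pauses start at rate
  `pause_probability_per_s` and last an exponential time; a pause ends
  in detachment with probability 0.3, otherwise the motor resumes.
  A pause band the motor cannot reach triggers a warning and no pauses.

Every stall, pause and detachment is logged with ground truth
(`TrueEventLog`), along with a per-sample motor state series, so
detector recovery can be scored exactly.  The dwell/rebinding/pause
parameters are this package's own additions: stall *durations* are not
derivable from the assay description, and without a dwell parameter the
stall-time statistics could not be generated; 0.5 s puts the simulated
dwell mixture in the observed sub-second range.

## 2. Trap trace analysis (`dynmech.trap`)

**Downsampling** is by non-overlapping block means (noise reduction,
not decimation); an affine signal maps onto its block-midpoint values
exactly, which the tests use as a closed-form check.

**Calibration.**  The one-sided position spectrum of a trapped bead is
Lorentzian, S(f) = D/(π²(f_c² + f²)) with D = k_BT/γ and
f_c = κ/(2πγ).  A pointwise-sampled OU process is an AR(1) process
whose spectrum is the *alias-folded* Lorentzian, so
`calibrate_stiffness` fits Σ_{k=−10..10} S(f + k·f_s) to a
Welch-averaged spectrum with relative-error weighting (the periodogram
noise scales with the spectrum); fit range 5 Hz – 0.45·f_s.  Without
folding, the fitted corner frequency is biased high by tens of percent
when f_c is within a decade of Nyquist.  The pure single-Lorentzian fit
remains available (`fit_lorentzian(..., n_alias=0)`) and inverts a
noiseless Lorentzian to 10⁻⁶ relative.  Stiffness is κ = 2πγf_c.

**Stall detection.**  A sample is a candidate when its force is at
least `min_force` *and* within `stationary_tolerance` of the trace's
running median over a 100 ms window (edge-replicated).  Maximal
candidate runs longer than `min_duration` become events.  If
`snap_back_required`, a sample within `snap_back_max_interval`
(default 20 ms) after the run must drop by `snap_back_min_drop`
(default 2 pN) below the event's median force, or below 0.5 pN.
Wild-type criteria: 2.5 pN / 100 ms with snap-back; mutant criteria:
1 pN / 150 ms without the snap-back requirement, admitting both pauses
and stalls of a motor that dwells at low force — a reproducible
surrogate for the manual review such traces otherwise need.

Numerical choices and their consequences:

* `stationary_tolerance` defaults to 0.75 pN ≈ 3.75σ of the 250 Hz
  block-averaged force noise at the default trap parameters (σ ≈ 0.2
  pN).  A much tighter band (e.g. 2σ) makes individual noise samples
  break candidate runs faster than the 100 ms minimum duration and the
  detector finds nothing; 3.75σ keeps runs intact for tens of seconds
  while still rejecting force jumps.
* The stationarity test is *local*, so a slow force ramp is itself
  "stationary" and an event can begin on the ramp shoulder below the
  plateau.  The stall force, computed from the final 20 % only, is
  insensitive to this; the snap-back requirement provides specificity.
* Raising `min_duration` can only remove events (the candidate runs
  are fixed).  Raising `min_force` is *not* monotone in the event
  count: a higher threshold can split one run into two fragments that
  both pass the remaining filters.  This is a property of per-sample
  thresholding, not an implementation artifact.
* Index conventions: stall force averages samples from
  ⌈start + 0.8·(end − start)⌉ through the end sample inclusive (a
  plateau drifting 3→4 pN reads 3.9); stall time counts samples in
  [start, end) at ≥ 80 % of the event's own stall force, so a
  rectangular 0.5 s plateau reads exactly 0.5 s.  Neither window
  extends past the event.

**Force-sampling histogram.**  Pooled force samples are binned at
0.25 pN and the normalized density fitted with a sum of 3 Gaussians by
least squares (the histogram is fitted, not the samples), initialized
from the highest local maxima of a lightly smoothed copy.  The
component nearest 0 pN is the unbound dwell.  Subtraction removes every
component whose mean lies within max(2σ₀, bin width) of zero: when the
data are genuinely unimodal at zero the 3-component fit degenerately
splits the unbound peak across components, and removing only one would
leave spurious "bound" mass.

**Stall-time survival fit.**  The empirical 1−CDF is fitted with
w·e^(−t/τ₁) + (1−w)·e^(−t/τ₂) (nonlinear least squares, τ bounded
positive, w ∈ [0,1]), initialized from log-linear fits to the head and
tail thirds.  If the two time constants agree within 10 % the data are
effectively single-exponential: the model is refitted with one
exponential and flagged `degenerate`.  Standard errors come from the
fit covariance.  Means are reported ± SEM with the n−1 standard
deviation.

## 3. Toy complex and trajectory generator

The toy complex is a *geometric stand-in*, not a physical model.
Tubulin is an elongated slab of residues (Cα grid exactly symmetric in
x and y) whose longest principal axis is +z by construction; the
α-chain sits at negative z so the longitudinal axis is signed α → β.
The MTBD anchor Cα pair (labels A3295/W3395) midpoints at (0, 25, 0),
putting the radial axis at +y; the MTBD vector (anchor midpoint to the
A3288/Y3402 midpoint) is (0, 10, 0); two stalk arms rise at 60° from
the MTBD top and carry the R3191/S3501 pair.  A glutamate (dynein
E3306) and an arginine (α-tubulin R402) face each other with a closest
N–O distance of ≈ 5.5 Å — outside the 4 Å salt-bridge cutoff, so the
contact is *off* until scheduled.  Residue numbering mirrors human
dynein heavy-chain numbering for the eight labeled residues so
selections read identically on real models.  Layouts whose tubulin
second moments come out equal (e.g. a square cross-section) are
rejected as degenerate.

`generate_trajectory` emulates trajectory *observables*: per frame it
(i) samples a tilt from a Gaussian mixture and rigidly rotates the
dynein chains about `tilt_axis` through the anchor midpoint, (ii) adds
per-residue isotropic Gaussian noise (one displacement shared by a
residue's atoms; optionally restricted to chosen chains), and (iii)
forces or breaks scheduled contacts by moving the single closest
relevant atom radially across the cutoff, so the realized per-frame
contact count equals round(frequency · n_frames) exactly, with the
realized value recorded.  Zero noise + zero tilt + empty schedule is a
bitwise identity.  What this does **not** emulate: any force field,
solvent, correlated backbone motion, side-chain rotamers, or coupling
between tilt and contacts — so passing tests demonstrate that the
*measurement pipelines* are correct and unbiased, not that real
trajectories behave this way.

## 4. Geometry pipelines (`dynmech.geometry`)

Principal axes are computed from unit-mass tubulin Cα atoms: PA1 is the
eigenvector of largest spread (smallest moment), signed from the α- to
the β-tubulin center; PA2 is the component of (anchor midpoint −
tubulin center) orthogonal to PA1; PA3 = PA1 × PA2.  Near-equal
leading moments raise a degeneracy error.

Projected angles take the plane and reference axis as explicit
parameters because the two natural readings of "the MTBD angle in the
plane perpendicular to the longitudinal axis" disagree: the pipeline
default measures the around-axis tilt in the PA2–PA3 plane against PA2
(plane normal PA1), and the stalk angle in the PA1–PA2 plane against
PA1; `literal_methods=True` instead projects the MTBD vector onto the
PA1–PA2 plane against PA2.  Signs follow the right-hand rule about the
plane normal; angles live in (−180°, 180°].  A distribution may be
re-zeroed for reporting against a reference peak; any such offset is
the caller's explicit choice.

Superposition is least-squares with a proper rotation (no reflection),
via `scipy.spatial.transform.Rotation.align_vectors`; the RMSD is
recomputed from the residuals because the solver's internal residual
uses a cancellation-prone formula that is unreliable below ~10⁻⁷.
Collinear or <3-point sets are rejected.  The stalk vector superimposes
a full-length reference onto each frame using the stalk-base Cα
selection (mtbd-chain residues 3288–3402 present in both structures)
and reads the R3191/S3501 midpoint off the transformed reference.

RMSF aligns every frame to the first frame's tubulin Cα atoms and
takes the per-residue Cα root-mean-square deviation about the
across-frame mean (not about a reference frame).  For isotropic
per-residue noise of sd σ the closed form is σ√3; note that when the
*alignment selection itself* is noisy, the fitted rotations acquire
O(σ/√N) jitter that a long lever arm (the stalk) amplifies by a few
percent — the generator's `noise_chains` option exists to separate
that alignment property from estimator bias.  Fluctuation comparisons
are reported as 100·(mean RMSF_variant / mean RMSF_baseline − 1) over
a residue selection.

Contacts: basic-N/acidic-O ≤ 4 Å (distinct residues) for salt bridges;
side-chain carbons (carbon atoms other than backbone C/CA; glycine has
none) ≤ 8 Å for hydrophobic pairs; hydrogen bonds need donor–acceptor
≤ 3.5 Å and an H–donor–acceptor angle ≤ 30° at the donor.  The atom
tables (Lys NZ, Arg NE/NH1/NH2, His ND1/NE2; Asp OD1/OD2, Glu OE1/OE2;
standard donor/acceptor valence) are editable defaults, since no
universal enumeration exists.  Hydrogens are associated to a donor by
same-residue proximity (≤ 1.2 Å).  Hydrogen-bond detection *requires*
hydrogens; an explicit `heavy_atom_fallback` accepts donor–acceptor
distance plus an antecedent–donor–acceptor angle ≥ 90° when an
antecedent heavy atom exists, and distance alone otherwise — a looser
criterion, which is why it is opt-in.  Distance series report the
minimum kind-relevant atom distance per frame; thresholding that series
at the salt-bridge cutoff reproduces the per-frame salt-bridge
indicator by construction.

## 5. Motility classification (`dynmech.motility`)

Tracks shorter than 1.5 s (3 frames at ~2 fps) are excluded.  A track
is processive when some window achieves ≥ 500 nm displacement at a
sustained rate ≥ 100 nm/s — the automated equivalent of a sloped
kymograph line.  The rate qualifier matters: a pure excursion rule
fires on long diffusive walks, which reach 500 nm often but slowly.
Remaining tracks are static when the net displacement is < 210 nm
(2 pixels) *and* an exact permutation test finds no significant MSD
growth; otherwise diffusive.  The test statistic is the lag-1 MSD:
under the static null the positions are exchangeable (iid localization
noise about a fixed point), so permuting them gives the exact null
distribution, and because the total variance is permutation-invariant
this is a von Neumann ratio test for positive path correlation.
Significance defaults to 0.01 with 499 permutations (seeded
deterministically from the samples), keeping the static false-call
rate at 1 % while the event lengths give the test power against slow
diffusion.  These surrogate rules are decisions, not reconstructions
of anyone's manual scoring.

Velocity segmentation is recursive binary splitting of the
position–time line fit: a split is accepted when it reduces the summed
squared residuals by more than `breakpoint_tolerance` (default 25 %
relative) with both sides ≥ 1 s.  Run velocity is the *unweighted*
mean of segment speeds (a duration-weighted option exists behind a
flag); run length is the net first-to-last displacement.  Streaming
velocities are per-track least-squares slopes, averaged per group
(e.g. per embryo) because the group is the unit of comparison.
Scoring percentages are exact fractions with integer display rounding.

Track generator defaults (frozen after a design-time separability
check): processive runs 4–10 s at |N(800, 200²)| nm/s (floor
150 nm/s); static and diffusive binding events 12–22 s; diffusion
coefficient 2×10³ nm²/s (0.002 µm²/s, slow 1-D lattice diffusion);
localization noise 10 nm (centroid precision of a bright spot at
105 nm pixels); frame interval 0.5 s.  Under these defaults the
classifier recovers the generating class for ≥ 99 % of tracks; with
shorter events or coarser localization the static/diffusive boundary
degrades gracefully toward the test's significance level.

## 6. Problem sizes and determinism

All generators are bitwise reproducible given (params, seed).  The
test suite and the acceptance script use fixed problem sizes chosen so
each statistical check has comfortable margin: 24 traces × 10 s for
stall recovery, 30 s at 5 kHz for calibration, 100 random traces of
10⁴ samples and 1000 random atom configurations for the oracle
equivalences, 10⁴ frames for the RMSF closed form, 5×10⁴ samples for
the 3-Gaussian fit, 2×10³ dwell times for the survival fit and 4×10³
frames for the two-peak angle fit.

## 7. Known limitations

* The motor model is a stand-in; its parameters are not claimed to
  match dynein kinetics, only to produce the ramp/stall/snap-back/pause
  phenomenology with controllable ground truth.
* The stall detector's stationarity rule is local; very slow drifts
  below the tolerance band pass as stationary (see §2).
* Event-count monotonicity holds in `min_duration` but not in
  `min_force` (run splitting).
* Contact chemistry tables are defaults, not a reconstruction of any
  specific software's tables; results at the cutoff boundary depend on
  them.
* The trajectory generator's tilt and contacts are independent by
  construction; correlations between orientation and binding that real
  trajectories may show are out of scope.
* Insertion codes, altlocs and multi-model PDB inputs are unsupported;
  residue keys are (chain role, author residue number).
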