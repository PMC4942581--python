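# Methods

## Task and coordinate conventions

The analyses assume a 10-element reaching sequence: from a centre target at
the origin to each of five outer targets (7 cm radial distance) and back,
one element per 0.5 s, positions in cm sampled at 1 kHz, time zero at trial
start. The five outer-target angles are not identifiable from the task
description we emulate; the default geometry spreads them at 90°, 162°,
234°, 306° and 18°. Every headline quantity (structure counts, complexity
values, relaxation monotonicity, scenario ranks) is angle-independent;
absolute jerk magnitudes are not, and are treated as convention-dependent
throughout.

## Minimum-jerk via-point trajectories

Within a chunk the hand model minimizes ∫‖d³r/dt³‖²dt subject to
interpolating each target at its scheduled time. Boundary conditions are
rest-to-rest: zero velocity *and* zero acceleration at both chunk ends.
Zero end-velocity is part of the halt definition; zero end-acceleration is
a package choice that makes chunks genuinely independent subproblems (the
concatenated trajectory has a well-defined, finite jerk at boundaries) and
reproduces the classic single-reach quintic r(τ) = D(10τ³ − 15τ⁴ + 6τ⁵),
whose integrated squared jerk is 720 D²/T⁵ and whose peak/mean speed ratio
is 1.875.

By the Euler–Lagrange condition the minimizer is piecewise quintic with
continuity of derivatives 1–4 at interior via points. We solve the
resulting square linear system in per-segment quintic coefficients (local
time τ ∈ [0,1] per segment for conditioning; ≤ 60 unknowns per chunk,
solved densely). The integrated squared jerk of a solution is evaluated
analytically from the polynomial coefficients; the test suite validates
the solver against an independent equality-constrained quadratic program
(KKT system over the same coefficient space but with only C⁰–C² continuity
imposed, jerk Gram matrices by Gauss–Legendre quadrature) to 10⁻⁶ relative
cost on random instances.

A geometric consequence worth knowing: when a chunk contains a collinear
out-and-back pair (centre → outer → centre with no later asymmetry to
break the reflection symmetry), the optimal via-point passage has exactly
zero speed — the model "flies through" by momentarily reversing, not by
looping. Boundary detection must therefore not treat every zero-speed
instant as a halt (below).

## Efficiency

Efficiency is the negative squared jerk of the duration-normalized trial:
the trial is affinely stretched to 5 s and resampled (cubic interpolation,
5000 uniform samples) because integrated squared jerk scales as T⁻⁵ and
faster execution would otherwise masquerade as a smoothness change. Jerk is
estimated by three differentiation stages with a smoothing pass before
each: a 101-tap (100-ms support) Hamming-windowed sinc FIR, 10 Hz cutoff,
applied forward–backward (zero phase) with odd-reflection padding so linear
trends pass unchanged. The statistic is the *mean* per-sample squared jerk
(cm² s⁻⁶), which is sampling-rate invariant; the raw time integral
(cm² s⁻⁵) is exposed separately because the analytic oracles are stated for
it. The filter support is the experimentally motivated constant; the cutoff
is a package default chosen well above the ~2–6 Hz content of 0.5-s
reaches.

Because the absolute jerk scale depends on these conventions, outlier
filtering in the pipeline defaults to a batch-relative threshold (95th
percentile of squared jerk) rather than an absolute value; an absolute
threshold (default 0.2 cm² s⁻⁶, the scale used in the joystick literature
this emulates) remains available, and no conclusion in the package depends
on absolute jerk magnitudes.

## Chunk-structure machinery

Structures are 9-bit HALT/VIA vectors; complexity is
log Σ_j exp(M_j) over chunk lengths M_j — exactly permutation-invariant,
strictly increased by merging adjacent chunks, with attainable range
[1 + ln 10, 10]. Degenerate sets (identical-complexity classes) are the 42
integer partitions of 10.

**Boundary detection** follows the adaptive threshold rule: candidate
halts are interior local minima of the smoothed speed below 5% of the
trial's peak; between consecutive local maxima exceeding 25% of peak only
the lowest candidate is kept; plateaus collapse to their first sample for
determinism. Two package choices extend the rule where it is underspecified:

* a candidate only counts as a halt if speed stays below threshold for at
  least 25 ms (default). A genuine halt dwells at the target (even a
  rest-to-rest model passage spends ≳ 60 ms below a 5% threshold), whereas
  a collinear-reversal via point crosses zero speed for ~10–15 ms. Setting
  `min_halt_ms=0` recovers the bare rule.
* retained minima are assigned to the nearest of {sequence start, the 9
  internal boundaries (capture times when available, else the uniform
  schedule), sequence end}; minima nearest the start/end belong to the
  rest phases bracketing the sequence and are discarded; ties go to the
  earlier boundary.

## Pareto frontier

The default frontier is the convex upper envelope of the 512
(complexity, efficiency) points (monotone-chain upper hull pruned to
nondominated vertices): it is the natural "maximum achievable efficiency
per unit complexity" trade-off curve and exhibits diminishing returns. The
staircase of merely nondominated points is computed as well
(`pareto.nondominated`); the two differ in what they guarantee — every
landscape point is pointwise-dominated by a staircase point, but only
envelope-dominated by the hull.

## Learning-path analyses

**Scenario simulation.** Efficiency improvement over a unit learning
interval is the normalized saturating exponential
E(t) = (1 − e^(−t/C)) / (1 − e^(−1/C)); complexity as a function of
efficiency uses the same family with a signed exponent k = 2 − 1/C_e:
X(E) = (1 − e^(−kE)) / (1 − e^(−k)), the diagonal at C_e = ½. C_e < ½
gives a convex path hugging the Pareto frontier (complexity deferred);
C_e > ½ a concave path away from it (complexity spent early); X is
pointwise increasing in C_e, so smaller curvature always costs less en
route. The exact functional family is a package choice constrained to the
stated qualitative properties (exponential improvement; both curves map
0→0, 1→1, strictly increasing; parameter-ordered curvature). Defaults:
curvatures (0.05, 0.25, 0.5, 1.0, 2.0) as scenarios 1–5, rates
(0.1, 0.25, 0.4) as curves E1–E3; cumulative outlay ∫₀¹X(E(t))dt by
adaptive quadrature (tolerance 10⁻⁸), ranked per rate with ties broken by
scenario order.

**Random-walk null.** Day-to-day complexity changes are summarized by a
Gaussian (sample mean/SD of successive differences, ≥ 3 days). Null
walkers start at the observed day-1 complexity and take i.i.d. Gaussian
steps, each state clipped to the attainable range [1 + ln 10, 10] (the
walk must stay in realizable structure space; the clip is a package
choice). The per-walker statistic is its average complexity across days;
the observed path's percentile in 5,000 walkers measures
cost-effectiveness (low percentile = complexity kept low for the
efficiency achieved). Simulations are vectorized and bit-reproducible
given a seed.

**Degenerate-set trend.** Squared jerk vs within-set repeat index is
modelled as jerk = a_i·e^(b·repeat)·noise across the top-8 most frequent
degenerate sets, fitted on the log scale as a linear mixed model with a
per-set random intercept (statsmodels MixedLM, REML). The log-scale fit
linearizes the exponential fixed effect and assumes multiplicative noise —
the stable standard estimator for this design. b is z-tested (Wald). Sets
with fewer than 10 trials are dropped; if the random-intercept variance
collapses the per-set offsets fall back to mean residuals.

**Prevalence vs efficiency.** Within each visited degenerate set with ≥ 2
members, observed structure selection frequencies are compared with model
efficiencies. Default pooled mode rank-transforms both within each set,
pools across sets, and computes one Spearman ρ; per-set mode computes one
ρ per set (≥ 3 members) and t-tests the per-set values against zero. The
pooled mode is the default because single sets are small (≤ 42 members)
and many are visited sparsely.

## Synthetic-data generator

The generator emulates the multi-day joystick recordings the analyses were
designed for: per trial it takes a planted chunk structure's model
trajectory, optionally blends it toward a per-element trapezoidal-speed
profile (constant-acceleration ramps over 10% of the element), inserts
dwell pauses at HALT points (the trial lengthens; duration normalization
downstream absorbs this, as in the real pipeline), and adds Gaussian
position noise low-pass filtered at 5 Hz. Capture times are emitted per
element. Trials are deterministic given the RNG state.

The default learning schedule emulates a cost-effective (efficiency-first)
learner over 20 days × 100 trials: dwell pauses shrink from 250 ms
(reactive, cue-driven captures, comparable to a reaction time) to 50 ms
(anticipatory), noise decays 0.02 → 0.005 cm, and the trapezoid blend
0.32 → 0.02, all mostly within the first half; in the second half HALT
bits melt into VIAs (Markov drift calibrated so the expected halt count
falls 9 → ≈1.5 by the last day, with a 12× smaller reverse rate).
Trial-to-trial variability comes from transient exploration flips whose
probability decays 0.03 → 0.002, so unique structures per day decrease
while consecutive-trial Hamming distances stay small but nonzero. 20 × 100
is the package's desk scale for end-to-end positive controls; the schedule
generalizes to any (n_days, trials_per_day).

Two generator caveats matter for interpreting passing tests. First, the
trapezoidal blend raises measured squared jerk at weight 1, but it is not
a monotone efficiency dial: under the triple-smoothed jerk statistic,
intermediate blends can measure *smoother* than pure minimum jerk (the
10-Hz smoothing crushes the trapezoid's high-frequency corner bursts while
its constant-speed cruise contributes no jerk at all). The schedule
therefore drives the efficiency trend with dwell, noise and structure
merging, and uses the blend as a trajectory-shape (goodness-of-fit) dial.
Second, noise amplitudes are kept in the regime where velocity noise stays
below the 5% detection threshold; at several times the default noise,
boundary detection degrades (missed halts and split chunks), as it would
on real data — detection accuracy on noisy input is a measured property,
not a guarantee.

What the generator does *not* emulate: biomechanics (no arm dynamics,
torques or muscle noise), reward and reaction-time processes, speed
profile asymmetries of real reaches, target-capture tolerance windows, or
any within-day fatigue/warm-up structure. Passing end-to-end tests show
the pipeline recovers planted structure and planted learning trends under
the model's own kinematic assumptions — not that real kinematics satisfy
those assumptions.

## Numerical choices and degenerate inputs

* Trials shorter than 3× the filter support are rejected for smoothing;
  fewer than 7 samples for jerk; zero-duration trials for normalization.
* Duplicate via-point times and all-zero speed profiles raise errors;
  singular via-point systems surface as diagnostics rather than NaNs.
* Ties: lowest-minimum selection and minima-to-boundary assignment break
  toward the earlier sample/boundary; scenario rank ties toward the
  earlier scenario; plateau extrema collapse to their first sample.
* The 512-structure landscape is cached per geometry within a process.

## Known limitations

* The efficiency statistic's absolute scale is convention-bound; only
  comparisons within a fixed convention are meaningful.
* The convex-hull frontier assumes the trade-off is meaningfully convex;
  with very different geometries (e.g. near-degenerate target angles) the
  staircase may be the safer object.
* The mixed model assumes a shared decay rate across degenerate sets with
  set-specific amplitudes only; a set-specific-rate model is out of scope.
* Boundary detection is the threshold rule only — no probabilistic or
  HMM segmentation — and inherits that rule's sensitivity to the 5%/25%
  thresholds, exposed as parameters for sensitivity analysis.
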