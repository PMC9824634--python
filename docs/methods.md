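# Methods

This note documents the models, algorithms and numerical choices
behind `msaccid`, and what the bundled synthetic data can and cannot
establish about real recordings.

## Signal model and preprocessing

A fixation recording is a monocular gaze trace (x, y in degrees of
visual angle) at a fixed rate, 1 kHz by default. The trace is modeled
as the **additive** superposition of four components: a microsaccade
train, drift (power in 0–40 Hz, mean speed a few arcmin/s), tremor
(70–103 Hz, RMS tens of arcseconds) and i.i.d. Gaussian sensor noise.
Additivity is an approximation justified by the components' disjoint
frequency/amplitude signatures.

Preprocessing runs in order:

1. **Spectral low-pass at 104 Hz** — per-axis DFT, bins above the
   cutoff zeroed, inverse DFT. Eye movements carry no power above this
   frequency; everything removed is sensor noise.
2. **Kalman smoothing** (optional, off by default) — per-axis
   constant-velocity linear filter, state (position, velocity),
   transition [[1, dt], [0, 1]], piecewise-constant-acceleration
   process noise scaled by `q` (default 1e-4) and measurement variance
   `r` (default 1e-3). Implemented directly; it is the standard
   textbook filter.
3. **Mains notches** — DFT bins within ±0.5 Hz of 50 and 100 Hz zeroed.
4. **Event detection** (below), then detected intervals are excised by
   linear interpolation and the residual is split by DFT restriction
   into drift (0–40 Hz) and tremor (70–103 Hz). The two bands plus the
   discarded remainder reconstruct the residual exactly.

All spectral filters operate on the full trace with no tapering.
Because the trace is not periodic, the DFT filters ring near the two
ends (Gibbs transients); rather than taper (which would bias the band
contracts), the detectors exclude the first and last 50 ms of each
trace. On a 15 s fixation this discards 0.7 % of the data.

### Detectors

Intervals are 0-based and half-open everywhere.

**Velocity detector** (default). Step velocities are smoothed by an
11-sample moving average; per-axis scale is the median-based SD
estimate sqrt(median(v²) − median(v)²), robust to the events
themselves. A sample is supra-threshold when
(vx/η_x)² + (vy/η_y)² > 1 with η = λ·SD and λ = 6. A run of
supra-threshold samples becomes an event when (a) it lasts ≥ 6 ms and
(b) its peak normalized radius reaches `peak_lam` = 20. The peak
criterion is the package's adaptive enhancement of the classical
velocity threshold: band-limited tremor at the simulated scale
produces brief bursts that cross 6 SDs (measured up to ~14) but never
approach microsaccadic peaks (measured ≥ 42 across the test cohorts),
so the two-threshold scheme separates them cleanly. With these
defaults, detected event counts stay within ±30 % of ground truth and
interval-level F1 ≥ 0.89 on all simulated test traces.

**Chi-square detector** (config switch). For every window of 11
samples, the 10 squared steps per axis, normalized by a robust
baseline step SD (1.4826 × MAD over the whole trace), form a
chi-square(10) statistic under quiet Gaussian motion. A window is
flagged when either axis exceeds the upper quantile at the
Šidák-split tail 1 − sqrt(1 − α), giving the two-axis test exact size
α (default 0.01) per window; overlapping flagged windows merge.
Summing both axes into one statistic would have 20 degrees of freedom,
not the intended 10, and would not be calibrated — hence the per-axis
construction.

## The 13 features

Per event (n points, 1 ms spacing): duration (n−1 ms); height (max
distance of interior points from the chord through the endpoints,
computed as |cross product|/base, equivalent to the Heron/semi-
perimeter form; with a zero base the distance to the start point is
used); area; sharpness H/S (0 when S < 1e-12); base length; the
base/duration ratio (deg/ms) and the mono/double flag (double iff
ratio < 0.01; a tie is mono); mean step speed; windowed maximal speeds
over all full windows of 11 and 21 step speeds (falling back to the
mean when the event is shorter); mean signed pseudo-acceleration
(first differences of the speed magnitudes — a telescoping mean, so it
can be negative); the mean of the 10 largest pseudo-acceleration
magnitudes (all of them when fewer exist); maximal pairwise diameter
(O(n²), events are short).

**Area of a self-crossing trajectory.** The trajectory is implicitly
closed. Crossings between non-adjacent edges are found by solving the
2×2 linear system for the two edge parameters; a crossing exists iff
the matrix is invertible and both parameters lie in [0, 1] (a
non-invertible matrix means parallel edges). The closed walk is then
split: whenever a crossing point is met the second time, the loop
between its occurrences is a simple polygon whose absolute shoelace
area is accumulated and which is excised from the walk; the remainder
contributes its absolute area. For simple curves this is the plain
shoelace area; for out-and-back figure-eights and isolated crossings
it equals the sum of the planar-arrangement face areas; for fully
interleaved patterns (a pentagram) a region wound k times is counted
once per covering loop. Trajectories of real microsaccades are in the
first two classes.

Counting note: the double ratio and the binary double flag are both
features (P6 and P7), which is how the count reaches 13 from 12
printed scalar quantities.

**Normalization.** Each feature column is divided by its Euclidean
norm over the *training* events only; the same scales are applied to
held-out data. An all-zero column keeps scale 1.

## Distances and the error ratio

The quasilinear form ρ_ql(A,B) = Σ w_i δ_i² + Σ_{i<j} w_ij δ_i δ_j
(δ = feature difference) has N = 91 nonnegative weights, unit norm:
13 single-feature weights then the 78 i<j cross weights in
lexicographic order. For general nonnegative weights the form is
indefinite; its value *as a distance* is the magnitude |δᵀMδ|, which
coincides with the raw value exactly when the weight matrix is
positive-semidefinite, i.e. when the form is a genuine squared
distance. The magnitude — rather than clipping negatives to zero — is
deliberate: clipping declares the entire negative cone of the form
"distance zero", and the weight optimizer then fakes arbitrarily small
within-person distances by making the form negative on them, which
generalizes terribly (held-out segments land in the wrong person's
negative cone). With the magnitude there is no such shortcut. The
signed value remains available (`raw=True`).

Segment distances: `d1` (minimum pairwise ρ — optimistic, provably
violates the triangle inequality, see the constructed counterexample
in the tests), `d2` (ρ between feature mass centers), `d3` (ρ between
*trimmed* centers: events are ranked by ρ to the untrimmed center and
the closest ceil(0.9·n) re-averaged — robust to outlier events).
Person distance `dP` is the minimum segment distance. The error ratio
`Err` is the sum of within-person segment distances (unordered pairs)
over the sum of between-person distances (ordered pairs of distinct
persons — the verbal definition; including i = k would put
within-person terms in the denominator). `Err` is degree-0
homogeneous in the weights.

**Learning uses d2, identification uses d3.** The d3 trim ranking
changes discontinuously with the weights (a swap in the kept set jumps
the center), littering Err with micro-discontinuities that dominate
finite-difference gradients — measured at stalled iterates, the
numeric "gradient" had norm ~3 while its negative was an ascent
direction at every step size. The d2 objective is piecewise smooth
and optimizes cleanly; the trimmed d3 then provides outlier robustness
where it matters, in the held-out comparison. Both remain available
everywhere via the `d_name`/`--distance` switches.

## Optimization

Minimize Err over {w ≥ 0, ‖w‖ = 1}. Start: 91 Uniform(0,1) draws,
normalized. Gradient: central finite differences (h = 1e-4), one-sided
where a negative probe would leave the feasible set. After each step,
negative components are zeroed and the vector renormalized (free,
since Err is scale-invariant). Two line searches:

* `crawl` (default): an adaptive step length, capped at ξ = 1e-3 —
  halved until a decreasing step is found, then the iterate crawls
  forward in multiples of that step while the objective decreases,
  probing one extra step past the last win; the step length persists
  (doubling after success, never above ξ). Gradients are computed once
  per outer iteration, which is the expensive operation.
* `halving`: classical backtracking from step 1 by halves.

Stop when the iterate displacement falls below tol = 1e-6 (the
stopping threshold is a package default; no canonical value exists),
or after `max_iter` iterations (500 by default; the bundled study uses
60, which suffices for a ~3× Err reduction at this problem size).
Accepted Err values are strictly decreasing by construction.
`multi_start` runs 30 seeded restarts (seeds = base_seed + index) and
returns the best final Err along with all runs.

## Identification protocol

Leave-one-fixation-out: per person, four fixation segments train
(feature scales from pooled training events; weights from multi-start
descent on the training cohort), the fifth is held out. The table cell
(r, c) sums d3 from test segment r to each of person c's four training
segments. Greedy assignment: the first pick is the global minimum of
the raw table; after removing its row and column, each remaining row
is divided by its row sum (L1) before the next global minimum, and so
on. An all-zero row is left unnormalized. Ties break to the lowest row
index, then the lowest column index (the protocol itself does not
specify tie handling). Non-square tables are rejected; the protocol
guarantees square ones.

## Synthetic data

Profiles are drawn per person: microsaccade rate 1–2 /s
(literature-typical; the study protocol does not fix it), amplitude
mean 0.15–0.25° (bracketing the canonical 12 arcmin) with SD
0.02–0.06°, peak-velocity scale 25–60 deg/s (sets event duration,
clipped to 8–80 ms), double fraction 0–0.3, drift speed 2–6 arcmin/s,
tremor RMS 0.002–0.006° (≈7–22 arcsec), sensor noise SD
0.0005–0.002°. Cohorts default to a latin-hypercube layout (each
parameter on an even grid with independent seeded permutations), so
simulated persons are clearly distinct — the regime the identification
study assumes. Uniform random profiles are available with
`separated=False`.

One event is a straight stroke with a Gaussian speed bell
(σ = duration/6, a single realistic velocity peak); a double event
appends a mirrored return stroke whose endpoint offset stays below
half the mono/double threshold. Events arrive by a Poisson process
with overlapping arrivals re-drawn (≥10 ms separation); gaze stays
where an event ends. Drift and tremor are white noise band-restricted
by DFT masking and rescaled to the target mean speed / RMS; sensor
noise is i.i.d. Gaussian. All randomness flows through explicit
integer seeds; identical seeds give bit-identical data, and every
trace carries its ground-truth intervals.

**What the simulator does not emulate:** oculomotor main-sequence
correlations beyond the amplitude–duration link, curved or torsional
event trajectories, binocular conjugacy, blinks and artifacts, head
motion, and any drift/tremor structure beyond their band and scale.
Passing the end-to-end study therefore shows the pipeline is correct
and self-consistent under the stated signal model — not that real
populations are separable; that question needs real recordings.

## Study scale and runtime

The bundled identification study uses 4 persons × 5 fixations × 15 s
at 1 kHz, velocity detection, 30 optimizer restarts × 60 iterations on
the d2 objective, d3 identification — about 6 minutes on one CPU. The
expensive step is the 91-component finite-difference gradient (182 Err
evaluations per iteration); Err evaluation is vectorized over segment
pairs via the 13×13 weight matrix.

## Known limitations

* ρ_ql with indefinite weight matrices is not a metric; the package
  takes magnitudes and documents the consequences rather than
  projecting onto PSD matrices (which would abandon the 91-weight
  parameterization this package exists to study).
* d1 violates the triangle inequality by construction (tested).
* Finite-difference gradients on a piecewise-smooth objective have no
  convergence guarantee; the strict-decrease line search makes every
  accepted step an improvement, and multi-start hedges local minima.
* The greedy assignment is not the Hungarian optimum; it reproduces
  the published procedure exactly, including the raw first pick.
* FFT filters assume long traces; on clips much shorter than ~1 s the
  50 ms edge exclusion becomes a large fraction of the data.
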