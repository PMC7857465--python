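# Methods

## Data model and grids

A waveform is one joint-angle curve (degrees) time-normalized to one
gait cycle and sampled uniformly.  Two grid conventions are used by the
generators and both are carried explicitly on the `Waveform` object:

- the sine simulator samples t = 1..100 (% cycle, 100 points, no
  duplicated endpoint), the natural grid for a model defined by
  sinusoids of the cycle fraction;
- the Fourier engine reconstructs on t = 0..100 (101 points), so that a
  cyclic curve shows its (identical) start and end sample.

The index computations are grid-agnostic: they only require that all M
curves of a group share one grid.  CSV I/O keeps the file's own uniform
grid by default so that write/read round-trips are sample-exact;
resampling onto a 0–100% grid of any size is available by argument and
uses linear interpolation with endpoint clamping.

ROM (range of motion) is defined as the peak-to-peak excursion
max − min of the sampled curve.  This is the only definition under
which the simulators' "offset as %ROM" calibration is self-consistent.

## Indices

Definitions are in the README.  Numerical choices:

- All summary SDs are sample SDs (denominator M − 1).  This convention
  is what makes the offset-case intercept spread come out at
  √(2.5)/2 ≈ 0.79 of the maximum imposed offset for the five-point
  symmetric design, matching the published progression.
- The CMC radicand is kept in the result as a diagnostic.  A negative
  radicand (within-frame variance exceeding variance about the grand
  mean) marks the index undefined; it is never materialized as a
  complex number, and renders as "–" in reports.  A group with zero
  total variance (all samples of all curves equal) is flagged
  `degenerate`.
- LFM R² is the squared Pearson correlation between curve and
  reference, identical to the OLS coefficient of determination for a
  simple regression with intercept.  A constant curve against a
  non-constant reference gets R² = 0; a constant reference is an error
  (`degenerate reference`).
- The R² > 0.5 linearity rule is reported as a boolean flag
  (`linear_assumption_valid`), never enforced.
- CMC similarity strata: poor [0, 0.60), moderate [0.60, 0.75), good
  [0.75, 0.85), very good [0.85, 0.95), excellent [0.95, 1].

## Sine-curve simulator

Curves follow k(t) = O + (1+α)(ROM/C)[0.5 sin(2π(t−τ)/100) +
0.5 sin(4π(t−τ)/100)] on t = 1..100.  C is the peak-to-peak amplitude
of the bracket, evaluated on a dense cycle grid (≈ 1.760173; the exact
stationary-point value is 2·0.5·s(1+2c) with c = (−1+√33)/8,
s = √(1−c²), and the dense evaluation agrees with it to ~1e−10).
Dividing by C makes the ROM parameter the curve's actual peak-to-peak
amplitude up to grid discretization (< 0.05° at T = 100).

Each case/level builds five curves varying one factor, the others held
at zero (ROM fixed at 5° when varying α, O, τ):

- offsets: O_j = O_max · {−1, −0.5, 0, 0.5, 1}, with O_max the stated
  %ROM converted to degrees;
- time shifts: τ_j = τ_max · {0, 0.25, 0.5, 0.75, 1} (one-sided, since
  shifts are stated as 0–τ_max ranges), applied as continuous phase
  shifts inside the sine arguments;
- amplitude factors: spacing equal to the stated α, so the extremes
  reach ±2× the stated value (`doubled`, the default) or extremes at
  the stated ±α (`stated`).

The equal spacings themselves are a design choice calibrated against
the published index values: the offset spacing is pinned by the
SD−a₀ and MAV columns, the time-shift spacing by the CMC and R²
anchors, and the amplitude spacing by SD−a₁ and MAV.  The two α
conventions are both kept because the published table is internally
inconsistent: the MAV/RMSD/SD−a₁ cells match the doubled spacing while
the CMC column of the α case matches the narrower stated spacing
(recomputation gives 0.97 vs the printed 0.99 under `doubled`).  The
discrepancy is documented rather than hidden, and one further cell
(offset case, level V CMC: printed 0.04, recomputed ≈ 0.06) recomputes
differently under every convention tried; tests flag it at its
recomputed value.

## Fourier engine

A mean gait curve is modelled as y(t) = A0/2 + Σ_k [A_k cos(2πkt/100)
+ B_k sin(2πkt/100)].  Fitting is linear least squares on the sampled
grid (not an FFT), so it handles the 101-point grid with duplicated
endpoint and arbitrary uniform grids alike.  The order n is the
smallest whose reconstruction RMSE is below the tolerance, default
0.01° (1/100 of the ~1° precision of optical gait measurement); the
reached RMSE is recorded on the model.  If the grid's Nyquist order
cannot reach the tolerance the fit fails, reporting the best RMSE.

Perturbations act in coefficient space: an offset O adds 2·O to A0; α
scales every harmonic pair by (1+α); a time shift τ rotates pair k by
kθ, θ = 2πτ/100.  For a band-limited model the rotation is exactly the
circular time shift, so no resampling is involved; the three operators
commute, and ROM scales exactly by (1+α) because the constant term
carries no ROM.

## Synthetic gait cohort

The stride generator stands in for a measured cohort.  Base curve
shapes are synthetic fixtures — band-limited trigonometric curves
hand-tuned to the qualitative features of normative sagittal gait
(hip: near-sinusoidal flexion–extension, 2 harmonics; knee: stance
flexion bump plus a large swing peak, 5 harmonics; ankle: biphasic
dorsi/plantar-flexion with a push-off trough, 4 harmonics).  Subject
templates rescale the base shape to a ROM drawn from N(43, 6²) for the
hip, N(64, 6²) for the knee and N(19, 1.5²) for the ankle (degrees;
truncated below at 1°), plus a subject offset drawn from N(0, 3²)
(hip/knee) or N(0, 1.5²) (ankle).  The ROM distributions follow the
between-subject magnitudes typical of healthy adult treadmill walking
(knee > hip > ankle); the offset SDs are a package choice of the order
of marker-replacement effects, kept below the between-subject offset
perturbation ranges so that those ranges dominate the BS contrast.

Stride groups draw, per curve: α ~ U(−α_max, α_max) (as a fraction of
the template ROM), O ~ U(−O_max, O_max)·ROM/100 (degrees), τ ~
U(0, τ_max) (% cycle), and reconstruct the perturbed template on 101
points.  Draw order is fixed (subject ROM, subject offset; then per
curve α, O, τ) and a single seeded generator threads through all
draws, so every group is reproducible from one seed.  The generator
records its draws, which is what makes exact parameter-recovery checks
possible: in pure-offset groups the LFM intercepts equal the drawn
offsets centred on their group mean, and in pure-amplitude groups
a₁_j(1+ᾱ) = 1+α_j — the centring/normalisation appears because the
reference is the group mean, and random uniform draws (unlike the sine
simulator's symmetric designs) do not average to zero.

Because the base shapes are synthetic, analyses built on them
reproduce qualitative structure — WS/BS orderings, the dominance of
time shift in mixed perturbations, joint-shape effects on CMC — not
any real cohort's exact index values.  Passing tests therefore
demonstrate correctness of the machinery and of the orderings, and say
nothing about the specific numbers a particular laboratory would
measure.

## Monte Carlo engine

Default perturbation ranges (maximums, per joint and comparison):
within-subject α = O = 5 %ROM, τ = 5 %cycle for all joints;
between-subject hip 10/30/10, knee 5/15/10, ankle 10/20/10 (α %ROM /
O %ROM / τ %cycle).  A WS simulation perturbs one subject template
M = 5 times; a BS simulation perturbs five independently drawn
templates once each.  Single-factor blocks zero the other two ranges;
the mixed simulation (MS) draws all three at once.  Each block is
assumed to be Monte Carlo with the stated number of simulations
(default 1000).

Aggregation is two-level: CMC and MAV are averaged (mean, sample SD)
across simulations, with undefined-CMC draws excluded from the CMC
statistics and counted (`n_undefined_cmc`, logged at warning level);
LFM coefficients and RMSD are first summarized (mean, SD) across the
five curves of each group, then those means and those SDs are averaged
across simulations.  ROM is reported as mean ± SD across simulations
of the group-mean curve's ROM.  Row seeds of the 24-row grid derive
from one master seed via a spawned seed sequence, so the whole grid is
reproducible from a single integer.

Tests and the acceptance checks run the grid at 200 simulations per
row with fixed seeds; the qualitative orderings they assert are stable
well below that.

## Rendering

Stored results always keep full precision.  Reports round half away
from zero — dimensionless quantities (CMC, a₁, R²) to 2 decimals,
degree quantities to 1 — render an undefined CMC as "–" and a CMC
above 0.995 as ">0.99", and CSV output carries a parallel
full-precision column per formatted one so rendered files re-parse
losslessly.

## Known limitations

- The synthetic cohort's curve shapes are plausible but not measured;
  index values that depend on real curve shape (e.g. exact CMC levels
  per joint) are illustrative.
- The between-subject construction uses per-curve subject templates;
  pooling strategies (e.g. comparing subject means to a grand mean)
  would change BS magnitudes, not the WS/BS orderings.
- Only sagittal-plane, single-cycle, time-normalized curves are
  modelled; no event detection, filtering or motion-capture file
  formats.
- Pointwise dispersion indices (SD, CV, ICC, SEM, TEM, MDC, MAD, MD)
  are out of scope.
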