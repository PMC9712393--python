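# Methods

## The design problem

High-field protein NMR needs shaped carbon pulses that rotate the whole
aliphatic region (about 80 ppm, i.e. ±12 kHz at a 300 MHz carbon Larmor
frequency) exactly like a hard 90° or 180° pulse, while leaving the aromatic
and carbonyl regions untouched, and while respecting a hardware cap on the
peak rf amplitude (15 kHz nutation frequency).  `surbop` designs such
*band-selective universal-rotation* (UR) pulses with a gradient-ascent
optimal-control (GRAPE-type) loop and simulates their offset/B1 response.

A shaped pulse is a piecewise-constant control sequence `u_x[k], u_y[k]`
(Hz) with timestep `dt`.  For one isochromat at offset `nu` the step `k` is
an exact rotation by

    theta_k = 2*pi*dt*sqrt(u_x^2 + u_y^2 + nu^2)

about the unit axis `(u_x, u_y, nu)/|.|`, represented as a quaternion
`(A, B, C, D)` with `D = cos(theta/2)` and `(A, B, C)` the axis scaled by
`sin(theta/2)`.  Cumulative propagators are quaternion products; because
every step is an exact rotation there is no integration error — the only
approximation in the whole forward model is the piecewise-constant control
assumption itself.

### Rotation convention

Rotations are right-handed and active: a 90° x-pulse takes `+z` to `-y`, and
free evolution at positive offset rotates `+x` towards `+y`.  The mirrored
convention produces equally valid, phase-reflected pulses; all modules and
tests use the one convention, fixed in `surbop.quaternions`.

## Cost function

For each passband isochromat `i` (31 offsets equally spaced on ±12 kHz) the
cost is the component-wise squared quaternion distance between the net
propagator and the target rotation `U_F`; this pins both rotation axis and
angle, i.e. UR behaviour.  For each stopband isochromat `j` (31 offsets per
stopband, ±[18, 60] kHz) only `A^2 + B^2` is penalized: any z-rotation
(Bloch–Siegert-type phase shift) is free.  Every term is evaluated at five
B1 scales (0.95, 0.975, 1.0, 1.025, 1.05) that multiply the controls only.

The scalar cost averages the passband terms with `1/(2n)`, the stopband
terms with `1/(2m)`, and both over the B1 ensemble, with free multipliers
`w_sel` and `w_0` (default 1).  This normalization is chosen so that the
analytic gradient assembled from the averaged costate pairing is *exactly*
the derivative of the reported scalar — the package's finite-difference
tests enforce agreement to ~1e-6 relative.  With both weights at 1 the
passband and the stopbands each contribute half of a perfect-failure cost of
order 1, so cost values are comparable across grid sizes.

The quaternion distance penalizes `-U_F` (cost 4) although `-U_F` is the
same physical rotation: the literal double-cover penalty is kept because the
costate formalism is linear in it.  Empirically, optimizations from random
starts never stall on the wrong cover (the residual error is diffuse across
isochromats), so no sign-minimization option was needed in the default path.

## Gradients

The terminal costate is the derivative of the isochromat cost with respect
to the final propagator (`2*w_sel*(X_N - U_F)` in the passband,
`2*w_0*(A, B, 0, 0)` in the stopband).  It is transported backwards by
multiplying with conjugated step quaternions, and paired at step `k` with
`dq_k/du * X_{k-1}`, where `dq_k/du` is the *closed-form* derivative of the
step quaternion with respect to each control.  The classical small-rotation
generator form (`H_x = pi*dt * L_{e_x}`, a first-order approximation) is
available as `scheme="first_order"`; it agrees with the exact scheme to a
few percent at 15 kHz controls and is retained only for comparison.  Because
the B1 scale multiplies the controls before propagation, the chain rule
contributes a factor `b1` per ensemble member; omitting it fails the
finite-difference test at the ±5 % scales.

## Optimizer

Projected descent: `u <- u - eps * grad`, followed by radial clipping of any
over-limit step to the 15 kHz amplitude cap (phase preserved; a 1e-12
relative dead-band makes the projection exactly idempotent).  The update
direction is steepest descent by default or Polak–Ribière conjugate
gradients (`scheme="conjugate"`), with an automatic restart to steepest
descent whenever the conjugate direction stops being a descent direction
under the projection.

The step size uses an approximate line minimization: starting from the last
accepted step, double while the cost drops, otherwise halve (and, if the
remembered step is so small that the change is below floating-point
resolution, probe upwards); one parabolic interpolation refines the final
bracket.  The candidate evaluated is always the *clipped* pulse, so every
accepted step strictly decreases the constrained cost and the cost trace is
monotone with the constraint active.  A fixed-step mode reproduces the
literal constant-`eps` update for didactic use; it is not monotone.

Convergence is declared when the relative cost change stays below
`tolerance` (default 1e-8) for 10 consecutive iterations, or when no step
size along the descent direction improves the cost (a projected local
minimum).  Multi-start (`multi_start`) runs the loop from consecutive
seeds and ranks the results; the optimization landscape has many local
optima and the published campaign-style usage is hundreds of random starts.

## Starting shapes and study conditions

Random starting shapes draw per-step amplitude uniformly on `[0, u_max]`
and phase uniformly on `[0°, 360°)` (uniform polar sampling, matching the
"random amplitudes and phases" prescription), reproducible under a fixed
seed.  The flagship design uses `dt = 0.5 µs` and `N = 667` steps.  The
published pulse length of 333.3 µs is not an integer multiple of 0.5 µs;
667 steps (333.5 µs) is the closest realizable duration and is the package
default, with the duration an explicit configuration value.

## Response profiling

`response_map` propagates one spin per (offset, B1) grid point — the default
grid is 141 offsets over a 130 kHz span × 51 B1 scales on [0.8, 1.2] — and
records the final magnetization; net propagators are kept alongside so that
propagator-level metrics are available.  `offset_profile` applies a global
zero-order phase such that the central offset is purely absorptive,
mirroring how measured offset profiles are processed.

Metrics (`compute_metrics`) over the optimized region (|offset| ≤ nu_p, B1
within ±5 %):

* **passband ripple** = `100*(I_max - I_min)/I_max`, where the intensity I
  is the transverse magnitude for 90° targets or the inverted longitudinal
  component for 180° targets (configurable; the peak-intensity convention
  used for measured spectra is not uniquely defined, so the choice is
  explicit);
* **max phase deviation** of the net rotation axis from the target axis;
* **stopband leakage** = max `sqrt(A^2 + B^2)` of the net propagator over
  the stopband offsets.

## Problem sizes used in the tests

The unit tests exercise pulses of 8–50 steps against closed forms, an SU(2)
matrix-product oracle and a Bloch-ODE oracle.  The convergence benchmarks
use a reduced control count `N = 100` at the full 333.5 µs duration
(`dt = 3.335 µs`): this preserves the physical time-bandwidth situation of
the design problem while cutting the cost of one iteration by ~7x, and 300
line-search iterations reach below 1 % of the starting cost for both
targets.  A reduction that shortens the pulse instead (N = 100 at
`dt = 0.5 µs`, i.e. a 50 µs pulse) changes the physics: with a
time–selectivity product that small, the cost plateaus at 11–42 % of its
starting value for any number of iterations — a useful negative control,
kept in the unit tests as a descent smoke test only.  One full-scale single
run (N = 667, 1000 conjugate-gradient iterations, one seed) is part of the
acceptance suite.

## Known limitations

* Single uncoupled spins, no relaxation, no amplifier droop or other
  hardware distortion of the waveform.
* The optimizer is first-order (steepest/conjugate with line search);
  exact-Hessian methods are out of scope.
* A single run from one random start converges to a local optimum; matching
  the published shapes point-by-point is not expected and not attempted —
  quality is asserted through band-level properties.
* The average-cost formulation controls the *mean* band error; worst-case
  (minimax) stopband behaviour at the inner stopband edge converges much
  more slowly than the mean, which matters for single-run, fixed-iteration
  budgets (see the acceptance analysis).
* Shape files carry amplitude as percent of a calibration peak; absolute
  calibration is the user's responsibility when importing shapes.
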