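# Methods

## Model overview

The package studies isometric two-joint torque production: a fixed
posture, a planar torque space (shoulder horizontal flexion/extension x
elbow flexion/extension), and targets on the 1 Nm circle. At fixed
posture each muscle's force is affine in its activation — the active
force-length term scales with activation while the passive term does not
— so the whole plant collapses to

    T = D a + T_PL,        D in R^(2 x N_mus),  a >= 0,

where column `i` of `D` is muscle `i`'s torque per unit activation
(moment arms x maximum isometric force x active force coefficient) and
`T_PL` is the constant passive torque. The rigid-tendon convention is
used throughout: fiber length is a fixed function of posture, so the toy
muscle's force is exactly affine in activation and the affine fitter's
nontrivial exercise comes from an optional quadratic activation term
(`quadratic_gain`, default 0). The fitter regresses *normalized* force
(force / F_iso) on activation; its error statistics (mean absolute
error, normal-consistent median absolute deviation) are reported in
percent of F_iso.

Controllers are feedforward networks. The input is the 4-vector
`x = (tau_1, tau_2, b_1, b_2)`: the desired torque plus two constant
task-irrelevant bias inputs (b = (1, 1)), which give the network the
constant degree of freedom it needs to cancel `T_PL`. A learned input
matrix `W_inp` (n_m1 x 4) feeds an M1 layer of n_m1 = 1000 neurons; a
fixed innervation matrix maps M1 to muscles, either directly
(`a = relu(Z W_inp x)`, non-synergy) or through a fixed nonnegative
synergy matrix (`a = relu(W_syn Z_syn W_inp x)`). Innervation columns
are initialized uniformly on the unit sphere; `Z_syn` is rescaled
globally (one scalar) so the mean torque amplitude over M1 neurons
matches a reference non-synergy initialization — without this the two
architectures would start at different effective gains and their
learning could not be compared fairly. The global (rather than
per-column) rescaling is the minimal reading of matching the "average"
amplitude. Activations are rectified but not clipped above 1;
above-unit activations are legal and logged.

Learning is stochastic gradient descent with weight decay. Each trial
draws one target uniformly, runs the forward pass, and applies

    W_inp <- W_inp - alpha dJ/dW_inp - beta W_inp,
    J = 1/2 |tau - T|^2,

with the gradient flowing through the rectifier (subgradient 1 where the
pre-activation is positive, 0 otherwise — including exactly at 0). The
rule is implemented in increment form; the assignment form (replacing
the weights by the update) would discard the learned state each trial
and cannot be what "weight decay" semantics intend. The per-trial error
norm is recorded *before* the update so the curve reflects performance
at presentation time. Learning speed is the rate `v` of the
three-parameter exponential `|e_t| = gamma1 exp(-v t) + gamma2`, fitted
by bounded nonlinear least squares (all parameters nonnegative;
initialization gamma2 = last-decile mean, gamma1 = first-decile mean
minus gamma2, v = 10/n). The solver is started from a ladder of rate
guesses (x4 apart) and the lowest-residual fit is kept, because a single
start occasionally latches onto the first-trial transient (v ~ 1 with
negligible gamma1). Curves are fitted raw; a centered-moving-average
option exists but is off by default.

## The criteria

Direction bias (DB) measures the angular irregularity of the module
torques where it matters: on the circle the network must actually cover,
`|tau - T_PL| = 1`, centered at `-T_PL`. Each module's active torque ray
is intersected with that circle (the origin lies strictly inside
whenever `|T_PL| < 1`, so the forward intersection is unique and the
closed-form quadratic root applies); intersection points get polar
angles about the circle *center*; DB is the population (1/N) standard
deviation, in degrees, of the circular gaps between neighboring points.
With `T_PL = 0` this reduces to the angular regularity of the module
directions themselves. Power bias (PB) is the population standard
deviation of the module torque amplitudes in Nm; the definition as
printed in terms of vectors is read as a scalar-amplitude deviation,
matching its description as the spread of module "gains". Duplicate
directions are legal (a zero gap); `|T_PL| >= 1` raises rather than
extrapolating outside the supported geometry. DB is invariant to common
rotations and to amplitude changes; PB is invariant to rotations and
permutations and is positively homogeneous — the two criteria probe
orthogonal properties by construction.

## Synthetic plant

The generator emulates a 22-muscle two-joint system: column directions
stratified over eight 45-degree sectors (guaranteeing agonists and
antagonists around the whole plane), amplitudes log-normal with median
1 Nm and sigma_log = 0.5, passive torque in a seeded random direction
with exact magnitude 0.5 Nm by default (0.3 and 0.7 are the passive
scaling conditions). Construction verifies, by nonnegative least squares
on a dense 120-direction grid, that every unit-circle target is
reachable, and redraws otherwise. What the generator does *not* emulate:
posture-dependent moment-arm structure, anatomical muscle groupings,
activation dynamics, and correlated passive torques. Results on this
plant therefore validate the criteria's *logic* (that DB and PB track
learning performance under the stated learning rule), not any
muscle-specific anatomical claim.

## Learning-rate calibration

With unit-norm innervation columns, n_m1 M1 neurons and input scale
`|x|^2 ~ 3`, the effective gain of one gradient step on the torque error
is approximately `alpha |x|^2 (n_m1 / N_mus) lambda(D D^T)` — about
600 alpha for the default plant — so stability requires alpha below
~2e-3. The package default is alpha = 3e-5 with decay beta = 1e-4,
chosen once so that the non-synergy baseline at 25,000 trials lands at
the canonical operating point for this class of model: learning speed
v of a few 1e-3 per trial and a final error of a few hundredths of a Nm.
Larger alpha converges faster to a lower equilibrium error (the
learning-forgetting equilibrium error scales like beta/alpha); the
reported phenomena are about differences *between* module sets at a
fixed alpha, not about the absolute value.

## Module-set generation

The activation dataset holds one pattern per 3-degree torque direction:
a fresh non-synergy network is trained on the single target
`u + T_PL` (so that the *active* torque converges to `u`; training on
`u` alone would leave the active torque at `u - T_PL` because the
network also cancels the passive torque), the mean activation of the
last 100 trials is taken, and the pattern is rescaled so
`|D pattern| = 1` exactly. Dataset training uses alpha = 1e-4 and
20,000 trials per direction — single-target training converges to the
learning-forgetting equilibrium, and weakly actuated sectors converge
slowly, so the sweep default would sit above the 0.02 Nm convergence
check; directions that still miss it are retried (at most twice) with a
fresh seed and doubled budget, and a direction that fails all retries is
a hard error naming the angle.

FSforDB draws N_mod distinct patterns uniformly: all amplitudes are
1 Nm, so PB = 0 and only DB varies. FSforPB computes the ray directions
whose shifted-circle intersections are exactly evenly spaced (random
rotational offset), snaps each ray to the nearest dataset pattern by
actual torque direction, accepts the draw only if the realized DB stays
below 2 degrees (exact DB = 0 is unattainable on a 3-degree grid),
then applies gains uniform on [0.5, 1.5] renormalized to mean amplitude
exactly 1 Nm — select, scale, renormalize; the renormalization preserves
directions so the DB check is unaffected. The joint generator rescales
an FSforDB draw by independent gains, so both criteria vary and
decorrelate across draws (|r| ~ 0.03 over 60 draws). A candidate set
enters an experiment only if a synergy network using it learns the
12-target task below the feasibility cutoff (0.1 Nm; 0.15 Nm for the
joint family), which screens out sets whose learning falls into poor
local optima; rejected sets are logged with their DB/PB so sweep
statistics can report the censoring this induces.

NMF extraction uses 10 seeded random restarts keeping the best squared
error (the factorization is not unique, so the seed is recorded), with
the module count chosen as the smallest rank whose mean VAF
(1 - SSE/SST) over seeded restarts exceeds 0.95. Synergy vectors are
normalized to unit norm with the scale absorbed into the coefficients,
since the per-component scale split is otherwise arbitrary.

## Experiments and statistics

Sweeps train each admitted module set repeatedly and summarize
performance as the *median* final error (mean of the last 100 trial
errors) and median learning speed across repetitions. All sets in a
sweep share one block of repetition seeds (common random numbers), so
between-set comparisons are not diluted by initialization noise. The
statistics layer fits the univariate first-order regressions of error or
speed on one criterion (R^2, F-test p-value, slope) and the
two-criterion regression `X = k1 PB + k2 DB + k3` with the overall
F-test and `VIF = 1/(1 - R_cross^2)` from regressing one criterion on
the other. Context transplantation (modules extracted under one
biomechanical context and used in another) is emulated by rotating the
plant's torque columns and rescaling its passive torque; the rotation
angle is a config parameter and explicitly an emulation, since real
posture changes live in a full musculoskeletal model outside this
package's scope. Group-comparison hypothesis tests are delegated to
standard statistical routines; the package's own statistics are the
criteria, the regressions and the VIF.

## Problem sizes

Default experiment sizes mirror the full study design (90 / 30 sets, 30
repetitions, 25,000 trials). The test suite and the acceptance script
run a scaled design chosen as a package default: 30 direction-varying
and 15 gain-varying sets, 10 repetitions, 10,000 trials, 5 baseline
repetitions at 25,000 trials. At this scale the sign structure — speed
falling with DB, error rising with PB, VIF ~ 1 — reproduces reliably,
though with wider p-value variation across experiment-level seeds than
the full design would give; the effect sizes on the synthetic plant are
also genuinely smaller than on a real musculoskeletal model, whose
anisotropic torque geometry spreads the criteria over a wider range.

## Known limitations

- The plant is statistical, not anatomical; absolute DB/PB values are
  not comparable to values computed on a specific musculoskeletal model.
- The exponential learning-speed fit is a summary of a noisy,
  non-exponential process; per-repetition estimates are noisy and only
  medians across repetitions are interpreted.
- Learning-rate and initialization scales interact with plant scale;
  the defaults are calibrated for ~1 Nm torque columns and should be
  re-derived (see the stability bound above) for plants at other scales.
- The geometry is strictly planar; neither the criteria nor the
  generators extend to 3+ joint torque spaces, and passive torques at or
  above the target radius are rejected rather than extrapolated.
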