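# Methods

## Model family

`latentchange` implements the dual latent change score (LCS) model family
for equally spaced repeated measures. The observed score of individual *i*
at occasion *t* is a latent level plus Gaussian measurement error,

    Y_i[t] = y_i[t] + e_i[t],        e_i[t] ~ N(0, theta),

and the latent level is the initial level plus the accumulated changes,
each change being

    dy_i[t] = y_a,i + beta * y_i[t-1]                     (univariate)

    dx_i[t] = x_a,i + beta_x x_i[t-1] + gamma_x y_i[t-1]  (bivariate,
    dy_i[t] = y_a,i + beta_y y_i[t-1] + gamma_y x_i[t-1]   + d_i[t] if
                                                            stochastic)

The loading of the additive component on each change is fixed at 1.
Between-person heterogeneity enters through the joint normal distribution
of initial levels and additive components, with mean `(mu0, mua)` and
covariance `phi`. Stochastic variants add innovations `d ~ N(0, psi)` to
every change; unlike measurement error, an innovation's effect persists —
it is carried into all later levels through the dynamics.

Assumptions baked into the family: all parameters are time-invariant;
occasions are equally spaced with spacing `time_lag`; effects,
innovations and errors are Gaussian and mutually independent; one
indicator per process. Time-varying parameters, unequal spacing,
multiple-indicator measurement structures, higher-order (acceleration)
change equations, and change-to-change or 2-lag couplings are out of
scope.

## Parameter accounting

Free parameters are the means (2p), the distinct entries of `phi`
(p=1: 3; p=2: 10), the self-feedbacks (p), the free couplings (0–2), the
distinct entries of `theta` (p plus, bivariate with the
`error_covariance` flag, one within-occasion error covariance), and, for
stochastic models, the distinct entries of `psi`. This makes the
univariate deterministic dual model a 7-parameter model and the full
stochastic bivariate model a 24-parameter model (4 + 10 + 4 + 3 + 3).
The decomposition of the 24 is a design choice of this package: it
requires the within-occasion measurement-error covariance to be free,
which is why that choice is exposed as an explicit `ModelSpec` flag
rather than hard-wired.

## Discrete and continuous time

The deterministic mean dynamics are the linear-affine system
`y[t] = (I + A) y[t-1] + mu_a` in discrete time and `dy/dt = a + b y` in
continuous time. Conversion uses the matrix exponential:
`A_dt = expm(b * lag) - I` and `a_dt = (∫_0^lag expm(b s) ds) a`, with the
integral evaluated through the augmented matrix `expm([[b, I], [0, 0]]
lag)` so that singular drift (including `b = 0`, where `a_dt = a * lag`)
needs no special-casing. The inverse direction takes the principal matrix
logarithm of `I + A_dt` and fails, by design, when that matrix has an
eigenvalue on the closed negative real axis (e.g. `beta_dt = -1`): such
discrete dynamics have no real continuous-time equivalent. Univariate,
the continuous-time solution is the exponential curve
`y(t) = y_As - (y_As - y(t0)) exp(-r t)` with rate `r = -b` and asymptote
`y_As = a / r`; the package's conversion reproduces this closed form at
integer multiples of the lag to 1e-10, and round trips
(dt→ct→dt) are exact to the same tolerance.

## Shape classification

Univariate: `|beta| <= tol` is the linear regime (slope `mu_a`, constant
if `|mu_a| <= tol`); otherwise the asymptote `mu_a / (-beta)` is compared
with the initial-level mean — decelerated (beta < 0) versus accelerated
(beta > 0), growth versus decline by whether the asymptote lies above or
below the start, and constant if the trajectory starts within `tol` of
its asymptote. Note the direction of change is *not* the sign of the
additive component.

Bivariate: classification reads the eigenvalues of `M = I + A`. A complex
pair means the mean trajectories oscillate — damped if the modulus is
below `1 - tol`, explosive above `1 + tol`, sustained in between. Real
eigenvalues give non-oscillatory dynamics, convergent iff the spectral
radius is below 1. Defining oscillation through complex eigenvalues is a
design choice (the qualitative taxonomy this formalizes is usually
presented visually); it has the consequence that one of the six canonical
coupled regimes shipped in the scenario registry (`table1_C`) is formally
a damped oscillation with modulus sqrt(0.69) ≈ 0.83 and a period of ~23
occasions — over a short panel it is indistinguishable from decelerated
change, which is exactly why eigenvalues, not visual impressions, are the
operative criterion here. Similarly `table1_B` is divergent (real
eigenvalues 0.7 and 1.3) even though its x-process alone would decelerate.
The default `tol` is 1e-8 and every classifier accepts it as an argument.

The univariate identity `y_As = y_a / (-beta)` does not carry over to
coupled systems; the equilibrium is the solution of `A y* + mu_a = 0`
(rejected when `A` is singular, since then no isolated equilibrium
exists).

## Implied moments and likelihood

Stacking occasions, the latent levels are linear in the individual
effects: `levels = L (y0, ya)` with occasion-t block `[M^t, S_t]`,
`S_t = sum_{k<t} M^k`. Hence

    mean = L (mu0, mua)
    cov  = L phi L' + Q + R

with `R = I_T ⊗ theta` and innovation accumulation
`Q[t,s] = sum_{k=1}^{min(t,s)} M^{t-k} psi (M^{s-k})'` (zero when
deterministic). The geometric sums are built by recurrence rather than
through `(M^t - I) A^{-1}`, so `beta = 0` and singular `A` need no limit
handling.

Likelihood evaluation is casewise Gaussian ("full-information"): each
row's observed subvector is scored against the matching subvector/
submatrix of the implied moments, which marginalizes missing entries
without imputation. Rows are grouped by missingness pattern; within a
pattern the deviance is computed from sufficient statistics (pattern
mean and scatter), so the objective cost is independent of N after a
single pass over the data. All-missing rows are dropped with a warning.
Covariance solves use Cholesky factorization with the log-determinant
taken from the factor; a 1e-10 jitter is added only if factorization
fails, and logged.

A second, fully independent route computes the same -2 log-likelihood by
Kalman filtering the state `(levels, additive components)` with
transition `[[M, I], [0, I]]`, process noise `psi` on the level block,
observation noise `theta`, and initial moments `((mu0, mua), phi)`. The
two routes agree to 1e-6 on every tested panel, with and without missing
entries; the filter also provides O(T) scaling if long panels are ever
needed.

## Estimation

The optimizer works in an unconstrained coordinate system: means and
dynamic parameters map through the identity; every covariance block maps
through its Cholesky factor with log-transformed diagonal, so any
coordinate vector corresponds to a valid (positive semi-definite up to
floor) parameter set and no explicit constraints are needed. Couplings
declared fixed are pinned at zero. Log-diagonal coordinates are bounded
to ±12 during optimization (variances between ~4e-11 and ~3e10) purely to
keep boundary cases (true zero variances) from drifting.

The internal objective is the per-row deviance (-2LL / N), which keeps
gradient magnitudes comparable across sample sizes. Starting values are
moment-based: first-occasion means and variances, the self-feedback from
the median ratio of successive mean changes, an even split of the
first-occasion variance between level variance and error variance.
Additional starts jitter these coordinates (spread 0.2 by default, 5
starts; the recovery studies use 2). Each L-BFGS-B run is restarted once
from its own solution, which resets the limited-memory Hessian and
reliably tightens the gradient. Convergence is declared when the
optimizer reports success and the infinity-norm of the central-difference
gradient of the per-row deviance is below 1e-5. Explosive dynamics are
not excluded (no bounds on beta or gamma).

Standard errors: the observed information is half the numeric Hessian of
-2LL at the optimum; its inverse, carried through the Jacobian of the
natural-parameter map (delta method), gives natural-scale SEs. A
non-positive-definite Hessian is flagged and SEs are withheld. AIC and
BIC are `-2LL + 2k` and `-2LL + k ln N` with k the free-parameter count.

`recovery_study` runs seeded simulate-and-refit replications and reports
per-parameter bias, RMSE, the Monte-Carlo SE of the mean estimate,
coverage of ±1.96 SE intervals, and the convergence rate.

## Synthetic data

The generator draws individual effects from `N((mu0, mua), phi)`, unfolds
the change recursion exactly (innovations drawn i.i.d. `N(0, psi)` per
change when stochastic), and adds occasion-wise `N(0, theta)` error. One
master seed spawns three independent substreams (effects, innovations,
errors), so switching the error model does not perturb the latent draws,
and identical inputs give bit-identical panels.

What it emulates: Gaussian random effects, persistent latent shocks
versus transient measurement error, the variance fan-in/fan-out that the
self-feedback sign produces. What it does not: non-Gaussian or skewed
populations, informative dropout or any missingness mechanism (masks must
be supplied by the user), time-varying dynamics, measurement
non-invariance. Passing tests therefore certify the estimator under the
model's own assumptions, not robustness to their violation.

The scenario registry (`fixture(name, n, seed)`) reproduces the
illustrative configurations used across the documentation: the four
exponential curves (rates 4 and -0.4, initial levels 0 and 10, shared
asymptote 5, stored as their lag-1 discrete equivalents), the
self-feedback ladders (-0.2/-0.5/-1 for decelerated growth toward 5;
0.2/0.5/1 for accelerated decline away from 15), the variance scenarios
(initial-level variance 10 with additive-component variance 0 or 12),
and the six bivariate regimes A–F. Where a scenario's source prints only
some values, the registry fills the rest with documented defaults
(initial-level variance 1, additive variance 0.1, error variance 0.5,
bivariate means mu0 = (0, 0), mua = (1, 1)) chosen to produce curves of
the intended shape; they are constants in `simulate.py`, not tuned
quantities.

## Numerical choices and tolerances

- PSD checks tolerate eigenvalues down to -1e-10; classification
  boundaries use tol = 1e-8; dt↔ct round trips are tested at 1e-10; the
  two likelihood routes at 1e-6.
- Monte-Carlo oracle tests compare analytic and sample moments on the
  z-scale at the 3-SE significance level with a Bonferroni family-wise
  correction for the number of simultaneous comparisons — a raw
  elementwise 3-SE rule over ~44 moments rejects a correct implementation
  for roughly a third of seeds, while genuine moment defects give |z| two
  orders of magnitude beyond either threshold.
- Problem sizes: oracle moment checks use 200,000 simulated individuals;
  the recovery studies use 50 replications at N = 500 (deterministic
  univariate, T = 5) and N = 1000 (stochastic univariate), sizes at which
  every parameter's bias is within Monte-Carlo noise and convergence is
  essentially certain.

## Known limitations

- T = 3 panels fit but are weakly identified for dual-change dynamics;
  the package warns rather than refuses.
- The FIML route cannot handle a singular implied covariance (e.g. all
  variances zero); estimation keeps variances positive by
  parameterization, but evaluating the likelihood exactly at a boundary
  parameter set fails by design.
- Standard errors assume an interior optimum; at boundary solutions
  (zero variance estimates) the Hessian check will typically withhold
  them.
- No support for irregular spacing or individually varying observation
  times; continuous-time estimation from such data is a different
  problem.
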