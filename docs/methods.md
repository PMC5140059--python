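# Methods

`reactionet` learns the topology and rate constants of stochastic mass-action
reaction networks from single-cell *snapshot* time series: population samples
at discrete times in which each cell is measured once and destroyed, so no
per-cell trajectories exist. This note records the model, the estimators, the
numerical choices, and what the synthetic benchmarks do and do not
demonstrate.

## Model

A network of N species evolves under the chemical master equation with L
mass-action reactions, each with stoichiometry vector `s_l` and propensity
`a_l(x) = k_l g_l(x)` where `g_l` is `x_a` (unary), `x_a x_b` (distinct
reactants) or `x_a (x_a - 1)` (homodimer; the conventional 1/2 is absorbed
into `k_l`). Taking expectations yields ordinary differential equations for
the means and central moments that are **linear in the rate constants**:

    dM_r/dt = sum_l k_l F_rl(M)

with stoichiometric moment functions

    F_{mu_i, l} = s_li E[g_l]
    F_{C_ij, l} = s_li Cov(X_j, g_l) + s_lj Cov(X_i, g_l) + s_li s_lj E[g_l]

expanded about the mean (e.g. `E[X_a X_b] = mu_a mu_b + C_ab`). Bimolecular
propensities introduce third central moments, but only as *inputs* estimated
from the data: regression targets stop at order two, so no moment-closure
approximation is ever made.

Gradient matching replaces ODE integration: moment time-derivatives are
estimated directly from the interpolated snapshot moments, turning parameter
inference into the linear model `b_hat = A_hat k + eps` with
`eps = eps_A k - eps_b` — noise enters the response *and* the design matrix,
and its variance depends on the unknown `k`. The estimator is therefore
stepwise:

* **Step 1 — feasible generalized least squares.** A pilot nonnegative
  least-squares (NNLS) fit on the first-order (mean) rows gives `k_LS`;
  per-row residual variances `sigma_j^2 = sd_b_j^2 + sum_l k_LS_l^2
  sd_A_jl^2` (independence of the two noise sources assumed; the SDs come
  from a bootstrap of the full estimator pipeline) whiten the system; NNLS on
  the whitened system gives `k_FG`, whose support Phi (relative threshold
  `1e-6` of the largest coefficient) prunes the library, typically by an
  order of magnitude.
* **Step 2 — adaptive relaxed lasso.** On the whitened system restricted to
  Phi, `min_{k>=0} ||b_S - A_S,Phi k||^2 + lambda sum_i |k_i/ktilde_i|` is
  solved by ADMM over 50 log-spaced penalties from the analytic all-zero
  bound down to `1e-6` of it. The adaptive weights `ktilde` are the
  magnitudes of the Moore-Penrose pseudoinverse solution on Phi (floored at
  `1e-12`); the literature describes the pilot estimate ambiguously, so the
  plain `k_FG` weights are available as a configuration switch. Each active
  set is refit without penalty (relaxed lasso). Five-fold cross-validation,
  stratified by moment block, records held-out error and per-reaction
  selection frequencies (stability selection; default threshold 0.8).
  BIC = `n ln(RSS/n) + s ln n` on the full-data relaxed refits picks the
  penalty, followed by backward stepwise elimination that drops reactions
  while the criterion does not increase. Prior-knowledge reactions are never
  penalised, never dropped, and are held at `k >= 1e-12` in every fit.

## Candidate library

Unconstrained enumeration over N species generates three canonical forms —
conversions A→B (one per unordered pair, low-to-high index), splits A→B+C and
associations A+B→C (species pairwise distinct) — giving
`C(N,2) + N·C(N-1,2) + C(N,2)·(N-2)` candidates: 30 for N=4, 2275 for N=14.
Synthesis and degradation reactions are not enumerated but are accepted in
explicit network specifications. Module-constrained enumeration applies the
same forms within each module and appends an explicit cross-module list.
Conversions are scored direction-free when comparing against ground truth,
since only one direction exists in the library.

## Synthetic data

Each cell is an independent Gillespie (direct-method) simulation; per-cell
RNG streams are derived from the master seed and the cell index, so results
are bit-reproducible and enlarging the ensemble never reshuffles earlier
cells. Measurement noise is binomial thinning `X_obs ~ Bi(X, p)` with known
capture efficiency p, the standard model for incomplete molecular capture in
cytometry and single-cell sequencing.

Noise correction inverts the thinning exactly through falling-factorial
moments, `E[(X_obs)_(r)] = p^r E[(X)_(r)]` (componentwise for mixed indices,
using the conditional independence of thinning across species): observed
central moments → raw → factorial, divide by `p^|r|`, and convert back. For
orders one and two this reduces to `E[X] = E[X_obs]/p`,
`Var X = (Var X_obs - p(1-p)E[X])/p^2`, `Cov = Cov_obs/p^2`. Corrected
variances can come out negative at low p and finite samples; they are clipped
to zero with a logged warning. The `1/p^3` amplification makes corrected
third moments noisy — consistent, but with large bootstrap SDs, which the
whitening step then uses to downweight the affected rows.

### The enzymatic benchmark fixture

E + S → ES (k=0.002), ES → E + S (k=0.1), ES → E + P (k=0.1), with
E(0)=100, S(0)=200, ES(0)=P(0)=0 and time in arbitrary units. Km = 100, so
the system is half-saturated at the initial substrate level. The default
snapshot design is 13 uniform time points on [5, 50]:

* the horizon 50 gives ≈95% substrate conversion;
* the window starts at t=5, about four relaxation times of the fast binding
  mode (`tau = 1/(k_on (E0+S0) + k_off + k_cat) ≈ 1.25`). Starting from
  ES(0)=0 the complex concentration has a boundary layer whose gradient no
  13-point uniform interpolant can represent: on the deterministic mean
  equations the maximum relative spline-derivative error exceeds 30% at t=0
  for every rate set we scanned, and drops below a few percent on the slow
  manifold. Placing the measurement window after the fast transient mirrors
  how snapshot time points are chosen in practice — from preliminary dense
  population measurements that record where the resolvable dynamics are.

What the fixture does *not* emulate: extrinsic cell-to-cell parameter
variability, cell division and lineage effects, non-mass-action kinetics,
and instrument background beyond binomial capture. Passing benchmarks on it
demonstrates the estimator chain is consistent and well calibrated for
intrinsic stochasticity — not robustness to those unmodelled effects.

## Gradient estimation

* `spline` — derivative of the cubic interpolating spline with **not-a-knot**
  end conditions. A natural spline (zero second derivative at the ends)
  systematically biases boundary derivatives of decaying moment curves; on
  the enzymatic benchmark that bias was large enough to induce two to three
  spurious compensatory reactions, while not-a-knot recovers the exact truth
  in five out of five seeds.
* `fds` — nonuniform central differences, one-sided at the ends. Checked to
  be consistently worse than the spline on smooth decay curves.
* `smooth` — sliding-window (default 5-point) moving-average smoothing of
  densely sampled ensemble moments followed by finite differences; an oracle
  available only in simulation, used for validating the moment equations and
  benchmarking the practical estimators.

Bootstrap variability (default B=200) resamples cells with replacement per
time point and re-runs the full pipeline (moments → noise correction →
gradients → design entries) per replicate. For the `smooth` oracle the
resampling is expressed through multinomial weights so each replicate's dense
ensemble moments are a single matrix product.

## Numerical choices

* NNLS with strictly positive lower bounds (prior knowledge) is solved by
  variable shifting around `scipy`'s active-set NNLS, preserving exact zeros.
* ADMM: penalty parameter rho=1 with adaptive factor-2 rescaling when the
  primal/dual residual ratio exceeds 10; absolute tolerance 1e-8, relative
  1e-6, at most 10^4 iterations; non-convergence is flagged per penalty and
  the result retained. Iterations run on unit-norm design columns (an exact
  rescaling of variables, mapped back afterwards) — without this the raw
  moment-scale columns make the iteration hopelessly slow.
* RSS is floored at 1e-12 inside information criteria so exactly consistent
  systems remain comparable; BIC ties (identical active sets refit along a
  zero-residual plateau) break toward the smallest penalty, where the
  cross-validated selection frequencies have stabilised.
* For libraries above 1000 candidates the BIC minimiser is replaced by the
  elbow rule: the sparsest model within 1% of the total criterion drop.
* Mean-trajectory reconstruction integrates the first-order (deterministic)
  mean equations of the recovered network with LSODA; this closure drops the
  covariance term of bimolecular propensities and is reported as an
  approximation.

## Problem sizes

The test-suite benchmarks run the full pipeline on the enzymatic fixture with
10^2–10^4 cells, 13 time points, bootstrap B=200 and 50-point penalty grids —
a deliberate scale-down (in cell count and system size, not in procedure) of
the original benchmark design, chosen so the complete suite runs on a laptop
in minutes. Larger systems (the 14-species receptor subunit at 10^5 cells,
module-constrained 58-species cascades) use the identical code path via the
CLI; only wall-clock time grows.

## Known limitations

* Rate constants are identified only over the observed dynamic range;
  reactions whose propensities are nearly collinear over the window (e.g.
  ES→E+S vs ES→E+P before product feedback separates them) trade off against
  each other at low cell counts.
* The residual-variance model assumes independent noise in response and
  design; both derive from the same cells, so the whitening is approximate.
* Gradient bias (as opposed to variance) is invisible to the bootstrap; time
  points must be placed where interpolation is adequate, as discussed above.
* Capture efficiency p is assumed known; misspecified p biases corrected
  moments systematically.
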