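# reactionet

Structure learning of stochastic mass-action chemical reaction networks from
single-cell **snapshot** time series.

Single-cell instruments (flow/mass cytometry, single-cell sequencing) measure
each cell once, destructively: the data are population samples at discrete
times, not trajectories. `reactionet` recovers which reactions — out of every
conceivable unary/binary reaction between the measured species — actually
drive the observed dynamics, together with their rate constants, by a
stepwise sparse regression built on the chemical master equation.

## Method in brief

For mass-action kinetics the central moments `M_r` (means, variances,
covariances) of the species copy numbers obey ODEs **linear in the rate
constants**:

    dM_r/dt = Σ_l k_l F_rl(M)

where each stoichiometric moment function `F_rl` is a polynomial in moments
estimable from the snapshots. Estimating the left side by gradient matching
(spline/finite-difference derivatives of the empirical moment curves) and the
right side from empirical moments turns structure learning into a sparse
nonnegative regression over an enumerated candidate library (2275 candidates
for 14 species — over 10^600 implicit topologies):

1. **Feasible generalized least squares.** Bootstrap the whole estimator
   pipeline to get per-entry variabilities of response and design; whiten;
   nonnegative least squares prunes the library to a small support.
2. **Adaptive relaxed lasso.** ADMM solves the weighted nonnegative-ℓ1
   problem along a penalty path; active sets are refit unpenalised;
   five-fold cross-validation yields stability-selection frequencies; BIC
   plus backward stepwise elimination select the final reaction set. Prior
   knowledge enters as positivity constraints that are never penalised.

Binomial measurement noise `X_obs ~ Bi(X, p)` with known capture efficiency
`p` is inverted exactly (falling-factorial moments) before any fitting.

See `docs/methods.md` for the full model, estimator and numerical details.

## Worked example

```python
import numpy as np
import reactionet as rn
from reactionet.network import ENZYMATIC_T_START, ENZYMATIC_T_END, ENZYMATIC_X0

network = rn.fixture_network("enzymatic")          # E+S <-> ES -> E+P
library = rn.enumerate_candidates(network.species) # all 30 unary/binary candidates
t_grid = np.linspace(ENZYMATIC_T_START, ENZYMATIC_T_END, 13)
snapshots = rn.ssa_simulate(network, ENZYMATIC_X0, t_grid, 10_000, seed=0)
result = rn.infer_network(snapshots, library, gradient_method="spline", seed=0)

print(f"step-1 support: {len(result.fg.support)} candidates")
for rx, k in zip(result.selected_reactions, result.selection.k_hat):
    print(f"  {rx.label(network.species):<14s} k_hat = {k:.4f}")
c = rn.confusion(result.selected_reactions, network.reactions)
print(f"tp={c.tp} fp={c.fp} fn={c.fn}")
```

Output:

```
step-1 support: 10 candidates
  ES -> E + S    k_hat = 0.0937
  ES -> E + P    k_hat = 0.0999
  E + S -> ES    k_hat = 0.0019
tp=3 fp=0 fn=0
```

From 10^4 simulated cells at 13 time points, the whitening step cuts the
30-candidate library to 10, and the lasso step returns exactly the three
planted reactions; the recovered rate constants sit within a few percent of
the planted values (0.1, 0.1, 0.002).

## Command line

```sh
reactionet simulate config.yaml            # SSA snapshot tables from a network spec
reactionet infer config.yaml snaps.csv     # run the two-step regression
reactionet evaluate final_model.csv truth.yaml
reactionet pipeline config.yaml            # simulate + infer + score
```

Configs are YAML (`RunConfig` fields); network specs are YAML blocks of
`species`, `reactions`, optional `modules`/`cross_module_reactions`, and
`x0`. Every run writes a `run_metadata.json` from which it can be reproduced
exactly.

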