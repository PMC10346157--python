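# Methods

`fermsense` implements a transfer-learning soft sensor for batch fermentation:
an LS-SVM regressor predicts hard-to-measure quality variables (cell
concentration C, product concentration P, g/L) from six online auxiliary
channels, its two hyperparameters are selected by an emotional particle swarm
optimizer, and a fuzzy balanced distribution adaptation step aligns a
labelled historical batch (source domain) with an unlabelled new batch run
under different operating conditions (target domain).  This note documents
the models, the defaults and why, the numerical choices, and what the
bundled simulator does and does not show.

## LS-SVM regression

Given `{(x_i, y_i)}`, the LS-SVM minimizes `||w||^2/2 + (gamma/2) sum e_i^2`
subject to `y_i = w^T phi(x_i) + b + e_i`.  The KKT conditions reduce
training to one symmetric linear system

```
[[0, 1^T], [1, K + I/gamma]] [b; alpha] = [0; y],
```

with the RBF Gram matrix `K_ij = exp(-||x_i - x_j||^2 / (2 sigma^2))`, and
prediction is `f(x) = sum_i alpha_i K(x, x_i) + b`.

* `gamma > 0` trades fit against smoothness (`gamma -> inf` interpolates);
  `sigma > 0` is the kernel width on normalized features.  The un-tuned
  baseline uses `gamma = 125`, `sigma = 10`.
* The saddle system is solved by a symmetric-indefinite LAPACK factorization
  (`sytrf`/`sytrs`).  When the reciprocal condition estimate (`sycon`) falls
  below 1e-12 the fit raises instead of silently pseudo-inverting, and every
  fit verifies its residual against `1e-8 * (1 + ||y||)`.

## Emotional particle swarm optimizer (IPSO)

A swarm minimizes an objective over a box.  Each particle carries an
emotional state `eX`, initialised uniformly in [-0.1, 0.1], that rises on
improvement and falls otherwise by

```
improved:  eX += (f_prev - f)(f - gb) / (gw - gb)^2
worsened:  eX -= (f - f_prev)(gw - f) / (gw - gb)^2
```

(`gb`/`gw`: global best/worst fitness; denominator guarded, eX clamped to
[-1, 1]).  Each iteration the swarm is partitioned around the mean emotion:
particles at or above the mean of the above-average emotions are *happy*,
those at or below the mean of the below-average ones are *sad*, the rest
*normal*.  A sorted-tertiles rule and an all-normal forcing (which makes the
optimizer bit-identical to the vanilla PSO baseline under the shared random
stream) are available as alternatives.

* Normal particles use the classical update with inertia `xi = 0.729` and
  acceleration weights `c1 = c2 = 1.494` (constriction-style defaults).
* Happy particles scale their cognitive and social terms by Weber-Fechner
  perception coefficients `r = -k ln(S/S0)`, `S` the absolute fitness gap to
  the global (cognitive term) or personal (social term) best, clamped to
  [0.1, 2.0] so velocities stay bounded.  The stimulus threshold `S0` is
  recomputed each iteration as the swarm's median gap to the global best:
  placing the unit stimulus at the typical gap centres the coefficients
  around 1, so perception modulates rather than suppresses the update (a
  fixed small fraction of the best-worst spread pegs every coefficient at
  the lower clamp and freezes the best particles).
* Sad particles restart: velocity uniform in `+-0.35 (u - l)` per dimension
  (the 0.35 amplitude is a separate constant from the velocity-update
  weights), and the position jumps to the previous global best with
  probability 1/2 or is re-initialized uniformly over the box.  The printed
  form of the random branch (`l + (u-l) * rand[-1, 1]`) would pile half of
  the clamped restarts onto the lower boundary; it is read here as uniform
  re-initialization, which is what "random initialization" describes.
  Restarted particles keep their personal-best memory.
* Positions are clamped to the box after every update.  A non-finite
  objective value mid-run triggers one re-sample of the particle (logged);
  at initialization it is an error naming the point.
* Termination: a fixed iteration cap (default 200) or an optional fitness
  threshold.  All randomness derives from one seed, split into independent
  substreams for positions, emotions and step noise so the PSO baseline
  consumes identical position/step streams.

The emotion formulas give near-zero rewards to particles close to the global
best (the `(f - gb)` factor) while penalizing any worsening by the large
`(gw - f)` factor, so the swarm's best performers tend to drift sad and be
restarted.  On smooth low-dimensional landscapes such as the hyperparameter
search below this is harmless and the restarts help escape plateaus; on
fine-grained multimodal benchmarks (e.g. Rastrigin in five dimensions) the
disruption of local refinement makes IPSO trail a well-parameterized
constriction PSO.  This limitation is inherent to the update rules, not to
their implementation, and is visible in the benchmark suite.

## Fuzzy balanced distribution adaptation (BDA)

BDA seeks a linear map `A` minimizing a weighted sum of marginal and
conditional maximum mean discrepancy between source and target,

```
min_A  tr(A^T X [(1-mu) M0 + mu MR] X^T A) + lam ||A||_F^2
s.t.   A^T X H X^T A = I,
```

where `X` stacks both domains (features in rows), `H` is the centering
matrix `I - (1/(n+m)) 11^T`, `M0` the marginal MMD matrix (`1/n^2`, `1/m^2`,
`-1/(nm)` blocks) and `MR = M1 + M2 + M3` the conditional one.  Because
regression has no classes, each label vector is softened into three fuzzy
sets — *small*, *medium*, *large* — anchored at its 5th/50th/95th
percentiles (small: 1 below p5, linear to 0 at p50; medium: triangular
p5-p50-p95; large: mirror of small).  Column-normalized memberships replace
the crisp class indicators in `MR`; with 0/1 memberships the classic
per-class matrices are recovered exactly.  Target-side sets are fitted on
soft labels predicted by the current regressor and refined by alternating
solve / re-predict rounds (default 10, early-stopped when soft labels move
by < 1e-4 in relative norm).

The stationarity condition yields the generalized eigenproblem
`(X M X^T + lam I) A = X H X^T A Phi`; `A` collects the eigenvectors with
smallest eigenvalues.  Defaults: balance factor `mu = 0.62`, ridge
`lam = 0.1`.

**Subspace dimension.**  By default the number of retained eigenvectors is
chosen by a spectral cut: trailing generalized eigenvalues larger than 10x
the median are dropped.  A large eigenvalue means the direction's objective
value is dominated by the ridge penalty `lam ||a||^2`, i.e. it is a
near-null-variance direction of the pooled data amplified by `1/sqrt(beta)`
under the unit-variance constraint; keeping such directions hands amplified
sensor noise to the downstream isotropic RBF kernel.  An explicit `dims`
overrides the cut.  Even with the cut the constraint whitens the retained
directions, so the adapted representation is not metric-equivalent to the
original one; on shift-free data this costs a few percent of RMSE relative
to skipping adaptation — the price of the method's scale normalization, not
removable by re-tuning `(gamma, sigma)`.

Numerical notes: the constraint matrix `X H X^T` must be positive definite
(guaranteed once no pooled feature is constant after centering); eigenvector
residuals are verified against 1e-6.  A degenerate label vector (all equal)
falls back to all-medium membership with a warning.  The printed form of the
centering matrix in the source description ("identity minus identity over
n") degenerates the constraint and is read as the standard centering matrix.

## Synthetic fermentation generator

The generator stands in for proprietary plant data and defines the study
conditions.  One batch is 90 h sampled every 0.5 h (180 rows).  States
follow Monod growth with a Luedeking-Piret product law:

```
dX/dt = mu_max f(T, pH) S/(Ks + S) X,   dS/dt = -(1/Yxs) dX/dt,
dP/dt = alpha_LP dX/dt + beta_LP X,
```

integrated by fixed-step RK4 (0.05 h internal step, substrate floored at
zero; mass balance `Yxs (S0 - S) = X - X0` holds to < 1e-6 g/L).
`f(T, pH)` is a product of quadratic penalties peaking at 28 degC and
pH 5.0.  Defaults: `mu_max = 0.18 1/h`, `Ks = 0.5 g/L`, `Yxs = 0.5 g/g`,
`alpha_LP = 0.12 g/g`, `beta_LP = 0.004 g/(g h)`, `S0 = 40 g/L`,
`X0 = 0.2 g/L` — a 90 h cycle that exhausts substrate around 40 h and ends
near 20 g/L biomass and 8 g/L product.

Auxiliary channels: oxygen demand `D = dX/dt + 0.05 X` drives a saturating
controller signal `u = D/(D+1)`; stirring ramps 350->450 rpm and airflow
225->375 L/min with `u`; dissolved oxygen falls with demand and recovers
with agitation/airflow (clamped to [0, 100] %); temperature and pH hold
their setpoints (28 degC, 5.0); headspace pressure follows a mild scheduled
ramp 0.035->0.045 MPa plus a demand term.  Per-channel Gaussian measurement
noise (sd: 3 rpm, 0.1 degC, 2 L/min, 0.02 pH, 1 %, 0.001 MPa) is seeded per
batch; batches within a domain also jitter inoculum (+-10 %) and initial
substrate (+-5 %).

A transfer scenario pairs source batches at these defaults with target
batches at shifted conditions — by default +3 degC setpoint, `mu_max x0.85`
and `Yxs x0.9` — producing both marginal shift (the temperature channel
moves far outside the source range once min-max scaled) and conditional
shift (the auxiliary-to-quality map changes).  Target labels are returned
separately and never shown to the pipeline.

What the generator does *not* emulate: fed-batch feeding and induction
phases, controller dynamics with lag and overshoot, sensor drift and
outliers, and cross-channel noise correlation.  Passing tests therefore
demonstrate the machinery's correctness and the direction of the transfer
benefit under controlled shift, not performance on plant data.

## Pipeline

For one quality variable: (1) min-max normalize features and label on the
source only (zero-range columns map to 0.5; no clipping on transform);
(2) select `(gamma, sigma)` by swarm search over 5-fold cross-validated
RMSE — folds are contiguous blocks because the rows are autocorrelated time
series, the box is `gamma in (0, 300]`, `sigma in (0, 50]`, and the first
particle starts at `gamma = 100`; (3) fit on the source; (4) predict soft
labels for the target; (5) run the fuzzy BDA refinement; (6) re-run the
tuner on the transformed source (the matched domains pass through the full
model, including hyperparameter selection, since the whitened scale
invalidates the original `sigma`) and predict the transformed target.
Predictions are mapped back to g/L before metrics.  C and P are modelled
independently (the regressor is scalar-valued).  Four variants are compared:
fixed-parameter LS-SVM, PSO-tuned, IPSO-tuned, and the full adapted model;
metrics are RMSE, R^2 (undefined for constant truth — reported as missing)
and MAE, aggregated as medians over optimizer seeds.

## Problem sizes

Library defaults follow the reference configuration (swarm 100, 200
iterations).  The test suite, the bundled comparisons and the acceptance
script run the tuner with a swarm of 12 for 12 iterations, 2 source batches
and 1 target batch, and 5-10 optimizer seeds — sizes chosen so the full
suite completes on a single CPU while leaving the orderings of interest
stable across seeds.

## Known limitations

* The emotional swarm trails constriction PSO on fine-grained multimodal
  objectives (see the optimizer section).
* Adaptation is not free under zero shift: the whitening constraint changes
  the feature metric by a few percent RMSE even with the spectral cut.
* One source and one target domain only; multi-source transfer and joint
  multi-output modelling are out of scope.
* The kernelized BDA variant is not implemented; the transformation acts on
  the input features directly.
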