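# Methods

`bleachnum` estimates absolute numbers of fluorescent molecules per cell
from the stochastic fluctuations of deliberately photobleached,
GFP-tagged proteins imaged on a wide-field microscope.  This note
records the models, the numerical choices, and what the synthetic-data
validation does and does not establish.

## The physical picture

Bleaching of a single fluorophore under sustained excitation is
first-order: a molecule survives to time t with probability
l = exp(-λt).  Starting from x0 independent molecules the surviving
count X_t is binomial, so

    E[X_t]   = x0 l,
    Var[X_t] = x0 l (1 - l).

Fluorescence is Y = ν X with ν the brightness of one molecule in camera
units.  The fluctuations therefore carry the absolute scale: for a fixed
mean fluorescence, large fluctuations mean few, bright molecules and
small fluctuations many dim ones.  Normalised fluctuations
Var[X_t / x0] scale as 1/x0.

## The fluctuation estimator

Eliminating l between the two moments gives, for any t > 0,

    x̂0 = E[Y_t] (y0 - E[Y_t]) / Var[Y_t],

an identity in x0 when the moments are exact, and (with negligible
measurement noise) the maximum-likelihood estimate of x0 given
(y0, E[Y_t], Var[Y_t]).  The package verifies the latter numerically by
marginalising an explicit likelihood whose model constraints are
represented as narrow Gaussians (`estimator.mle_x0`): the peak over x0
coincides with the closed form to below 1e-6 relative.

Per cell, E[Y_t] is estimated by Gaussian-process smoothing (below) and
Var[Y_t] by the squared residual (y_t - E[Y_t])².  Each cell with n_d
frames yields n_d - 1 pair estimates (one per positive time point); all
cells' estimates are pooled and the mode of a Gaussian kernel density
over log10 x̂0 (Silverman bandwidth, 512-point grid spanning the sample
range) is the point estimate.  Negative pair estimates — possible when
the smoothed mean at t exceeds y0 — are excluded from the density but
counted in the diagnostics.

**y0 convention.**  y0 is taken from the GP posterior mean at t = 0
rather than the raw first frame (config switch `y0_convention =
smoothed | raw`).  The raw frame carries its own measurement noise into
every single pair of the cell, correlating all of a cell's estimates
with one noise draw; the smoothed value does not.  Noiseless data make
the two conventions identical.

### Bias under heterogeneity and noise

If each molecule has its own brightness ν_i and survival l_i drawn from
a joint distribution, and measurement noise has variance σ_e², then

    x̂0 = x0 / (1 + ε),
    ε = (σ_e²/x0 + Cov[ν, νl] - Var[νl]) / (E[νl] (E[ν] - E[νl])).

Large measurement noise biases the estimate low; heterogeneity in νl
with little noise biases it high.  `predicted_bias` evaluates ε, and
`accuracy_margins` the small-bias conditions: both homogeneous-case
margins are widest midway through bleaching (E[l] = 1/2), and the
brightness-heterogeneity condition fails outright once
Var[ν] > E[ν]².  The validation suite confirms the law on a 3×3 grid of
noise × brightness-CV against ensembles of 10⁴ molecules: empirical
means match x0/(1+ε) within 3 standard errors and the sign of the bias
matches the sign of ε in every decidable cell.

### GP smoothing

The smoother is a zero-mean GP with squared-exponential kernel
k(t,t') = θ0 exp(-θ1 (t-t')²/2) plus i.i.d. observation noise θ2,
hyperparameters found by maximising the marginal likelihood inside hard
box bounds 1e3 < θ0 < 1e14, 1e-8 < θ1 < 1 (1/s²), 10 < θ2 < 1e10.
Traces are mean-centred before fitting and the offset restored.
Optimisation uses scikit-learn's GP regression with 5 restarts drawn
uniformly in the log of each bound interval; the posterior mean is then
evaluated in closed form at the observed times only (the variance rule
is defined only there).

θ2 sets the bias direction of the whole pipeline: forcing it low makes
the mean track fluctuations, shrinking the squared residuals and
inflating x̂0; forcing it very high over-smooths and deflates x̂0.  Both
directions are demonstrated on simulation in the test suite.  At
realistic noise the marginal-likelihood fit lands in between, and the
pooled mode stays within one order of magnitude of truth for
x0 from 1e3 to 1e6 (150 cells, 45 frames at 10 s) — overestimating by a
factor ~3-4 at the low end (smoothing bias and survival heterogeneity
dominate) and underestimating by a factor ~6 at 1e6, where the
quadratic term of the camera-noise variance dominates the bleaching
fluctuations.  That asymmetry is a property of the method at these
noise levels, not an implementation artefact.

## The Bayesian route

The explicit model gives each cell j two pools of molecules bleaching
at cell-specific rates λ1, λ2 from initial counts x0(1-α), x0α.  Under
the linear noise approximation the state is Gaussian with moment ODEs

    dμ_i/dt = -λ_i μ_i,
    dΣ_ii/dt = -2λ_i Σ_ii + λ_i μ_i,
    dΣ_12/dt = -(λ1+λ2) Σ_12,

solved in closed form over each frame interval.  A frame observes
y = ν(x1+x2) + f + noise, with f the residual autofluorescence and
noise variance either constant (σ_e0²) or quadratic in the signal,
σ_e0² + νx σ_e1² + (νx σ_e2)².  The quadratic case replaces the
state-dependent variance by its expectation under the one-step-ahead
prediction, after which the standard Kalman update applies; the log
likelihood is the sum of one-step predictive log densities from a
delta initial state (zero covariance, so the first predictive variance
is the noise variance alone — σ_e0 is kept away from zero by its
prior).  Negative filtered means are clipped to zero; Σ is not
adjusted.

**Shot-noise source term.**  The λμ source in the variance ODE is
driven by the data-independent LNA mean trajectory, not the filtered
mean.  With that choice the process noise is state-independent and the
filter is *exact* inference in one well-defined joint Gaussian model —
verified against a dense multivariate-normal evaluation of the whole
trace to 1e-6 (in practice ~1e-12).  Restarting the source term from
the filtered mean (the common alternative) makes the implied joint
density data-dependent and the two routes disagree at the 1e-2 level;
we prefer the internally consistent model.  The Σ update uses the
Joseph-stabilised form, algebraically equal to the textbook one.

### Priors and sampling

Parameters split into per-cell blocks (λ1, λ2, f, y0 ≡ νx0, α) and a
shared block (ν, σ_e0, σ_e1, σ_e2).  y0 is sampled instead of x0 so the
expected trace depends only on per-cell parameters, which decorrelates
the blocks.  Scale parameters carry proper 1/x priors (defaults:
y0 ∈ [1, 1e12], ν ∈ [1e-3, 1e3], σ_e0 ∈ [1e-2, 1e6], σ_e1 ∈ [1e-4, 1e3],
σ_e2 ∈ [1e-8, 10]); λ ∈ [1e-6, 1] 1/s, f ∈ [-1e4, 1e4] and α ∈ [0, 1]
are flat.  All bounds are configuration, not physics.

Sampling is Metropolis-within-Gibbs: per-cell blocks one cell at a time
(only that cell's likelihood is recomputed), then the shared block
against all cells.  λ1, λ2, f, α use Gaussian random walks; y0, ν and
the σ's log-normal random walks with the Hastings correction.  One
adaptive scale per block type follows a Robbins-Monro rule
(γ_t = 0.5/(1+t)^0.6) toward 0.234 acceptance and freezes at the end of
burn-in (default half the run), so post-burn-in draws target the exact
posterior.  Parallel tempering uses 10 chains by default tempering the
likelihood only (the hottest chain then samples the prior); adjacent
pairs propose swaps each sweep and the log temperature spacings adapt
toward a 0.234 swap rate by the same diminishing schedule.  Only the
unit-temperature chain is recorded.

Chains start from a nested optimisation: (1) bi-exponential
least-squares fits seed each cell's block; (2) a bounded global
optimiser (differential evolution, ~2000 evaluations/cell by default)
refines each cell with its own copy of the shared parameters; (3) the
shared block starts at the per-cell medians; (4) block-coordinate
ascent (Powell, log-transformed scale parameters) alternates shared and
per-cell optimisation, accepting only improvements; (5) half the chains
start at that optimum, half at optima reached from random prior draws.

### From samples to molecule numbers

A single fluorescence y maps to a posterior over x as the sample
mixture of N(x; (y-f)/ν, (σ_e0² + yσ_e1² + (yσ_e2)²)/ν²); negative x
is retained (the noise model permits it) and its mass reported.  For a
population mean over N cells the per-cell noise averages out and the
posterior is the mixture of ȳ/ν over the ν draws smoothed with a
log-normal kernel of log-sd σ_K = 0.1 — the kernel K(x,x') is read as a
normal in log x, the only interpretation consistent with positive
molecule numbers.  Replicates are combined post hoc: each replicate's
posterior becomes a log-normal KDE (same σ_K), the product is divided
by prior^(N-1), and a log-space random-walk Metropolis sampler (scale
tuned to 0.44 acceptance during burn-in, per-dimension step sizes from
the pooled spread) draws from the product.  Combining N identical sets
provably sharpens the posterior; disjoint replicate supports are
detected by kernel distance and flagged.

## The synthetic-data generator

Simulation is Markov-exact: over each interval every surviving molecule
survives independently with probability exp(-λΔt), so pool counts
follow exact binomial thinning — no stochastic-simulation algorithm and
no time-step error.  Fully heterogeneous ensembles draw one (ν_i, λ_i)
per molecule (optionally rank-correlated through a Gaussian copula) and
one exponential bleach time per molecule, at O(x0) cost.  Initial pool
counts round x0α to the nearest integer; reported ground truth is the
post-rounding total.  All randomness derives from a single seed through
numpy `SeedSequence` spawning.

Default study conditions: 45 frames at 10 s; brightness ν = 20 camera
units/molecule with noise scales σ_e0 = 136.6, σ_e1 = 1.31,
σ_e2 = 0.0027 (a realistic wide-field EMCCD operating point: the linear
term dominates the constant one, the quadratic term matters only for
the brightest cells); per-cell rates log-normal around 1e-3 and
8e-3 1/s (25% CV) — per-frame survivals ≈ 0.99 and 0.92 — with the pool
split α ~ Beta(8,8).  The generator emulates bi-exponential,
heterogeneous bleaching with mean-dependent Gaussian noise; it does not
emulate blinking or triplet photophysics, protein synthesis or
fluorophore maturation during bleaching (cells are fixed), cell-shape
or focus drift, or segmentation errors.  Passing the validation suite
therefore shows the *inference machinery* is correct and calibrated
under the stated model, not that real microscopes satisfy the model.

## Quality control and preprocessing

Corrections apply in the physical order: flat-field division,
background subtraction (negative values preserved — the noise model has
support there), then subtraction of the per-frame mean of bleached
wild-type cells.  Cell fluorescence is the sum of the brightest 80% of
in-mask pixels, with the pixel count rounded up (the rounding rule is
our choice).  A cell is rejected when any frame falls below its local
trend — a centred 5-frame rolling median, immune to single outlier
frames — by more than 5 robust standard deviations, standardised by a
local scale (rolling MAD of the residuals, floored by a
second-difference noise estimate) because the noise shrinks as the cell
bleaches; the first/last two frames are exempt, where a centred trend
is undefined.  The threshold implements a qualitative criterion
("large systematic deviations, such as a sudden drop") and is exposed
in configuration; it keeps ≥95% of clean simulated traces across
x0 = 1e3-1e6 while catching single-frame dropouts at any scale.

Bi-exponential fits f_i = a0 + a1 l1^i + a2 l2^i use bounded
least squares (0 < l ≤ 1), initialised from log-linear fits of the
first and last thirds of the trace with 3 random restarts; components
are reported slow-first (l1 ≥ l2) to break the swap symmetry, and
non-convergence is flagged on the result rather than raised.

## Problem sizes in the validation suite

The reproduction script (`scripts/acceptance.py`) uses: the full
99×3×2 identity grid; 1000 replicate ensembles of 10⁴ molecules per
bias-grid cell; 50 random filter/ODE instances; 150 cells × 45 frames
per decade of x0 for recovery; and 100 repetitions of a reduced
calibration study (3 cells, single pool, constant noise, 2 chains ×
1200 sweeps) for credible-interval coverage.  These sizes give
Monte-Carlo errors comfortably below the tolerances they are checked
against while keeping a full run in the minutes range.

## Known limitations

* The estimator's accuracy window requires measurement noise that is
  neither negligible (smoothing bias inflates x̂0) nor dominant
  (σ_e² deflates it); at x0 ≳ 1e6 with quadratic camera noise the
  underestimation approaches the order-of-magnitude boundary.
* If bleaching completes well before the last frame, late frames are
  pure noise and both routes degrade; the LNA itself needs tens of
  molecules to be trustworthy.
* The Kalman likelihood assumes frame-to-frame independent measurement
  noise; correlated errors are absorbed into apparent bleaching noise
  and bias ν upward (hence molecule numbers downward).  This is the
  regime the fluctuation estimator is designed to sidestep.
* Replicate combination operates on KDE approximations; with fewer than
  ~10² draws per replicate the kernel broadening (σ_K) is no longer
  negligible relative to posterior width.
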