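# Methods

## Model

DNA replication in eukaryotes proceeds by stochastic initiation (origin
firing), bidirectional fork progression, and pairwise fork coalescence.
`repkin` models the *ensemble-averaged* kinetics of this process for
arbitrary space-time initiation-rate profiles `I(x,t)` (initiations per kb of
unreplicated DNA per second) and fork-velocity profiles `v±(x,t)` (kb/s),
through three coupled fields: the replication fraction `f(x,t)` (probability
that position `x` is replicated by time `t` after S-phase entry) and the
right-/left-moving fork densities `ρ±(x,t)` (forks/kb):

    ∂f/∂t = v₊ρ₊ + v₋ρ₋
    ∂ρ±/∂t ± ∂(v±ρ±)/∂x = I(x,t)(1−f) − (v₊+v₋) ρ₊ρ₋ / (1−f)

New fork pairs appear at rate `I` thinned by the probability `1−f` that the
DNA there is not already replicated (passive replication); converging fork
populations annihilate in proportion to both densities and their closing
speed, renormalized by `1−f`.  In the homogeneous constant-rate limit the
system reduces to classical one-dimensional KJMA nucleation-and-growth
kinetics, `f(t) = 1 − exp(−I v t²)` and `ρ±(t) = I t exp(−I v t²)`, which the
test suite uses as an analytic oracle.  For constant `v` and arbitrary
`I(x,t)` the exact solution is also available through the backward light-cone
integral `1−f = exp(−∬_cone I)`; the solver was validated against it during
development.

The model is mean-field: it gives the infinite-cell average and carries no
cell-to-cell variability.  The complementary stochastic simulator
(`repkin.simulate`) generates single replication cycles with the identical
ingredients and is the package's ground-truth oracle and synthetic-data
source.

### Boundary conditions

* **periodic** — the molecule is a circle; the discrete advection flux
  telescopes, so the expected numbers of initiations and coalescences per
  cycle balance exactly (to the residual fork mass).
* **isolated** — a linear molecule; forks exit freely, zero inflow.
* **injection** — a fragment embedded in a longer genome.  The inflowing fork
  density at a boundary is the semi-infinite-flank edge density `I_out·t`
  thinned by the probability that the boundary point is still unreplicated.
  The package evaluates that thinning factor *self-consistently* with the
  local `f` at the boundary cell rather than with the flank-only closed form
  `exp(−I_out v t²)`: the two coincide when the interior replicates like the
  flank, but the closed form can underfeed by up to 2× when the interior has
  little initiation of its own (its expected number of boundary crossings is
  ½ instead of 1).  The standalone helper `boundary_fork_density` still
  returns the classical closed form `I_out·t·exp(−I_out v_out t²)`, whose
  peak sits at `t* = 1/√(2 I_out v_out)`.  In the simulator, injection is
  realized exactly by explicit homogeneous flanks of length `v_out·T` (with
  `T` the integration horizon, or 1.25× the label window during SMARD
  sampling, beyond which inflow can no longer affect the observables).

### Fork stalling at defects

With a defect model (mean spacing `d` kb, mean repair time `τ` s, possibly
infinite), moving forks convert to stationary stalled densities `ρˢ±` at rate
`v±ρ±/d`, are repaired at rate `1/τ`, and stalled forks are annihilated by
opposing moving forks.  The simulator places independent Poisson defect sets
per fork direction (strand-specific lesions) and draws exponential repair
times.  The repair term is integrated with an exponential-decay flux
(`(1−e^{−Δt/τ})/Δt` per unit density), which is exact for pure decay and
remains stable when `τ` is much smaller than the time step.

## Numerics

Explicit first-order scheme with operator splitting: each step first advects
`ρ±` with direction-aware conservative upwind fluxes, then applies the
source/sink terms to the advected fields.  The CFL condition
`max(v)·dt ≤ dx` is enforced at entry; with constant `v` and `v·dt = dx`
(Courant number 1) the advection is an exact lattice shift and the scheme has
no numerical diffusion, which is how the validation grids are chosen
(defaults: `dx = 0.5` kb, `dt = 10` s; validation: `dx = 0.25` kb,
`dt = 6.25` s).  The coalescence sink divides by `1−f` and is limited per
cell so that one step can never annihilate more forks than are present (all
pairwise sinks in a cell share one scale factor); without the limiter the
sink diverges by round-off as `f → 1`.  `f` is clamped to `[0, 1]`; an
excursion beyond `1 + 10⁻²` raises a numerical-instability error naming the
offending cell.  Expected initiation/coalescence counts are accumulated
during integration with the exact discrete quadrature, so the periodic-budget
identity holds to round-off (0.02% on the packaged test system at the default
grid).  Integration stops once the Poisson ending probability exceeds 0.999
(configurable) or at `t_max`, with the residual unreplicated mass recorded.

Known numerical limitations: the scheme is first order (halving the grid
halves the field error); at Courant < 1 the fork fronts acquire a diffusive
foot; the saturation tail of `f` carries an O(dt) bias that is invisible at
the validation grids but measurable at coarse ones.

## Timing curves

The start probability is exact within the model:
`P_s(t) = 1 − exp(−N_e(t))` with `N_e = ∬ I dx dt'` over the molecule (no
`1−f` factor: the first event is unconditioned), and for a sub-fragment the
no-start probability is multiplied by the no-crossing factors
`(1−f₊(x₋,t))(1−f₋(x₊,t))` built from the directional replication fractions
`f± = ∫ v±ρ± dt`.  The end probability treats the surviving fork count as
Poisson: `P̃_e = exp(−∫ q₊ dx)` with `q₊ = ρ₊/f` (the density per replicated
probability; the unnormalized variant is shipped for comparison but is
unphysical at early times, `P̃_e(0) = 1`).  For fragments,
`P_e = f(x₋,t)·exp(−∫ q₊ dx)`; the left- and right-moving variants agree
under periodic boundaries and their choice is a keyword.  The Poisson
approximation is accurate early and late in S phase and weakest mid-S: on the
packaged two-zone system — whose last coalescence is a nearly deterministic
meeting of two specific fronts — the maximum deviation from the simulated
last-coalescence CDF is 0.077–0.094 across ensemble seeds, and in
homogeneous systems it decreases monotonically as the expected number of
initiations grows (0.088 → 0.045 for `I₀L` from 2×10⁻³ to 5×10⁻²/s).

## The packaged test system

A 1000 kb periodic genome with two Gaussian initiation zones of σ = 25 kb
(≈50 kb extent): an "early" zone at 200 kb active throughout S phase and a
"late" zone at 800 kb, ten times more efficient at peak, switching on at
5000 s; constant fork velocity 0.04 kb/s.  The early-zone peak amplitude is a
package default of 10⁻⁵ initiations/kb/s, chosen once so that replication
spans a realistic mammalian S-phase scale (first initiation ≈ 1600 s, typical
completion ≈ 11000 s, ~5 initiations per cycle); only the 10× ratio and the
geometry are constrained externally.

## SMARD observables

The simulated SMARD protocol labels an asynchronous population (switch time
uniform on `[0, T_window]`, with `T_window` defaulting to the time the ending
probability passes 0.999), keeps molecules carrying both labels, and computes
red-green content per 5 kb bin, directional fork densities per 50 kb bin
(fork marks are label transitions, oriented red → green), and the content
autocorrelation (biased estimator, periodic wraparound where applicable, lags
to L/2).  The mean-field predictions are

    r̃(x)  = ∫ [f(x,t) − P_e(t)] dt / W,   ρ̃±(x) = ∫ ρ±(x,t) dt / W,
    W = ∫ [P_s(t) − P_e(t)] dt,

where the `P_e` subtraction removes fully replicated (uniformly red)
molecules from the content average and `W` is the expected time a molecule
spends two-colorable.  Because `P_s`/`P_e` for fragments are approximate (see
above), the fragment-level predictions carry a ≈1–2% scale bias, which is the
dominant model error in fitting.  The red-green content peaks highest at the
*early* zone (it is replicated first); the late zone produces the second
local maximum — peak height reflects replication order, and only
conditionally zone efficiency.

Synthetic molecule sets emulate ideal SMARD data: perfect asynchrony, exact
label transitions at the simulation lattice (0.1 kb), no optical resolution
limit, no fiber breakage or chimeras, and exactly one molecule per fragment
per cycle.  Passing tests therefore validate the estimators and the fitting
machinery, not robustness to those experimental artifacts.

## Fitting correlated profiles

Neighboring profile bins share molecules, so the data vector `y` (content
bins, then ± fork-density bins, per fragment and condition) is strongly
correlated — its short-lag content autocorrelation is materially positive.
The fit follows the iterative decorrelated least-squares loop: predict
`m(θ)`, simulate `n_sim` replicate experiments at θ with the experiment's
molecule counts, estimate their covariance (unbiased; rank-deficient when
`n_sim < dim y`, hence flagged), fit a positive-definite surrogate — per
block, a moving-average-smoothed variance profile (floored at a
binomial-scale minimum so degenerate always-one-color bins keep finite
weight) times the correlation `c + (1−c)·exp(−Δx/λ)`, both parameters fitted
to the mean empirical correlation by lag.  The constant term is real physics:
all bins of a molecule share its label-switch time, so content bins carry a
molecule-level common component on top of the local label continuity;
omitting it leaves residual correlation after whitening and inflates the
chi-square.  Cross-block covariances are set to zero, and the final surrogate
is a 50/50 shrinkage blend of this structured matrix with the raw empirical
covariance (still positive definite; the weight was calibrated so the
whitened residual chi-square evaluated *at a known generating scenario* is
~1.05, where the pure structure gives 0.77 and light shrinkage 1.5) —
Cholesky-factor it, whiten data and model with `L⁻¹`, and minimize the
unit-weight least squares over θ with bounds (rates and velocities in log10;
trust-region reflective with finite differences).  The outer loop refreshes
the covariance at the updated θ and stops when the largest relative parameter
change drops below 10⁻² (default limit 6 outer iterations).

The data vector also carries, per fragment, the fraction of fully labeled
molecules that are two-color, predicted as `W / T_window`.  This quantity is
directly available from the same collected molecules, is predicted by the
same rate-equation solution, and anchors the fragment's replication duration;
without it the fork velocity and the zone amplitudes form a sloppy valley in
which the small fragment-timing model bias produced ≈20% velocity errors.

Parameter uncertainties are the curvature (whitened Gauss-Newton) standard
errors `√diag[(JᵀJ)⁻¹]`; the reduced chi-square uses
`dof = dim(y) − dim(θ)`.  Two scenario families ship: a single-condition
two-zone family (10 parameters: two rounded-box zones — logistic edges of
scale 2 kb by default, since the profile shape is only weakly identified —
plus background, two boundary injection rates, one velocity) and a
two-condition global family (11 parameters) in which a "rearranged" allele
shares all initiation parameters but lacks the second zone, its domain
shortened by a 65 kb deletion, with per-condition velocities.

Synthetic recovery at experiment scale (two 300 kb fragments, 50 two-color
molecules each, five independent data sets): zone centers recovered within
9 kb, reduced chi-square 1.2–1.9, velocity median within 2% of truth with a
per-seed spread of ±10–20% (the sampling limit at this molecule count);
amplitudes are the sloppiest direction, recovered within a factor ≈2.

## Reproducibility

Every stochastic component consumes a single master seed through
`numpy.random.SeedSequence` substreams (per cycle, per replicate, per outer
iteration); ensembles, molecule sets and fits are bit-reproducible given
(data, seed, configuration).  CLI runs write a JSON manifest with the
configuration hash, seeds, grid, and wall time.

## Problem sizes used in the shipped validation

Field validation uses 1000-cycle ensembles binned at 10 kb × 250 s (events at
50 kb × 1000 s); injection and stalling checks use 600–800 cycles on
200–300 kb systems; SMARD estimator checks use 5000 synthetic molecules
(plus a 40-molecule experiment-scale set); recovery fits use 50 molecules per
fragment, 40 covariance replicates per outer iteration, and a 1 kb forward
grid.
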