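# Methods

This note documents the statistical machinery in `stmap`: the models,
the priors, the sampler, the synthetic-data law, and the numerical
choices a user should know before trusting the output.

## Problem setting

The package analyses a balanced areal panel: for each of n cities
(areal units nested in provinces) and each of T years we observe a
count of incident cases `O_it` and a male population `N_it`.  Because
incidence is strongly age-dependent and city-level age pyramids are
rarely published, risk is measured by the standardized incidence ratio
(SIR) from indirect standardization:

    N_itk  = N_it * p_k(province(i), t)        k in {0-14, 15-64, 65+}
    E_it   = sum_k N_itk * R_k / 100000
    SIR_it = O_it / E_it

where `p_k` are province-level age-composition proportions and `R_k`
national reference age-specific rates per 100,000 person-years.  SIR > 1
means above-reference risk after adjusting for age structure.  Cells
with `E_it = 0` are undefined and are dropped with a logged warning;
cells with `E_it < 1e-8` are rejected before model fitting.

## Spatial weights and autocorrelation

Adjacency is first-order queen contiguity: units are neighbours when
their boundaries share at least one point.  Contiguity is decided by
exact geometric intersection (tolerance 0); an optional snap tolerance
exists for sliver-ridden real-world layers but is off by default
because it is a data-cleaning concern, not a definition.  Islands are
retained with all-zero weight rows (their Moran lag is zero) rather
than dropped, so n is never silently changed.

Four statistics are provided:

* **Global Moran's I** on row-standardized weights, with conditional
  randomization inference: values are permuted across regions and the
  two-sided pseudo p-value is `(1 + #{|I_perm| >= |I_obs|})/(n_perm+1)`
  with `n_perm = 999` by default.  The reported z-score uses the
  mean/sd of the permutation distribution; the analytical
  normal-approximation moments are available as an option.
* **Local Moran (LISA)** `I_i = (c_i/m2) * sum_j w_ij c_j` with
  conditional permutation (region i held fixed), quadrant typing
  HH/LL/HL/LH at alpha = 0.05 by default, no multiplicity correction
  (matching common practice), with an optional Benjamini-Hochberg flag.
* **Getis-Ord Gi\*** with binary weights and self-inclusion
  (`w_ii = 1`), the standard z-score form, binned at the two-sided
  90/95/99% normal thresholds.
* **Spatiotemporal Moran's I** over joint space-time cells with a
  binary space-time weight matrix.  The default scheme links spatial
  neighbours within the same year plus each city to itself in adjacent
  years; `full_st` additionally links spatial neighbours at lag one.
  The statistic is weight-sum normalized as printed, so the matrix is
  used in binary form; inference permutes space-time cells jointly.

All four statistics are invariant to positive affine transforms of the
input, which the suite asserts numerically.

## The Bayesian model family

Counts follow a Poisson likelihood with the expected counts as offset:

    O_it | eta_it ~ Poisson(E_it * exp(eta_it))
    eta_it = alpha + b_i + gamma_t + phi_t + delta_it

* `alpha` — intercept, prior N(0, 1e6).
* `b_i` — spatial block: iid, Besag (ICAR, precision the graph
  Laplacian D - A with per-component sum-to-zero constraints), BYM
  (ICAR + iid with separate loggamma(1, 0.0005) precisions), or BYM2:

      b_i = (1/sqrt(tau_b)) (sqrt(1-omega) v_i + sqrt(omega) u*_i)

  with `v` standard normal, `u*` the *scaled* ICAR effect (the
  precision is multiplied by the geometric mean of the marginal
  variances of the constrained generalized inverse, so that geometric
  mean becomes 1), `tau_b` the marginal precision with a PC prior
  pc_prec(U=1, alpha=0.01), and `omega` the structured share with the
  distance-based PC prior pc(U=0.5, alpha=0.5).
* `gamma_t` — structured time: RW1/RW2 (improper difference
  precisions, rank T-1 / T-2, sum-to-zero and linear constraints) or
  stationary AR(1)/AR(2) in the unit-marginal-variance
  parameterization.  The AR(1) coefficient rho gets N(0, 0.15) on the
  transformed scale log((1+rho)/(1-rho)) by default (the printed
  "N(0, 0.15)" does not state a scale; variance on the transformed
  scale is the conventional reading, and a literal-scale option plus a
  pc_cor0 option exist).
* `phi_t` — iid year noise, precision with a PC prior by default.
* `delta_it` — Knorr-Held interaction, types I-IV built as Kronecker
  products of the factor structures (`Q_space (x) Q_time` for Type IV).
  The interaction reuses the temporal block's structural parameter
  (the AR rho), so the rho update sees both the gamma and delta prior
  terms.  Its precision `tau_delta` has pc_prec(1, 0.01) (the headline
  model) or loggamma(1, 0.0005) (the classic-prior model).

### PC priors

`pc_prec(U, alpha)` on a precision has density
`(lam/2) tau^{-3/2} exp(-lam tau^{-1/2})` with `lam = -ln(alpha)/U`,
i.e. an Exponential(lam) prior on the standard deviation, so
P(sd > U) = alpha exactly.

`pc_mix(U, alpha)` for the BYM2 mixing: the distance from the base
model (omega = 0, pure iid) is `d(omega) = sqrt(2 KLD)` where the KLD
between the BYM2 joint at mixing omega and the iid base is evaluated on
the constraint-orthogonal subspace using the eigenvalues of the scaled
ICAR generalized inverse.  Because d(1) is finite here, the exponential
prior on d is truncated at d(1) and its rate is solved numerically
(allowing negative rates when needed) so that P(omega > U) = alpha
holds exactly under the renormalized prior; the density integrates to 1
over [0, 1] by construction and the suite verifies both properties by
quadrature.

`pc_cor0(U, alpha)` for an AR(1) coefficient: base model rho = 0, with
`d(rho) = sqrt(-(T-1) ln(1 - rho^2))` (the KLD of a unit-variance
AR(1) of length T against white noise), rate solving
P(|rho| > U) = alpha; d(1) diverges so no truncation is needed.

### Identifiability of the interaction

The structural null-space constraints of the Kronecker interaction
(e.g. per-year spatial sums for Besag x AR(1)) are not sufficient for
identification when the temporal factor is proper: a constant-in-time
per-city component of delta is indistinguishable in the likelihood from
the spatial main effect, which biases the AR coefficient (the residual
after the spatial block absorbs those components is negatively
lag-correlated) and the interaction precision.  Following the standard
prescription in the disease-mapping literature, the default model
therefore constrains delta to be orthogonal to both main effects:
sum over cities within each year and sum over years within each city
are both zero.  The doubly-centred subspace factorizes as
S_space (x) S_time, so the constrained prior is again a Kronecker form
on an (n-1) x (T-1) coefficient array; the rho-dependent part of its
log-determinant is `(n-1) ln det(B_t' Q_t(rho) B_t)` with `B_t` an
orthonormal basis of the zero-sum subspace in time, and the precision
update uses rank (n-1)(T-1).  Setting
`ModelSpec(identifiable_interaction=False)` restores the
structural-constraints-only model; that variant reproduces the
signature seen in published registry fits of this family — an AR
coefficient posterior collapsed near zero and a persistently-signed
interaction surface — at the price of non-recoverable rho/tau_delta.
This requires a connected adjacency graph (lattices and national
city layers are; an error is raised otherwise).

## Inference

Posterior sampling is Metropolis-within-Gibbs:

* Latent Gaussian vectors use single-site random-walk Metropolis,
  vectorized over colour classes of the conditional-dependence graph of
  their precision (sites within a colour are conditionally independent
  given the rest, so simultaneous independent accept/reject is exact).
  Proposal steps adapt toward ~35% acceptance during burn-in only.
* Precisions with loggamma (Gamma) priors are conjugate:
  Gibbs draws from Gamma(a + rank/2, b + x'Qx/2).
* Precisions with PC priors use an independence Metropolis proposal
  drawn from the Gamma likelihood factor `tau^{rank/2} e^{-tau q/2}`;
  the acceptance ratio reduces to the PC-prior ratio, which keeps
  acceptance high even when tau and its field are strongly coupled.
* `omega`, `tau_b` and rho are updated by random-walk Metropolis on
  logit / log / log-odds scales.
* Several likelihood-preserving moves fight the posterior's confounded
  directions: the intercept swaps mass with the means of phi, gamma and
  the iid spatial vector; (omega, tau_b) proposals jointly rescale
  (v, u*) so the composite field b is fixed; the (v, u*) split is
  refreshed by an exact constrained Gibbs draw at fixed b every third
  sweep; and in the structural-constraints mode a shear move trades
  per-city delta time-means against the iid spatial vector.
* Sum-to-zero constraints are re-imposed by centering after every
  sweep, with the removed means transferred into the blocks that absorb
  them (intercept, phi/gamma, v/u), so the likelihood is untouched.

Defaults are 2 chains, 20,000 iterations, 10,000 burn-in, thinning 5;
a seed is required (no silent default).  Chains are initialized with
overdispersed jitter.  Split-R-hat and effective sample sizes (via
ArviZ) are reported for every scalar hyperparameter; a fit with any
R-hat > 1.05 is flagged non-converged and the CLI exits nonzero.
Because the weakly-identified temporal precisions (T = 4) have heavy
posterior tails, their R-hat can flag at short chain lengths even when
substantive parameters have settled; the flag is deliberately
conservative.

## Model comparison and calibration

* DIC: `Dbar + p_D` with `p_D = Dbar - D(posterior mean of eta)`.
* WAIC: `-2 (lppd - p_WAIC)` with the pointwise log-sum-exp lppd and
  the pointwise posterior variance penalty (ddof = 1).
* Randomized PIT for counts:
  `u = F(O-1) + v [F(O) - F(O-1)]`, `v ~ U(0,1)` with a fixed seed.
  F is the *cross-validated* (leave-one-out) predictive Poisson CDF,
  obtained from posterior draws by CPO-style importance weighting —
  the same construction INLA reports.  The in-sample
  posterior-predictive variant is available but is over-concentrated
  whenever the model carries cell-level random effects, so the
  cross-validated version is the calibration check: a uniform 10-bin
  histogram indicates a calibrated model.

The pipeline's selection rule requires the same model to minimize both
DIC and WAIC; if the criteria disagree the run is flagged "discordant"
and both winners are reported.  The default ladder is: pure-spatial BYM;
pure-temporal RW1 + iid; BYM + RW1 + iid + Besag x RW1 interaction with
loggamma priors; and BYM2 + AR(1) + iid + Type IV with PC priors.  The
prior-sensitivity grid varies one axis at a time: pc_prec
U in {0.5, 1, 2} x alpha in {0.01, 0.05, 0.1} for each of the four
precision parameters, the mixing threshold U in {0.3, 0.5, 0.7}, and
pc_cor0 thresholds U in {0.1, 0.2, 0.4} at alpha = 0.2 for rho —
42 settings, with baseline cells flagged and failed cells marked while
the grid completes.

## Synthetic registry generator

The generator draws every input the pipeline needs from one integer
seed (split with `numpy.random.SeedSequence`, so stage-level
reproducibility survives reordering): a unit-square lattice of cities
grouped into rectangular provinces, log-normal male populations,
province age compositions (a Dirichlet base per province plus a smooth
deterministic aging drift of the 65+ share, emulating how yearbook
compositions evolve over a short panel rather than resampling them
independently each year), reference rates, latent effects drawn from
the model law above, and Poisson counts.

The bundled `paper_scenario()` emulates a 132-city, 4-year national
male-cancer registry panel with the qualitative features of the real
series: prefecture-scale populations (median 1.2M males), a
deterministic annual log-risk trend of 0.055 (~5.6%/yr) dominating
small year noise so the national crude rate rises monotonically, aging
drift widening the crude/age-standardized growth gap, a fixed
southeast-high linear gradient of amplitude 1.2 on the log-risk scale
whose extra amplitude grows by 0.25 per year (carried by the
interaction), a BYM2 field with structured share 0.08, and an
interaction surface with a ~73%-negative background plus a small
(15%), strongly positive, spatially scattered set of anomaly cities at
fixed locations.  The scenario keeps the structural interaction
constraints so these anomalies persist across years, as a registry
surface with stable city-specific deviations does.  Numbers chosen once
at design time; they are generator knobs, not estimates of published
values.

What the generator does **not** emulate: county-to-city aggregation and
registry under-coverage, migration-driven age-structure bias within
provinces, irregular (non-lattice) adjacency, and reporting gaps.
Passing tests therefore demonstrate correctness of the machinery under
the stated law, not robustness to those real-data pathologies.

## Problem sizes used in the validation suite

Chosen to keep the whole suite desk-scale while leaving the replicate
counts at full strength: oracle cross-checks run on 20 random lattice
fixtures; parameter recovery uses 20 replicates per scenario on a
10x10 lattice with T = 4 and 2 chains x 2,500 iterations; model
selection uses 20 replicates on a 6x6 lattice; calibration uses a
528-cell panel; the scenario checks run on the full 132-city panel.
The `--quick` pipeline mode (2 chains x 2,000 iterations) exists for
smoke runs and CI-style checks; full-length chains are recommended for
substantive analyses.

## Known limitations

* The sampler is exact but not gradient-based; for much larger panels
  (thousands of units) an INLA- or HMC-based engine would be
  preferable.
* AR(2) support is minimal (coefficients fixed at stationary defaults
  unless updated externally); the published analyses this package
  targets use AR(1).
* The mixing-parameter posterior aggregates everything spatially smooth
  into the "structured" share, including deterministic gradients, so
  its posterior mean exceeds the generator's omega when a fixed tilt is
  present; comparisons should be directional, which is how the
  acceptance suite treats them.
* Multi-component (island-containing) graphs are supported for all
  spatial statistics and main-effect models, but identifiable
  interaction fits require a connected graph.
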