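# Methods

`pathway-uq` implements a three-stage workflow for over-parameterized
mass-action models of intracellular signalling: (i) inverse uncertainty
quantification by approximate Bayesian computation (ABC), with multiple
datasets merged sequentially through vine-copula priors; (ii) forward
propagation of the posterior sample to prediction ensembles; (iii) global
sensitivity analysis (GSA) on those ensembles by binned variance
decomposition and Monte Carlo filtering.  This note records the models,
defaults and numerical choices, and what the synthetic test bed does and
does not demonstrate.

## Reaction networks and thermodynamic structure

A model is a list of species and reversible elementary reactions
`A + B <=> C` with forward rate `kf`, backward rate `kr`, and dissociation
constant `Kd = kr/kf`; non-elementary steps (e.g. CaMKII
autophosphorylation) are declared as `custom` reactions with an explicit
rate expression and are excluded from all thermodynamic analysis.
Concentrations are µM; every sampled or stored parameter is a log10 value.
The base of the log scale is a package-wide convention (base 10) used
consistently for priors, entropies and copulas.

**Conservation laws.** Each group of interconvertible elementary species (a
moiety) yields one conserved total.  Compositions of complexes are resolved
by balancing reactions; each returned vector is verified against the
stoichiometric matrix (`c^T N = 0`), so a mis-specified model fails loudly
at parse time.

**Wegscheider constraints.** Around every independent reaction cycle the
equilibrium constants must multiply to one; equivalently each integer
null-space vector `z` of the mass-action stoichiometric columns imposes
`sum_j z_j log10 Kd_j = 0`.  The constraint basis is computed exactly with
rational arithmetic (sympy), and one Kd per cycle is designated
*constrained* and eliminated.  The default preference constrains the
last-indexed reaction of each cycle, which makes the free/constrained split
deterministic; callers can override it with an ordered `free_choice`.  The
solved form stores exact rational coefficients (integers in every simple
cycle), so completed log-Kd vectors satisfy the cycle identities to machine
precision.

**Equilibrium solver.** At detailed balance every reversible flux vanishes
individually, so equilibria depend on the mass-action parameters only
through the Kds.  The solver works in log10 concentration space: unknowns
are one representative per conserved moiety; every other species follows
from the cycle-consistent Kds through a resolution plan built once per
network.  The residual is the log-mismatch of each conserved total, solved
with scipy's `hybr` root finder (Levenberg-Marquardt fallback) from an
even-split initial guess, with optional warm starts along titration grids.
A zero total removes the corresponding moiety's species before solving.
Convergence demands a conservation residual below 1e-7 in log10 units;
failures raise with the residual norm rather than returning silently.

**ODE integration** uses LSODA (stiff-capable) at rtol 1e-8 / atol 1e-10.
Custom rate expressions are sympy-parsed once and evaluated on the clipped
nonnegative state.

## Experiments and the ABC distance

An experiment ("phenotype") fixes the totals of the active species, scans
one input over a strictly increasing grid, and reads out a symbolic
observable of the equilibrium (or ODE-endpoint) state, the totals and any
readout-scale parameters.  The distance between simulated and measured
curves is the root-mean-square pointwise error normalized per curve by the
data curve's maximum absolute value (or an explicit scale), averaged with
equal weight over curves.  This form is dimensionless, bounds each curve's
influence, and is swappable through `DistanceSpec`.  The summary statistic
is the identity: curves here are low-dimensional, so no further compression
is needed.  Experiments are weighted equally when merged.

## ABC samplers

*Rejection*: draw from the prior, keep draws with distance <= delta.
*MCMC*: Gaussian random walk in log10 space with the Marjoram rule —
accept iff the proposal's distance passes the current threshold and a
Metropolis ratio on the prior density passes (the likelihood-free chain
targeting the stated approximate posterior).  The threshold is adaptive
within a single run: it starts at the initial state's distance and shrinks
geometrically (factor 0.9 every 200 iterations by default) until the target
delta, after which sampling begins; only post-burn-in states at the target
threshold are retained (burn-in 20% of the sampling phase, optional
thinning).  A chain with no acceptance over a configurable window raises
with its last threshold and distance.  All runs are reproducible from a
single integer seed.

## Copula-chained sequential fitting

Datasets are fitted in sequence; after each step the posterior sample is
compressed into a reusable prior with two layers:

* **Marginals** — Gaussian-kernel densities with reflection at the support
  bounds (the current prior's box), because ABC posteriors frequently pile
  up against the prior edges where an unreflected KDE would leak mass.
  CDF and quantile maps are tabulated so that they are exact inverses.
* **Dependence** — a canonical vine (C-vine) of bivariate pair copulas over
  the rank-transformed sample.  The variable order is chosen once, by
  decreasing summed |Kendall tau|; tree j is rooted at position j.  Per
  edge the family is selected among independence, Gaussian, Clayton,
  Gumbel and Frank by maximized pseudo-likelihood, with parameters from
  inversion of Kendall's tau and an asymptotic independence test applied
  first.  A C-vine is a valid regular vine, and at this package's typical
  dimensionality (tens of parameters) it keeps density evaluation and
  inverse-Rosenblatt sampling simple and fast; optional truncation replaces
  deeper trees by independence.  Negative-dependence rotations of
  Clayton/Gumbel are not implemented — for negative tau the family set
  reduces to Gaussian/Frank — a deliberate parsimony choice.

The fitted object evaluates its log density (needed for the MCMC prior
ratio) and samples reproducibly, so the next ABC step targets exactly the
compressed posterior.  The package's fidelity checks are behavioural:
refitting the same dataset twice must leave the marginals unchanged within
KS tolerance, round trips must preserve pairwise Spearman correlations, and
fitted 2-D densities must integrate to one.  If a marginal is strongly
bimodal the approximation degrades; partitioning the sample and fitting one
copula per region is the recommended escape hatch, not automated here.

For semi-steady-state data the fit runs on the Kd parameters with kf held
constant, and the posterior is afterwards expanded to the kf dimensions by
simple rejection against the dynamic setups (kr = Kd * kf throughout);
equilibrium-mode setups are provably insensitive to kf, so they accept
every kf draw.

## Posterior characterization

Per-parameter information gain is the entropy reduction
`H_diff = H_prior − H_post` with `H = −Σ_k p_k ln(p_k) Δb` from the
density-normalized histogram, in nats.  Prior and posterior share the same
bin edges — 50 equal-width bins spanning the union of both samples by
default — which makes H_diff stable at the sample sizes the samplers
produce (10^3–10^4).  Correlation structure is summarized by the Pearson
matrix with rows ordered by hierarchical clustering of
absolute-correlation profiles (Euclidean metric, average linkage), so
strongly coupled parameters are adjacent.  Credibility intervals are
equal-tailed quantiles.  Parallel-coordinate output is a data export
(normalized coordinates plus a kernel-density line weight), not a figure.

## Global sensitivity analysis on the dependent posterior

Standard pick-freeze Sobol estimators assume independent inputs and cannot
be applied to an ABC posterior with internal correlations.  The first-order
index `S_i = V(E(Y|Θ_i))/V(Y)` is instead estimated directly on the
existing sample by binning: rows are split into equal-count bins by the
rank of parameter i (20 bins, minimum occupancy 20 by default), and S_i is
the occupancy-weighted variance of within-bin output means over the total
variance, per input-grid point.  Raw and [0,1]-clamped values are both
reported, and a variance-weighted aggregate across the grid is available.
The estimator carries a small positive bias of order 1/(bin occupancy) for
null parameters and a multiplicative bias of order 1/n_bins^2 for active
ones; the defaults balance the two at n ≈ 10^4.

Monte Carlo filtering splits the ensemble by a qualitative criterion —
built-ins are `monotonic` (successive differences above −2% of the curve
range, robust to solver noise) and `sign_pattern`, an LTD/LTP-style
predicate with explicit window and threshold parameters (near zero at the
lowest inputs, negative on a low window, positive on a high window) so a
published criterion can be transcribed exactly and its thresholds varied.
Parameters are ranked by the two-sample KS statistic of the
class-conditional marginals; parameter pairs by the symmetrized (Jeffreys)
KL divergence of 2-D histograms on a shared grid with 0.5 pseudo-count per
cell.  Symmetrization removes the direction ambiguity of KLD and the
pseudo-count removes zero-cell blow-ups; the self-divergence then vanishes
as n grows, which the tests verify at 10^3 and 10^4.

## Synthetic test bed

The demo network is a minimal ligand-binding system — protein L, ligand X,
partner P, complexes LX, LP, LXP — whose four reversible reactions close
one thermodynamic cycle (Kd4 = Kd1·Kd2/Kd3), with three conserved totals.
Two steady-state titration phenotypes emulate fraction-bound dose-response
assays: a scan of X with P absent (isolating Kd1) and with P present
(engaging Kd2/Kd3).  Ground-truth curves carry additive Gaussian noise at
2% of each curve's range by default, comparable to tight steady-state
binding assays; multiplicative lognormal noise is available.  The
ground-truth log10 vector (0.30, 0.10, −0.20) is deliberately offset from
the prior centers so recovery is informative.

The shipped CaMKII/CaM/PP2B/PP1 fixture (`data/camkii_synthetic.tsv`) is a
*synthetic reconstruction* of a published synaptic-plasticity network: it
reproduces the published structural facts — 25 species, 34 reactions, all
but two elementary reversible, sequential Ca binding of calmodulin and of
every protein-CaM complex, a kautMax-driven autophosphorylation and a
PP1-dependent dephosphorylation used only for predictions — but not the
original reaction table or fitted kinetics, which are not redistributed
here.  It is exercised by structural tests only (counts, 12-cycle
constraint consistency, conservation structure, equilibrium solvability);
no claim about reproducing the published calibration or predictions
attaches to it.

What the synthetic tests show: the full loop (noise injection → sequential
ABC through the copula chain → credibility intervals) recovers the
generating parameters, with 95% intervals covering the truth in ≥ 90% of
seeded replicates at the default noise level, and the estimators hit their
analytic oracles (uniform/Gaussian entropies, Ishigami indices, truncated-
Gaussian ABC posterior).  What they do not show: performance on real
digitized dose-response data with model mismatch, correlated measurement
error, or the dimensionality of the full pathway model.

## Problem sizes and defaults

Default run sizes are chosen so the whole verification suite is a
desk-scale computation: ABC toys at n = 2000, copula checks at n = 5000,
sensitivity oracles at n = 10^4–2·10^4, and recovery at 20 replicates of a
1500-iteration chain per dataset (the acceptance script runs 8 replicates).
The MCMC proposal step (0.25 log10 units on the demo posterior) gives
acceptance rates in the few-percent range, and the adaptive ladder
(delta_0 = start distance, factor 0.9 per 100-iteration block) reaches the
target threshold in a few thousand iterations.

## Known limitations

* Equilibrium solving requires the mass-action subnetwork to determine all
  species from moiety representatives; exotic topologies (e.g. a complex
  formed only via reactions with stoichiometric multiplicity > 1) are
  rejected rather than mishandled.
* The C-vine with tau-inversion estimation is cruder than a full
  Dissmann-selected R-vine with per-edge MLE; for strongly tail-dependent
  or negatively Clayton-like posteriors the Gaussian/Frank fallback may
  under-fit the tails.
* The binned S_i estimator reports first-order effects only; under strong
  parameter dependence indices need not sum to one and have no unique
  attribution interpretation.
* ABC-MCMC retains duplicated states by construction; rank-based copula
  fitting tolerates ties, but heavy duplication (very low acceptance)
  degrades the compression — thin the chain or lengthen it.
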