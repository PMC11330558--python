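# Methods

This note documents the models, algorithms, numerical choices and known
limitations of `eurysize`, in the spirit of a statistical methods appendix.

## Trees and the time axis

Trees are rooted, with strictly positive branch lengths in Myr and tips at
their (generally non-contemporaneous) fossil ages. Node ages are in Ma
before present; by default the youngest tip anchors age 0, and an explicit
`root_age_ma` places the tree on the absolute age axis — required whenever
an environmental curve (indexed in Ma) is coupled to a trait model.
Zero-length branches are a validation error rather than being silently
jittered: they almost always indicate a data problem. Polytomies are
accepted; all matrix-based algorithms work from the shared-path covariance,
which is polytomy-safe.

## Continuous trait models

The trait is log body length (natural log of cm). All models are
parameterized with an explicitly free root state `z0` — including OU, which
is used in its *fixed-root, non-stationary* form. On fossil (non-ultrametric)
trees a stationarity assumption at the root is not innocuous, and the
fixed-root form nests BM exactly as `α → 0`. The multi-peak (OUM) models do
not force the root regime's optimum onto `z0` for the same reason.

Closed-form Gaussian models (BM, TREND, EB, KAPPA, OU) are evaluated as
exact multivariate-normal densities. The environment-coupled OU integrates
its mean ODE `dm/dt = α(θ(t) − m)`, `θ(t) = θ₀ + β·E(t)`, exactly over a
piecewise-linear interpolant of the fitted curve on a 0.25 Myr grid (the
same granularity the curves are resampled to); because all tips share one
age axis, the mean is a function of root-to-tip time only and is computed
once per parameter vector. The OUM models accumulate mean, variance and
the between-lineage discount segment-by-segment along the painting; with
per-regime `α` the covariance uses
`Cov(i,j) = Var(X_mrca)·exp(−∫α)` along each mrca-to-tip path.

**TREND on ultrametric trees is refused**: with contemporaneous tips the
drift term is an exact linear function of a constant and is confounded
with `z0`.

### Pulsed likelihood

The pulsed model is Brownian motion plus compound-Poisson jumps
(rate `λ_J` per lineage-Myr, Normal(0, `δ²`) jump sizes). The likelihood is
computed by pruning with **Gaussian-mixture messages**: the conditional
likelihood at each node is a finite mixture over per-branch jump counts.
Numerical policy (the central numerical decision of the package):

- per-branch Poisson counts truncated at the smallest `m` with tail mass
  < 1e-10 (1e-6 during the cheap exploration phase of fitting);
- components below 1e-12 of the largest weight are pruned; the discarded
  mass is tracked and must stay below 1e-6 (error otherwise);
- near-coincident components (means within `tol` local standard
  deviations, log-variances within `tol`) are **merged by moment
  matching**, which conserves mixture mass exactly; `tol` = 0.01 for
  evaluation, coarsened adaptively if the mixture exceeds the component
  cap (256 by default);
- branches whose expected jump count exceeds 25 use a single
  moment-matched Gaussian (CLT regime); a jump rate implying more than
  ~2000 expected jumps on the whole tree is rejected as implausible.

With `λ_J = 0` or `δ² = 0` the computation collapses exactly (not
approximately) to BM. Merging at tol 0.01 perturbs log-likelihoods by
~1e-3 on 100+ tip trees — far below any model-selection margin observed —
and is validated against a truncated-series oracle (single branch) and a
10⁶-draw Monte-Carlo oracle (4-tip trees) in the test suite.

Fitting the pulsed model profiles `z0` out of the root mixture (the root
message does not depend on it), optimizes (`σ²`, `λ_J`, `δ²`) on the log
scale with derivative-free Nelder–Mead in two phases (coarse exploration,
then a polish at evaluation accuracy), and starts from several points
along the `λ_J·δ²` ridge: the same apparent variance flux can come from
rare large jumps or frequent small ones, and gradient methods stall on
that ridge.

### Optimizer

All other models use multi-start L-BFGS-B on transformed parameters
(log scale for positive parameters) within documented bounds
(`σ², δ² ∈ [1e-8, 1e4]`, `α ∈ [1e-8, 1e2]`, `Κ ∈ [0, 3]`,
`λ_J ∈ [1e-8, 10]`, `|β| ≤ 100`, `|μ| ≤ 10`), with one moment-based start
(GLS root and BM rate) plus seeded Latin-hypercube restarts (10 by
default; analyses in this repository use 2–3, which calibration showed is
sufficient at these problem sizes).

### Parameter counts

AICc uses fixed, documented counts: BM 2, TREND 3, EB 3, KAPPA 3, OU 4,
PULSED 4, ENV_OU 5; OUM with shared dynamics `3 + (number of regimes)`
(OUM2 5, OUM3 6); the free-dynamics OUM variant (per-regime `σ², α`) adds
2 per extra regime (OUM2 7, OUM3 10). Shared dynamics is the default:
freeing nine parameters on three regimes is rarely identifiable at
~135 tips. Ranking uses per-tree AICc weights and the **median** weight
across trees (means are reported alongside); ties break toward fewer
parameters, then model name.

## Habitat evolution

Mk likelihoods use Felsenstein pruning with level-batched linear algebra
and eigendecomposition-based transition matrices (scipy `expm` fallback
for defective rate matrices). Missing tip states are fully ambiguous.
Root prior options: uniform, stationary (default; robust least-squares
null vector with a uniform fallback for degenerate matrices), or a fixed
state.

**Stochastic mapping** samples node states from their joint conditional
distribution and branch paths by uniformization (endpoint-conditioned;
rejection sampling is kept in the tests as a cross-check on small cases).
The pipeline maps under the single AICc-best Mk structure by default;
averaging maps over the rjMCMC posterior is available by calling
`stochastic_map` with sampled rate matrices.
A continental "colonization" is any transition event whose destination
state is continental, anywhere in a sampled history.

**rjMCMC over rate structures.** The model space is every assignment of
the k(k−1) off-diagonal entries to shared-rate classes, including a zero
class (structural absence). The prior is uniform over canonical
structures; class rates are i.i.d. exponential with mean equal to the
Fitch parsimony change count divided by total tree length. This
empirical scale matters: a prior crowded near zero makes a free rate
indistinguishable from a structural zero and erases the reversible-jump
Occam penalty. Moves alternate log-scale rate updates with single-entry
reassignments in which persisting classes keep their rates and only a
freshly created class draws from the prior (birth-from-prior; the
dimension-matching Jacobian is 1, and the acceptance ratio reduces to the
likelihood ratio times the neighbourhood-size ratio). Detailed balance is
validated by running the chain without data and comparing the visit
distribution to the uniform prior.

Two structure summaries are reported: the modal full structure, and the
modal **zero pattern** (which entries are structurally zero, marginalizing
over how the nonzero rates are grouped). The zero pattern is the summary
used for the terrestrialization question — whether direct
marine ↔ continental transitions are absent — because the grouping of the
nonzero rates is a nuisance dimension there.

**Regime paintings.** Habitat paintings relabel stochastic maps
(three-peak identity; two-peak merges marine + continental into "other").
The extinction-crisis painting splits branches exactly at the crisis age;
post-crisis lineages outside the two named surviving clades default to the
pre-crisis regime (configurable).

Character histories serialize as a segment table (CSV) or a simmap-style
Newick with per-branch `{regime,length}` annotations. Subtree re-analyses
(e.g. per suborder) are the same pipeline applied to pruned trees,
selected by the trait table's clade column via the `clade_filter` config
key.

## Ancestral size and origin counting

The root state is the GLS estimate under BM with its sampling variance
(CI on the log scale, reported back-transformed to cm). Internal nodes
use the BM conditional expectation given the tips. An **origin** of large
(≥ 50 cm) or giant (≥ 100 cm) size is an edge whose reconstructed parent
value is below the log threshold and whose child value is at or above it
(plus one if the root itself reconstructs above threshold). Counting from
GLS point reconstructions is a documented choice — stochastic-map-based
counting of a discretized trait would be an alternative. The count is
monotone non-increasing in the threshold whenever the threshold exceeds
the root reconstruction, which is the regime of both thresholds used.

## Ecology statistics

PGLS uses Pagel's λ residual structure (λ fixed at 1 by default — plain
BM covariance — with λ = 0 and ML-λ available). The permutational ANOVA
computes the PERMANOVA pseudo-F from Euclidean distances of standardized
ecospace counts (predators, prey, co-occurring eurypterids, assemblage
richness — the default variable set), with
`p = (1 + #{F_perm ≥ F_obs}) / (1 + n_perm)`. Predator/prey rules: a
predator is a carnivorous fish, nautiloid or eurypterine over 2× the
focal eurypterid's length, or a stylonurine over 5× (sweep feeders);
hibbertopterids (suspension feeders) never qualify; prey are mobile
benthic or nektonic species under half a predatory eurypterid's length,
sessile taxa excluded. Size groups split at 0.5 m exactly. Assemblage
groupings are taken as given in the community table; grouping taxa from
single localities with environmentally similar coeval units is input
preparation, not something the package infers.

## Synthetic data

The generator emulates the shape of a Palaeozoic fossil dataset:

- **Trees**: forward fossilized birth–death simulation (birth 0.05,
  death 0.028, fossil sampling 0.04 per lineage-Myr; 467–252 Ma window),
  pruned to 135 tips. Fossil samples with sampled descendants (sampled
  ancestors) are dropped and a lineage's latest sample becomes its tip, so
  reconstructed trees stay strictly binary with positive branch lengths.
  A "posterior" tree set applies multiplicative log-normal branch-length
  jitter (sd 0.08) to the base topology — temporal, not topological,
  uncertainty.
- **Sizes**: pulsed evolution with root `z0 = 2.8` (≈ 16 cm), gradual
  rate `σ² = 0.0015` ln²-cm/Myr, jump rate 0.003 per lineage-Myr and jump
  variance 1.0 ln²-cm (≈ e-fold size shifts) — a handful of large jumps
  per tree, the regime the pulsed model describes.
- **Habitat**: ordered 3-state chain with direct marine ↔ continental
  rates structurally zero (terrestrialization only through marginal
  settings), root marine.
- **Curves**: smooth low-order harmonic series sampled at 1 Myr
  (temperature ~26 ± 3 °C; dissolved O₂ ~190 ± 25 µM with a slow rise),
  clipped to plausible bounds.
- **Community**: log-normal lengths (median ≈ 20 cm) over eight guilds in
  several assemblages.

What the generator does **not** emulate: preservation and collection
bias, stratigraphic clustering of sampling, correlated habitat-and-size
evolution, topological uncertainty, or measurement error in sizes.
Passing tests therefore demonstrate the correctness and statistical
calibration of the machinery under the stated generating processes, not
robustness to those real-data complications.

## Validation problem sizes

The validation suite checks likelihoods against independent oracles
(direct MVN constructions, exhaustive enumerations, truncated series,
Monte-Carlo and fine-step ODE integrations), the full set of nesting
identities, and simulation-based calibration. Calibration problem sizes
were chosen to give stable medians at practical runtimes on one CPU:
parameter recovery uses 12 simulate–refit replicates per model at 135
tips (2 restarts); pulsed-model recovery in the model-ranking check uses
10 replicate datasets against all 11 models; rjMCMC structure recovery
uses 20 runs of 8000 iterations at 100 tips on datasets simulated to
contain both marine and continental diversity; stochastic-map calibration
uses 20 000 maps against exhaustive enumeration; the ANOVA type-I rate
uses 1000 null datasets with 199 permutations each.

For the identifiability of each model's parameters at this scale:
`σ²` (BM/TREND), `μ` (TREND), `r` (EB), `Κ` (KAPPA), `θ` (OU, OUM per
regime) and `β` (ENV_OU) are recovered with small median bias. Documented
weakly identified quantities: `σ²` under EB (correlated with `r`; median
bias at the tolerance boundary), `α` generally (only its order of
magnitude is constrained), and the individual `λ_J`, `δ²` of the pulsed
model, which trade off along a variance-flux ridge — their product
`λ_J·δ²` is the well-identified quantity and is what recovery is measured
on.

## Known limitations

- The pulsed likelihood is deterministic but approximate beyond the
  stated merge tolerance; pathological parameter corners (thousands of
  expected jumps) are rejected rather than evaluated.
- Only the Gaussian (jump-normal) Levy kernel is implemented for the
  pulsed model; heavier-tailed jump kernels would need their own mixture
  or characteristic-function machinery.
- rjMCMC explores a 3-state structure space of a few thousand models;
  modal-structure estimates need enough iterations (8000+) to stabilize,
  and the full modal structure is noisier than the zero-pattern summary.
- No measurement-error term in the trait models; no multivariate traits;
  no Bayesian trait-model fitting; no covarion/hidden-state Mk models.
- PGLS assumes a single λ for all residuals; no phylogenetic ANOVA of the
  ecospace variables (the permutational test is non-phylogenetic by
  design, as a preliminary screen).
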