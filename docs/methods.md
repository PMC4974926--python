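# Methods

This note documents the statistical machinery, the synthetic-data
generator, and the design decisions taken where the underlying
workflow left genuine choices open.

## Piecewise SEM by d-separation

A candidate model is a DAG over site-level variables. Rather than
fitting a global covariance structure, the model is tested locally
through its *basis set*: for every unordered pair of non-adjacent
variables (X, Y) one independence claim X ⟂ Y | pa(X) ∪ pa(Y), ordered
lexicographically for reproducibility. For a DAG this conditioning set
always d-separates a non-adjacent pair, which the test suite verifies
exhaustively against a path-blocking oracle for all DAGs up to five
vertices. A model definition may override a derived conditioning set
claim-by-claim (`claim_overrides`), for audits against externally
published basis sets.

Each claim is tested with a Pearson partial correlation: x and y are
residualized on Z by ordinary least squares (with intercept) and the
residuals correlated; the two-sided p-value uses Student's t with
n − 2 − |Z| degrees of freedom. Complete cases only; degenerate
(zero-variance) inputs and n < |Z| + 3 raise typed errors rather than
returning NaN.

The claim p-values aggregate into Fisher's C = −2 Σ ln pᵢ, referred to
χ² with df = 2k. A saturated model (empty basis set) returns C = 0,
df = 0, p = 1 by convention and is flagged. A claim p-value of exactly
zero yields an infinite-C sentinel with a warning — the model is
decisively rejected, never silently dropped.

With 14 sites and the model structures used here, the basis-set claims
involve only the upstream (floral/environmental) variables — the
response is adjacent to all of them — so both candidate models can
pass the d-separation test while differing sharply in parsimony; the
AIC step does the discrimination.

### AIC on Fisher's C

Three formulas are available:

* `shipley`: AIC = C + 2K;
* `shipley_corrected` (default): AIC = C + 2K·n/(n − K − 1), the
  small-sample form;
* `as_printed`: AIC = 2 ln C + 2K, an audit option reproducing a
  formula that circulates in the applied literature. It is
  dimensionally inconsistent with the χ² scale of C, is undefined for
  C ≤ 0, and ignores n, which is why it is not the default.

K defaults to the number of edges (one parameter per path
coefficient). The alternative rule `edges_plus_variances` (one extra
parameter per variable) is available but not the default: at the study
scale of n = 14 the complete model then has K = 14 and the corrected
denominator n − K − 1 becomes non-positive, leaving the default AIC
undefined exactly where it is needed. ΔAIC support classes follow the
conventional 3/10 cut-points: < 3 substantial, ≤ 10 considerably less,
> 10 essentially none. Ties in ranking break lexicographically by
model name.

### Path coefficients and pruning

The coefficient of edge X → Y is the partial correlation of X and Y
given Y's other parents (a sole-parent edge is a plain Pearson r),
matching the estimator used for the independence claims so that the
fitted model and its test share one statistical currency. Pruning
removes edges with p above a threshold (optionally also requiring |r|
below a floor), but never edges on the model's keep-list — the
simplified model keeps the flower-richness and elevation arrows into
the response on suggestive-trend grounds even when non-significant.

## Floral and bee metrics

* **Flower density** per plant species = mean flowers per flowering
  individual × number of flowering individuals, with a direct-count
  mode for taxa whose individuals cannot be distinguished.
* **Temporal stability** = mean / sd of the weekly site totals
  (inverse coefficient of variation), sample (n−1) sd by default
  (configurable via `ddof`). A constant nonzero series returns an
  infinite-stability sentinel; an all-zero series is an error.
* **Rarefied richness** uses the exact hypergeometric expectation
  E[Sₙ] = Σᵢ [1 − C(N−Nᵢ, n)/C(N, n)], computed in log-space. The
  default depth is the minimum season total across sites — the largest
  depth every site supports.
* **Reproduction summaries** per (species, site): mean brood cells per
  nest (defined only where the species nested; absence is an explicit
  null, not zero), total cells and total nests (absence = 0). Species
  enter cross-species analyses only with ≥ 30 nests overall. For
  species provisioning a bare pollen mass instead of discrete cells,
  the occupied cavity length divided by a configurable length-per-cell
  constant (default 1.0, i.e. raw length) serves as the response; only
  relative comparisons enter the models.
* **Diet generalization** pools each species' pollen counts over
  individuals, then computes the rarefied degree (same analytic
  expectation as floral rarefaction) and rarefied inverse Simpson
  diversity 1/Σpᵢ², Monte-Carlo over multivariate-hypergeometric
  subsamples (no simple closed form exists); the Monte-Carlo standard
  error is reported alongside. Inverse Simpson was chosen over
  Gini–Simpson so that both indices share the "effective number of
  plant species" scale, making rarefied_simpson ≤ rarefied_degree.
  Depth defaults to the minimum pooled grain total across the species
  compared.

## Meta-analysis

Per-species coefficients r (from N sites) are combined as
z = atanh(r), weighted by w = N − 3 (the inverse sampling variance of
z), and averaged: z_w = Σwᵢzᵢ / Σwᵢ. The 95% interval is a percentile
bootstrap: species (z, w) pairs resampled with replacement B = 100,000
times, interval = 2.5th/97.5th percentiles of the resampled weighted
means. Percentile (not BCa) limits and resampling of (z, w) pairs are
deliberate: they are the simplest scheme consistent with weighting at
the species level. N per species is the number of sites actually
contributing to that species' coefficient (≤ 14 for the mean-cells
response, which is undefined where the species is absent).

Spearman correlations between the richness effect and generalization
use average ranks; for N ≤ 9 the two-sided p-value is exact (all N!
permutations enumerated, 5,040 at the study's N = 7), otherwise the t
approximation.

## The synthetic generator

The generator emulates the sampling structure of a trap-nest study on
an arid elevation gradient: 14 sites at 1,100–1,500 m, an 8-week
flowering season, 7 focal bee species, 15 plant species.

Site variables follow a standardized linear Gaussian causal system:
walking the DAG in topological order, each variable is the configured
linear combination of its parents plus Gaussian noise whose variance
is calibrated (via the implied covariance) so every variable has unit
marginal variance; configured coefficients are therefore standardized
effects, and an implied R² ≥ 1 is rejected as infeasible. Elevation
and fire age are uniform on their ranges and standardized by their
theoretical moments. Default effect sizes mirror the field estimates
(e.g. elevation → richness +0.39, richness → stability −0.54,
elevation → total cells −0.59); effects on the mean-cells response,
for which no community-level estimates exist, were set once to
moderate values with the observed signs (stability −0.30, richness
+0.15, elevation −0.20).

Natural scales are affine maps of the standardized draws (richness
mean 8 ± 1.8 species, abundance 2,000 ± 450 flowers/week, stability
2.5 ± 0.5), floored far in the tails so the maps are effectively
affine and partial correlations are unaffected. Weekly totals split a
site's seasonal flower total by a symmetric Dirichlet whose
concentration is tuned to the site's target CV (stability = 1/CV),
then spread over the plant species present (their number tracks the
richness draw) multinomially. The weekly *shape* is nuisance: the
realized inverse CV estimated from 8 weekly points is noisy and
Jensen-biased upward relative to the target, so target and realized
stability agree in rank only moderately (ρ ≈ 0.5–0.6); the modeled
quantity is the site-level stability variable itself.

Counts: nests per (species, site) are Poisson with log-rate = log
(4 nests) + a fixed per-species effect (sd 0.3) + 0.5 × the latent
total-nests driver; brood cells per nest are 1 + Poisson with a
log-mean shifted by the latent mean-cells driver. Pollen loads are
multinomial (≈ 300 grains/individual, one individual per nest, capped
at 40 per species) over a per-species Dirichlet diet whose
concentration rises geometrically from 0.08 to 2.0 across the species
list — a specialist → generalist gradient the rarefied indices should
recover. Poisson (rather than negative binomial) counts are the
default because the analysis layer never exploits overdispersion; the
distributions are configurable.

What passing tests on these data do **not** show about real data:
count layers are conditionally Poisson (real nest counts are often
overdispersed and zero-inflated), diets are stationary across sites,
weekly phenology has no autocorrelation, and all causal effects are
linear on the standardized scale. The generator validates the
machinery, not the field conclusions.

## Numerical and reproducibility choices

* Rarefaction ratios via log-gamma; binomials with N−Nᵢ < n contribute
  probability 0 exactly.
* Partial correlations clip to [−1, 1]; |r| = 1 returns p = 0.
* All randomness flows through `numpy.random.default_rng` seeds;
  bootstrap and Monte-Carlo results are bit-reproducible given the
  seed, and the pipeline writes a manifest (config hash, seed,
  version) sufficient to re-run byte-identically.
* CSV numerics are parsed with Python's `float` (correctly-rounded
  strtod) rather than pandas' fast parser, so write→read round-trips
  are exact.
* Problem sizes in the test suite: exhaustive DAG checks to five
  vertices; rarefaction enumeration to N = 8; 1,000 replicates for the
  type-I-error calibration at 50 sites; 5,000 sites for parameter
  recovery; B = 10⁵ bootstrap replicates. These sizes give Monte-Carlo
  noise comfortably below the assertion tolerances.

## Known limitations

* Fisher's C treats basis-set p-values as independent; with claims
  sharing data they are not, though calibration holds empirically here
  (type-I error ≈ 0.04–0.06 at the tested structures).
* No mixed models, latent variables, or non-Gaussian independence
  tests; responses enter the site-level models as totals or means, not
  through the count likelihoods that generated them.
* Partial-correlation path coefficients coincide with standardized
  regression slopes only when the effect's parents are uncorrelated;
  the parameter-recovery tests therefore target the model-implied
  partial correlations, which is what the estimator estimates.
* The exact Spearman p-value enumerates N! permutations and is capped
  at N = 9.
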