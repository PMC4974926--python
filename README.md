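# beesem

Piecewise structural equation modelling of solitary-bee reproduction
along environmental gradients: d-separation tests, AIC model selection,
cross-species bootstrap meta-analysis and rarefied diversity metrics,
with a synthetic-data generator that emulates a trap-nest field study.

## The problem

Cavity-nesting solitary bees provision each brood cell with pollen, so
their reproductive output (brood cells per nest, total cells and nests
per site) should respond to the floral resources around the nest: how
many flowers there are, how many plant species produce them, and how
steadily they are produced over the season. But floral diversity,
abundance and temporal stability all covary with elevation and
disturbance history, so a causal question — *does flower diversity
itself improve bee reproduction?* — cannot be answered with pairwise
correlations. This package implements the piecewise (local-estimation)
SEM workflow used for exactly this situation at small sample sizes
(a dozen-odd sites):

1. **Candidate causal models** are DAGs over site-level variables
   (elevation, years since fire, flower abundance, rarefied flower
   richness, temporal stability, and a reproduction response).
2. **d-separation test.** Every pair of non-adjacent variables must be
   conditionally independent given the union of both variables'
   parents (the *basis set*). Each claim is tested with the p-value of
   a Pearson partial correlation; the claims aggregate into Fisher's

   C = −2 Σᵢ ln *pᵢ*,

   which is χ²-distributed with 2*k* degrees of freedom (*k* claims)
   when the model is correct. A *large* p-value means the model's
   independence structure is consistent with the data.
3. **Model selection** by AIC built on C (small-sample corrected form
   `C + 2K·n/(n−K−1)` by default), with ΔAIC support classes
   (< 3 substantial, ≤ 10 considerably less, > 10 essentially none).
4. **Path coefficients.** Each retained edge X → Y is a standardized
   partial correlation of X and Y controlling for Y's other parents.
5. **Cross-species meta-analysis.** A path estimated per bee species is
   pooled on the Fisher z scale (z = 0.5 ln[(1+r)/(1−r)]) with
   inverse-variance weights w = N − 3 and a 100,000-replicate
   percentile bootstrap over species for the 95% interval.
6. **Diet generalization.** Pollen loads give each species a rarefied
   diet degree (analytic hypergeometric expectation) and rarefied
   inverse Simpson diversity (Monte-Carlo); Spearman rank correlations
   (exact permutation p for small N) relate these to the
   flower-richness effect on reproduction.

Because real trap-nest data sets are rarely redistributable, the
`synthetic_data` module is a first-class component: it draws site
variables from a standardized linear Gaussian causal system (effect
sizes defaulting to those observed in the field study the package
models), layers Poisson nest counts, shifted-Poisson brood cells and
multinomial pollen loads on top, and writes the same three CSV schemas
the I/O layer reads.

## Worked example

`examples/02_dsep_model_test.py` draws a 14-site synthetic gradient and
tests the two candidate models for the community total-brood-cells
response:

```
Simplified-model basis set:
  elevation _||_ stability | {'flower_richness'}

model1:total_cells: C = 11.953, df = 14, p = 0.610  (fits: claims not rejected)

model2:total_cells: C = 0.051, df = 2, p = 0.975  (fits: claims not rejected)

AIC ranking (small-sample corrected):
  model2:total_cells: AIC = 17.55, dAIC = 0.00 (support: substantial)
  model1:total_cells: AIC = 56.75, dAIC = 39.20 (support: none)

Path coefficients of the simplified model (partial r controlling for co-parents):
  elevation -> flower_richness: r = +0.725, p = 0.003
  flower_richness -> stability: r = -0.633, p = 0.015
  elevation -> total_cells: r = -0.705, p = 0.011
  flower_richness -> total_cells: r = +0.127, p = 0.694
  stability -> total_cells: r = +0.308, p = 0.331
```

Both models pass the d-separation test (p > 0.05: no claimed
independence is violated), but the simplified model wins decisively on
ΔAIC. The path coefficients then quantify each arrow: here elevation
raises flower richness (+0.73), richness lowers week-to-week stability
(−0.63), and elevation depresses total brood cells (−0.71) — the
richness and stability arrows to reproduction are weak for this draw.

The other examples cover floral metrics and rarefaction (`01`), the
weighted bootstrap meta-analysis (`03`), diet generalization (`04`) and
the full pipeline with its report bundle (`05`). The same pipeline is
scriptable from a shell:

```sh
beesem simulate --seed 3 --out data/
beesem report --config run.yaml --seed 3
```

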