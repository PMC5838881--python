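# Methods

## The model

`pairlim` tests, for every gene–metabolite pair, whether the linear
relationship between log2 gene expression *g* and log2 metabolite abundance
*m* differs between two phenotype groups. For each pair it fits by ordinary
least squares

    m = β₁ + β₂·g + β₃·p + β₄·(g×p) + ε,    ε ~ N(0, σ²)

where *p* is the phenotype encoded 0/1 (the reference level is 0). β₂ is the
gene→metabolite slope in the reference group, β₃ a phenotype main effect, and
β₄ — the interaction — the *difference in slope* between the two groups. A
two-tailed t-test on β₄ (t = β₄/se(β₄), df = n − k with k model columns) is
the core inference; a small p-value means the association is
phenotype-specific. Raw p-values across all pairs are adjusted with the
Benjamini–Hochberg step-up procedure.

Assumptions: independent samples, Gaussian homoscedastic residuals within the
model (one pooled σ² across both groups), a linear gene–metabolite
relationship on the log2 scale, and a strictly two-level phenotype. Paired or
repeated-measures designs, continuous phenotypes and >2 groups are out of
scope. Covariates may be appended as main-effect columns only.

### Effect size

The interaction p-value measures evidence, not magnitude. As an effect size
we use the difference in within-group Spearman rank correlations,
Δr = r(group 1) − r(group 0), each computed with average ranks on
pairwise-complete observations. Δr ∈ [−2, 2]; |Δr| > 0.5 is the default
secondary filter, and significance requires **both** BH-adjusted p <
`fdr_cutoff` and |Δr| > `min_abs_delta_r`, with strict inequalities. A
group's r is undefined (missing) with fewer than 3 paired observations or a
constant vector, and such pairs never pass the filter.

Because the phenotype encoding fixes the sign of both β₄ and Δr, and public
datasets rarely state their encoding, the reference level is an explicit
argument (default: lexicographically first level). Swapping the encoding
negates β₄ and Δr but leaves |t|, p-values and |Δr| unchanged.

## Batch solver

With ~10⁴ genes and hundreds of metabolites the pair universe reaches
millions of models (16,188 × 220 = 3,561,360; 18,228 × 379 = 6,908,412). The
solver iterates over genes: each gene's n×k design (intercept, g, p, g·p,
covariates) is factored once by thin SVD and solved against **all**
metabolite responses simultaneously as a multi-right-hand-side
least-squares problem. Per-response residual sums of squares give σ̂²;
se(β₄)² = σ̂² · [(XᵀX)⁻¹]₄₄ comes from the SVD
((XᵀX)⁻¹ = V S⁻² Vᵀ). This reproduces per-pair OLS exactly (cross-checked to
1e-8 on coefficients and 1e-10 on p-values against an independent
`numpy.linalg.lstsq`-based single-model path,
`interaction_pvalue_reference`) and fits the full 3.6M- and 6.9M-pair
universes in well under a minute each on one CPU.

Numerical edge cases are flagged, never fabricated:

- **Rank deficiency** (e.g. a constant gene): relative condition cutoff
  1e-10 on the design's singular values → flag `degenerate`, statistics NaN.
- **Zero residual variance** (exact linear fit): SSR ≤ 1e-12 × max(Σm², 1) →
  flag `zero_residual`, coefficients reported, p NaN.
- **Missing metabolite values**: complete-case per pair. Metabolites fully
  observed over a gene's retained samples share the batched solve; the rest
  fall back to the reference path with per-pair df. Pairs with fewer than
  k + 2 samples, or with an empty phenotype group after dropping, are
  flagged `insufficient_samples`. Each group must have at least
  `min_group_size` samples (default 4) for the fit stage to run at all.
- **BH with missing p**: flagged pairs are excluded from the family size m
  and stay missing after adjustment.

## Preprocessing filters

Implemented as pure row-subset operations (survivors are bitwise-identical
to input rows) with conserved counts reported per stage:

- **Replicate CV filter** (metabolites, raw scale): CV = sd/mean (sample sd,
  n−1) within each biological sample's technical replicates; per-metabolite
  summary = median CV across samples; median CV ≥ 0.3 (default) removes the
  metabolite. The comparison direction is exposed as a flag
  (`remove_high=False` inverts it). Groups with <2 non-missing replicates or
  zero mean contribute no CV; metabolites with no defined CV are retained
  with a warning. CV is computed pre-log because it is scale-dependent and
  conventionally reported on the raw scale.
- **log2 transform** then **replicate averaging** (arithmetic mean per cell,
  missing excluded), in that order.
- **Imputed-count estimation**: metabolomics pipelines impute a metabolite's
  missing values by its observed minimum, so (#samples exactly at the
  minimum) − 1 estimates the imputed count. Equality is exact at stored
  precision — minimum imputation writes identical values, and an epsilon
  would create false positives. Features with imputed fraction strictly
  greater than 0.80 (default) are removed.
- **Probe collapse**: many-to-one probe→gene maps are reduced to the probe
  with the highest mean expression; ties go to the lexicographically
  smallest probe ID (determinism; the choice is otherwise arbitrary).
- **Low-expression filter**: the ⌊fraction × n⌋ lowest-mean genes are
  removed (default 10%); ties at the cut are resolved by lexicographic ID,
  lower IDs removed first. Floor never removes more than requested.

## Clustering and visualization

Significant pairs are clustered on their 2-column signature
(r_group0, r_group1) by agglomerative hierarchical clustering with Euclidean
distance and complete linkage (scipy). Heatmap rows follow the dendrogram
leaf order. Cluster labels come from cutting into k clusters (default k = 2,
matching the typical correlated/anti-correlated split; there is no automatic
k selection — the cut is a documented convention, not an inference). Volcano
plots show Δr against −log10 of the BH-adjusted p, with adjusted p = 0
clamped to the smallest positive float and flagged.

## Synthetic data generator

`pairlim.simulate.generate` realizes the model generatively so that every
stage — and the statistical calibration of the test — can be verified
without external data:

- log2 gene levels ~ N(μᵢ, 1) with per-gene means μᵢ ~ U(4, 12), mimicking
  log2 microarray intensities; genes are mutually independent.
- Each metabolite is a linear response with intercept ~ U(8, 14) and
  Gaussian residual noise (`noise_sd`, default 0.5). Designated interacting
  pairs contribute `baseline_slope`·g + `beta4_magnitude`·g·p; metabolites
  with no interacting gene get the baseline slope through one random
  "anchor" gene, so plain (non-phenotype-specific) associations exist too.
- Interacting genes are assigned to metabolites as evenly as possible
  (round-robin over a shuffled metabolite list). With a random assignment,
  two interacting genes landing on the same metabolite would each act as a
  large extra residual-variance term for the other's pair, coupling
  per-pair power to the assignment draw.
- Raw materials for preprocessing: technical replicate columns =
  2^(log2 value + N(0, `replicate_noise_sd`)); redundant probes = gene value
  plus a per-probe constant offset; minimum imputation floors
  round(`imputed_fraction`·n) cells per metabolite (never the realized
  minimum itself) to the minimum value, so the post-hoc estimator recovers
  the planted count exactly.
- Everything is drawn from one `numpy` Generator seeded by `spec.seed`;
  identical specs are bit-identical.

Default study conditions are two groups of 12 samples and a 200 × 50 pair
universe (10⁴ pairs), which keeps Monte-Carlo checks fast while giving
binomial standard errors of ~0.002 at α = 0.05. The signal-recovery
scenario uses `fraction_interacting = 0.005` (50 pairs, one per metabolite),
`beta4_magnitude = 2`, `baseline_slope = −1` and `noise_sd = 0.5`: per-group
slopes are then ∓1, so residual variance is phenotype-independent for every
pair (the model's homoscedasticity assumption holds exactly, which BH's FDR
guarantee relies on), the analytic interaction t is ≈ 9 (power ≈ 1), and the
true |Δr| ≈ 1.9. Pair-enumeration checks use the published matrix shapes
(16,188 × 220 with groups of 6 + 14; 18,228 × 379 with 47 + 61).

What the generator does **not** emulate: real marginal distributions,
gene–gene and metabolite–metabolite correlation structure, heavy-tailed or
heteroscedastic noise, batch effects, and non-linear relationships. Passing
tests therefore demonstrate correctness of the computation and calibration
under the stated model, not robustness of the inference on real data.

## Numerical choices

- Spearman r is computed as the Pearson correlation of average ranks; the
  vectorized all-pairs path (rank, center, L2-normalize, matrix product) is
  used for complete rows and checked against `scipy.stats.spearmanr`.
- CSVs are written with shortest round-trip float representation and read
  with `float_precision="round_trip"`, so read(write(X)) == X exactly.
- Filtering uses strict inequalities on both cutoffs; boundary rows are
  excluded deterministically.
- All randomness in the pipeline flows through one seeded generator recorded
  in the run manifest; re-running a config on the same inputs is
  bit-identical.

## Known limitations

- Two-level phenotypes only; the interaction test is not extended to
  continuous or multi-level phenotypes.
- The pooled-variance t-test is exact under within-model homoscedasticity;
  strong group-wise heteroscedasticity with unbalanced groups will distort
  its calibration (as for any standard OLS interaction test).
- The k = 2 dendrogram cut is a convention for summarizing the signature
  heatmap, not a model-based cluster count.
- Normalization (e.g. array summarization, metabolomics batch scaling) is
  upstream of this package: inputs are expected normalized and, after the
  optional log2 stage, log2-scaled.
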