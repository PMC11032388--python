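# Methods

This note documents the statistical models behind `triomix`, the
parameters that matter, what the synthetic-data generator does and does
not emulate, and the numerical choices made where the design was open.

## Differential expression

Counts are modelled as negative binomial,
`count_ij ~ NB(mean = s_j * q_i, Var = mu + alpha_i * mu^2)`.

* **Prefilter.** Features with total count across all samples below 10
  are removed before any statistics (kept iff row sum ≥ 10).
* **Size factors** are classical median-of-ratios: per sample, the
  median over reference features (positive in every sample) of
  `count / geometric mean`. There is no pseudo-reference fallback; a
  matrix with no all-positive feature is an error. Note that scaling one
  sample by `c` moves its factor by exactly `c` *relative to the other
  samples*; because the geometric-mean reference includes the scaled
  sample, all factors also pick up a common `c^(1/n)` which cancels in
  every downstream ratio.
* **Dispersion** `alpha_i` is a per-feature method-of-moments estimate
  pooled across the two groups (`Var = mu + alpha*mu^2` solved from
  within-group means and variances of normalised counts), floored at
  1e-8. There is no empirical-Bayes trend sharing: at desk scale the
  per-feature estimate is sufficient, and the BH step at the end is what
  the calibration tests actually certify.
* **Wald test.** `log2FC = log2((mu_T + 0.5)/(mu_C + 0.5))` with the 0.5
  pseudo-count applied only in the ratio, never in the likelihood
  moments. The standard error comes from the delta method,
  `SE^2 = [v_T/(mu_T+0.5)^2 + v_C/(mu_C+0.5)^2] / ln(2)^2` with
  `v_g = (mu_g + alpha*mu_g^2)/n_g`; z = log2FC/SE is referred to a
  standard normal, two-sided. A feature with identical group means gets
  log2FC exactly 0; a degenerate feature with zero SE gets p = 1.
* **No fold-change shrinkage.** Shrunken estimators (apeglm-style) are a
  separate estimator family; downstream integration consumes only signed
  fold changes and significance calls, so raw ratios are reported.
* **BH adjustment** is the step-up rule
  `padj_(i) = min_{j>=i}(m * p_(j) / j)`, capped at 1, with a final
  elementwise `max(padj, p)` guarding the `padj >= p` invariant against
  one-ulp float rounding at subnormal p-values.

The raw Wald p-values are mildly anticonservative at n = 8 per group
(~7% below 0.05 under the null); the significance contract is at the
BH-adjusted level, where the null simulation rejects far below the
nominal 5%.

## Differential methylation

* Site tests are Welch's t on M-values (`log2(beta/(1-beta))`), with
  Satterthwaite degrees of freedom and a 1e-12 variance floor (floored
  sites are logged). Betas are clipped into [0.001, 0.999] at import.
* Islands aggregate member CpGs (coordinate containment, half-open) as
  `quotient = (mean_site mean_beta_T + eps) / (mean_site mean_beta_C + eps)`,
  `eps = 0.01` guarding near-zero denominators (configurable). The
  ratio-of-means form is used rather than mean-of-ratios; both are
  defensible, this one is stable when single sites approach 0.
* Island p-values combine member sites with Fisher's method
  (`-2 * sum(ln p) ~ chi2(2k)`), BH across islands. Fisher assumes
  independent sites, which is false for neighbouring CpGs in real
  arrays; at desk scale the synthetic generator draws sites
  independently, so the combination is exactly calibrated there. A
  Stouffer option is exposed for users worried about single-site
  outliers dominating.
* Promoters are `[TSS-1500, TSS+500)` on the plus strand and the mirror
  image for minus-strand genes, clipped at zero. Island-to-gene
  assignment requires an overlap of at least 1 base (configurable).

## miRNA–target pairs

Candidate pairs require validated interaction evidence and significance
of both members. Spearman ρ is computed on `log2(normalised count + 1)`
over the pooled tumour+control samples (the log is cosmetic for a rank
statistic; pooling is the default because the correlation is meant to
capture the regulatory dose-response across the whole cohort, and a
13-sample-scale design cannot afford tumour-only correlation).
Reduction keeps, per gene, the pair with maximal |ρ|; ties break by
smaller p, then lexicographic miRNA id, making the output deterministic.
No sign constraint is applied: positively correlated pairs are retained
and show up as noncanonical regulation downstream.

## Integration, clustering, exclusivity

* The integrated table has one row per significant DEG; the island is
  the lowest-p significant DM island among those overlapping the gene's
  promoter (ties: larger |log2 quotient|, then id), the miRNA comes from
  pair reduction. Class labels follow from field presence and always
  partition the DEGs.
* The cluster matrix has three channels: gene log2FC, partner miRNA
  log2FC, island log2 quotient. Fold changes are already logarithmic
  and enter as-is; only the methylation quotient is log2-transformed
  (double-logging a signed log fold change is undefined). A missing
  modality is imputed as 0 = "no measured epigenetic change" before
  z-scoring each channel (complete-case clustering is available via
  config).
* k-means is Lloyd's algorithm with initial centres drawn uniformly
  among data points, best of 100 restarts by within-SS (the classic
  `nstart` semantics), over k = 8..12. The "best" k is the one with
  maximal mean silhouette; the criterion is reported per k and a fixed
  k can be forced. Silhouette was chosen because it needs no ground
  truth and penalises both over- and under-splitting; nothing downstream
  depends on the specific k.
* Per cluster, dominance = `|m| / (|m| + |q|)` where m and q are the
  cluster means of the scaled miRNA and methylation channels; when both
  magnitudes are below 0.05 the cluster is "silent" and gets 0.5 by
  convention. The global exclusivity index is the gene-weighted fraction
  of clusters with dominance outside [0.25, 0.75] (θ = 0.25, a symmetric
  band around equal contribution; sensitivity exposed in the CLI). The
  index is invariant to gene order and cluster relabelling.

## Enrichment

Hypergeometric upper tail `P(X >= k)`, summed in log-space for
stability, per GMT term against a user-supplied background; the default
background in the pipeline is all genes retained after prefiltering
(the proper universe for a synthetic cohort), not all annotated human
genes. BH is used across terms; empirically tailored corrections from
web services are deliberately not reproduced. Sets smaller than 3 after
background intersection are skipped.

## Synthetic cohorts

The generator states a world and the tests measure the pipeline against
it. Defaults: 1000 genes, 100 miRNAs, 600 CpG islands of 10 CpGs, 8 vs 8
samples, the four regulatory classes at 0.25 each, |log2FC| = 2 for
planted genes and miRNAs, beta shift 0.3 (0.3 → 0.6 for hypermethylated
islands), NB dispersion 0.1, size factors log-uniform in [0.7, 1.4],
Beta precision 50, 10% noncanonical couplings, decoy fraction 0.5.

* **Geometry** is deterministic: genes every 10 kb on one chromosome,
  random strand; each DM/BOTH gene's island sits centred inside its
  promoter window, background islands in intergenic space; an O(n²)
  brute-force containment check runs on every build.
* **Canonical direction convention:** miRNA up ⇒ gene down; promoter
  hypermethylation ⇒ gene down. Noncanonical couplings flip the sign.
* **Latent miRNA activity.** Each miRNA carries a per-sample log2-normal
  activity deviation (SD 0.75) that is added to its own mean and, with
  opposite sign for canonical couplings, to its target gene's mean. This
  term is what makes a true partner statistically distinguishable from a
  decoy: without it every differentially expressed miRNA correlates with
  every DEG through the shared group effect and max-|ρ| reduction would
  be a coin flip. The SD was anchored to the |ρ| ≈ 0.8 magnitude that
  strong validated pairs show in published cohorts of this size; larger
  values inflate miRNA within-group variance enough to cost DE power at
  8 vs 8.
* **Decoy interactions** are validated rows that exercise the filters
  without changing planted classes: significant-miRNA decoys target only
  MIR/BOTH genes (stress-testing reduction), unaffected-miRNA decoys
  target arbitrary genes (stress-testing the significance filter), and a
  further 10% of rows carry `predicted` evidence and must be discarded
  by the evidence filter. Decoys to DM/NONE genes are excluded by
  design: under presence-based classification they would *be* true
  miRNA associations and change the planted label.
* **Not emulated:** array probe design and probe-level artefacts,
  correlated neighbouring CpGs, batch effects, tumour purity/stromal
  contamination, a mean–dispersion trend, multi-factor designs and
  HPV-stratified effects. A green recovery test therefore establishes
  that the pipeline's logic and statistics are correct under its own
  model assumptions — not that those assumptions hold on any particular
  real dataset.

## Determinism

All randomness flows from one config seed through tagged
`numpy.random.default_rng([seed, tag, ...])` streams: truth, geometry,
counts per layer, methylation, metadata, interactions and gene sets are
independent streams, so regenerating a cohort is byte-identical and
replicate cohorts (different `seed_offset`) share the same truth.
The pipeline derives per-stage seeds from its root seed
(`seed * 1000003 + stage`, mod 2^31) so stages can be rerun alone.

## Known limitations

* The Wald test's raw p-values are slightly liberal at very small n;
  conclusions should be drawn at the FDR-adjusted level.
* Fisher's combination over-weights islands with many CpGs when sites
  are positively correlated, as they are on real arrays.
* The exclusivity index depends on the clustering resolution: at very
  small k, mixed clusters pull the index down regardless of the
  underlying architecture. The per-cluster dominance scores are reported
  so this is visible.
* Pair reduction keeps exactly one miRNA per gene; genuinely
  multi-miRNA regulation is represented only by its strongest partner.
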