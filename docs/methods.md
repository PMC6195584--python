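# Methods

This note documents the statistical models behind `nutriomics`, the choices
made where the design was genuinely open, and what the synthetic-data tests
do and do not establish about real data.

## Study design emulated

The pipeline targets a three-condition, four-replicate cell-culture design:
unstimulated endothelial cells (`control`), TNFα-stimulated cells (`TNF`),
and cells pre-exposed to a mixture of epicatechin metabolites before TNFα
stimulation (`ECMIX_TNF`). Two contrasts matter: `TNF_vs_control` (the
inflammatory programme) and `ECMIX_vs_TNF` (the metabolite effect on the
inflamed state). Three molecular layers are measured on the same samples:
gene expression (two-colour array, log2 scale), mature-miRNA expression
(866 features, log2 scale), and CpG methylation (450K-style beta values).

## Differential analysis (expression and miRNA layers)

Per feature, a pooled-variance two-sample Student t-test:

t = (x̄_B − x̄_A) / √(s_p² (1/n_A + 1/n_B)),  df = n_A + n_B − 2,

with two-sided p-values and Benjamini–Hochberg step-up adjustment across
features. Significance is `p_adj < α` with α = 0.01 for genes and α = 0.05
for miRNAs (both configurable); direction is the sign of the mean
difference. The equal-variance form (not Welch) is deliberate and
configurable only through the code, since the emulated design has equal
group sizes and a shared noise model.

Normalization: two-colour data can be lowess-normalized on the MA plane
(M = log2 R/G regressed on A = ½ log2 RG, span 0.3, 2 robustness
iterations; the residual M − fit(A) is returned). The miRNA layer is scaled
by subtracting each sample's 75th percentile, computed with linear
interpolation between order statistics — percentile conventions differ
between tools, so the rule is fixed and tested. An optional minimum-SD
filter (default 1e−8) drops essentially constant features before testing.

**Power at the defaults.** With 4 replicates and log2 noise SD 0.25, a
planted |log2 FC| = 2 gives a t noncentrality of ≈ 11.3 at df = 6, so the
BH-1% call recovers ≈ 90% of planted genes and the pipeline produces an
outcome on the scale of the emulated study (hundreds of significant genes).
A noise SD of 0.5 halves the noncentrality to ≈ 5.7; at that level the
*test-wise* 1% power is 0.92 but BH-adjusted calls at 1% across thousands
of features recover only ~25% of planted genes — an unavoidable consequence
of df = 6 noncentral-t dispersion plus step-up multiplicity, not an
implementation artifact. The recovery tests therefore check detection power
at the test's 1% level and FDR control at the adjusted level as two
separate properties.

## miRNA-target consensus

A prediction table stores, per (miRNA, gene) pair, how many of nine
prediction algorithms report the pair (0–9). The consensus target set of a
miRNA list is the union over queried miRNAs of genes with support ≥ 5
(configurable in [1, 9]); the threshold is evaluated per pair, and the
union (not intersection) across miRNAs matches the pooled per-condition
target list the pipeline reports. Raising the threshold can only shrink
the set; the union decomposes over query partitions. Both properties are
tested, along with precision/recall ≥ 0.95 on simulated tables
(sensitivity 0.9, false-positive rate 0.01 per algorithm: a false pair
needs 5 of 9 independent rare events, probability ≈ 1e−8).

## Methylation layer

### Probe QC

A probe is removed when its detection p-value exceeds 0.01 in *any* sample
(the conservative aggregation; the vendor-style rule is ambiguous), when a
SNP overlaps the last 3 bases of its probe sequence, or when any beta value
is missing. Removal counts are reported per criterion and the filter is
idempotent.

### BMIQ between-design normalization

Infinium type I and type II chemistries produce systematically different
beta distributions (type II modes compressed toward 0.5). Per sample, a
three-state beta mixture (unmethylated / intermediate / methylated) is
fitted separately to each design by EM:

- initialization: hard split at β = 0.25 / 0.75;
- E-step: posterior responsibilities under the current weights/shapes;
- M-step: weights by mean responsibility, shapes by weighted moment
  matching (shapes bounded ≥ 1e−2);
- convergence at log-likelihood improvement < 1e−5, at most 200 iterations
  (non-convergence returns the last iterate with a warning flag).

Type II probes are assigned to states by maximum posterior. U- and M-state
values are quantile-mapped onto the corresponding type I component
(x → CDF under the type II component → inverse CDF under the type I
component); intermediate values are linearly dilated between the
transformed state boundaries. Type I values are returned bit-identical,
the mapping is monotone within each state, and on synthetic data the KS
distance between the design-type distributions drops by an order of
magnitude (≈ 0.45 → ≈ 0.03). Degenerate situations (an empty state, or
collapsed anchors) fall back to the identity for the affected values with
a logged warning.

### Empirical-Bayes moderated testing

Per-probe residual variances s² (df = n_A + n_B − 2) are shrunk toward a
common prior. With e = log s² − ψ(df/2) + log(df/2), the prior degrees of
freedom d₀ solve ψ′(d₀/2) = var(e) − ψ′(df/2) (Newton inversion of the
trigamma function, 50 iterations, tolerance 1e−8; d₀ > 1e6 is reported as
infinite), and s₀² = exp(mean(e) + ψ(d₀/2) − log(d₀/2)). Posterior
variances are s²_post = (d₀s₀² + df·s²)/(d₀ + df) and the moderated t
statistic t = Δβ/√(s²_post(1/n_A + 1/n_B)) is referred to a t distribution
with df + d₀ degrees of freedom. For (near-)constant input variances the
estimator's log-scale bias offset would overcorrect, so the infinite-d₀
branch uses the geometric mean, making the degenerate case exact. On 5000
variances simulated from the model (d₀ = 4, s₀² = 0.01) the estimates land
within 20% / 10%.

Testing runs on beta values by default (Δβ is the directly interpretable
effect); logit2 (M-value) testing is available via `use_mvalues` but off by
default.

### DMPs and DMRs

A DMP is a probe with BH-adjusted p < 0.1 **and** |Δβ| ≥ 0.10 (hypo/hyper
by the sign of Δβ; the 0.099 case is excluded — the Δβ rule is a ≥ bound).
DMR candidates are maximal runs of probes on one chromosome with
inter-probe gaps ≤ 1000 bp (probes sorted by chrom, pos, probe-ID
tie-break). Each candidate combines its member p-values by Stouffer's
method with equal weights, converting two-sided p to signed z via the Δβ
sign so coherent shifts reinforce and opposed shifts cancel. BH runs across
all candidates; a region is reported when FDR < 0.05, it has ≥ 3 probes,
and its peak |Δβ| > 0.10. This is a deliberately simpler combiner than a
kernel-smoothed region statistic; it satisfies the same acceptance rules
(probe count, region FDR, peak effect) and is exactly testable. Coordinates
are 1-based inclusive internally; BED export is 0-based half-open.

## Over-representation analysis

For a query of n features from a universe of N, a set with K members in
the universe and k in the query scores P(X ≥ k) under
hypergeometric(N, K, n) — one-sided upper tail only, since the question is
over-representation. BH adjustment runs across sets within one collection
and one query; ranking is by raw p with name tie-break. The universe is
always the set of features *measured on the layer after QC*, never the
whole genome — the only universe constructible from the pipeline's inputs
and standard ORA practice. The same machinery tests DMP enrichment in
gene-region and CpG-island categories against the filtered probe universe.

## Integration

Gene-level sets (ECMIX DEGs, DMP genes, consensus target genes) and
pathway-level top-K lists (default K = 40, by raw p) are intersected; all
2^m − 1 Venn regions are reported with the underlying sets so the counts
can be reconciled (regions sum to the union — an invariant the tests
recompute). Percentages are stored at full precision with a one-decimal
display value. The DMP–miRNA comparison extracts miRNA host-gene symbols
(prefix `MIR`, configurable) from DMP-mapped genes and intersects them with
the DE miRNA list. Pathway identity is exact name match. The report
serializes to canonical JSON (sorted keys); serialize → parse → serialize
is byte-identical, which is also how end-to-end determinism is asserted.

## Synthetic-data generator

The generator is first-class, tested code. What it emulates, per layer:

- **Expression** — per-gene baselines N(7, 1.5²), i.i.d. Gaussian log2
  noise (SD 0.25). Planted TNF-responsive genes (1000 of 10,000) shift by
  ±2 log2 units in both TNF-containing arms; planted ECMIX-responsive genes
  (253) shift in the ECMIX arm only. 66 of the 253 are shared with the TNF
  set and 44 of those flip sign, mirroring the emulated study's partial
  counteraction of the inflammatory programme.
- **miRNA** — 866 features; 19 TNF-responsive (all up), 20 ECMIX-responsive
  (19 down), 2 shared with opposite direction; per-sample log2 offsets
  (SD 0.5) make 75th-percentile scaling consequential.
- **Methylation** — 20,000 probes in clusters of 3–8 (gap 200 bp inside,
  10 kb between, six synthetic chromosomes). Methylation state
  (unmethylated/intermediate/methylated, weights 0.45/0.10/0.45) is drawn
  per *cluster* — CpG-island-like coherence, which also makes planted
  region shifts directionally coherent. Beta values are logit-normal around
  state centers (0.1/0.5/0.9 for type I; pulled toward 0.5 by factor 0.75
  for type II; 28% type I); logit noise SD 0.15 ≈ 0.04 beta-scale SD at
  mid-range. 300 DMPs (Δβ = 0.2) and 10 five-probe DMRs (Δβ = 0.3) are
  planted in the ECMIX arm, always shifting away from the local mode;
  anything outside (0.01, 0.99) is clipped with a warning. Detection
  p-values fail at rate 0.001 per probe-sample; 2% of probes are
  SNP-flagged. Cluster gene annotation draws from the same gene universe as
  the expression layer; ~2% of clusters are miRNA host genes (`MIRxxxx`),
  and two planted-DMP clusters are re-annotated to host genes of planted DE
  miRNAs.
- **Pathways** — 200 sets of 20–100 genes; 20 planted sets oversample the
  planted gene groups of all three layers at 5× their base rate, creating
  the shared enriched core the integration stage should recover.
- **Targets** — per miRNA, 100–300 true target genes; each of 9 algorithms
  reports a true pair with probability 0.9 and a non-pair with probability
  0.01; the table keeps pairs with support ≥ 1.

One global seed; each layer derives a child generator at a fixed offset, so
layers are individually reproducible and the whole bundle is a pure
function of the configuration.

**What it does not emulate:** probe-level correlation beyond cluster state,
dye bias and background (no IDAT/scanner modelling), batch and chip
effects, gene-length or GC confounding in enrichment, realistic gene-set
overlap structure, cell-type mixtures, and hydroxymethylation. Passing
tests demonstrate that the *machinery* is correct and calibrated under the
stated noise model — not that real-data preprocessing concerns are solved.

## Problem sizes and runtimes

The default end-to-end configuration (10,000 genes / 866 miRNAs / 20,000
probes, 12 samples) runs in a few seconds on one CPU — deliberately scaled
down from a 450K array's 485k probes while keeping every structural feature
(design-type mixture, clusters, planted regions) intact. Replicated
calibration checks (20-seed null FDR, 20-seed null DMR, 10-seed ORA and
consensus recovery) use 1000–6000 features per replicate; the hypergeometric
oracle sweep enumerates every (k, K, n, N) with N ≤ 12 exactly.

## Known limitations

- The BMIQ M-step uses weighted moment matching rather than full MLE shape
  updates; it converges fast and recovers mixture weights within ±0.05, but
  shape estimates are less efficient than MLE in small samples.
- Stouffer region combination treats member probes as independent; with
  correlated probes the combined p is anti-conservative in principle,
  though the null-calibration test (mean false DMRs ≤ 1 over 20 seeds at
  FDR 5%) shows the realized rate is controlled under the generator's
  noise model.
- A cluster containing a single very strong DMP can qualify as a region
  when its combined evidence survives BH — consistent with the stated
  acceptance rules (≥ 3 probes, ≥ 1 strong CpG), but worth knowing when
  interpreting DMR counts on data with many isolated DMPs.
- The t-test assumes equal group variances; no Welch option is exposed.
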