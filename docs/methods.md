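# Methods

This note records the models, conventions and numerical choices behind
`symcell`, in the spirit of a statistical methods appendix. Nothing here
states an empirical result that the test suite or `scripts/acceptance.py`
does not itself compute.

## Synthetic data model

The generator emulates a two-sample (symbiotic / aposymbiotic) droplet
scRNA-seq experiment aligned to concatenated host+symbiont genomes.

**Counts.** Gene counts are negative binomial with
`Var = μ + μ²/r`, where `r` (`nb_dispersion`, default 10) is a single
global size parameter, sampled as a gamma–Poisson mixture. Per-cell
library sizes are log-normal (`log-mean log 2000`, `log-sd 0.35`,
i.e. a median around 2,000 UMIs — the order of magnitude of a typical
coral droplet run). Expected counts are
`μ_cg = L_c · (1 − s_c) · P_{k(c),g}` for host genes and
`μ_cg = L_c · s_c · Q_g` for symbiont genes, where `P_k` is cluster *k*'s
host expression program, `Q` the symbiont program, and `s_c` the cell's
symbiont read *share* of a fixed sequencing budget (reallocation, not
extra depth).

**Programs.** Host programs share a log-normal baseline
(`log-weights ~ N(0,1)`); each cluster up-regulates a disjoint block of
25 marker genes 8-fold, which keeps clusters well separated and marker
detection well-posed. The planted immune set (40 genes) and
nutrient-cycling marker set (10 genes) get a moderately expressed
baseline (`log-weight ~ N(0.5, 0.5)`) so the planted effects are
detectable rather than drowned in zeros. No further gene–gene
correlation is modeled.

**Planted effects.** Symbiotic-state cells of the *effect* cluster have
immune-set means multiplied by `2^(−1.5)` and nutrient-marker means by
`2^(+1.5)`, then the program is renormalized (the budget is fixed). The
*null* cluster is identical in distribution across states. Hosting cells
exist only in the symbiotic sample's *hosting* cluster (5% of its
symbiotic cells); their symbiont share is Beta(70, 30) — mean 0.7,
sd ≈ 0.046 — against a 0.1% leak elsewhere, which makes the per-cell
symbiont fractions sharply bimodal around the 0.5 classification
threshold. Doublets (6% of cells) are sums of two uniformly chosen
same-state cells and are only ever *flagged*, mirroring a pipeline that
consumes an external doublet caller's calls.

**Annotations.** Immune genes carry immune-pathway GO terms
(immune response, NF-κB, Toll-like receptor, interleukin, TGF-β
signaling) and are enriched for the chaperone COG category "O"; 25
random background GO terms cover ~3% of genes each. Immune and nutrient
genes are always Pfam-annotated (curated gene sets are, in practice);
background genes at rate 0.85 — otherwise the driver table's Pfam gate
would remove planted drivers at random, which is not a property of the
method under test.

**What the generator does not model** — ambient RNA, UMI duplication,
transcriptome-wide co-expression structure, batch effects beyond the
state split, mitochondrial content. Passing tests therefore demonstrate
correctness of the inference machinery and its calibration under an NB
world, not robustness to every artifact of real droplet data.

## Quality control

Genes detected (count ≥ 1) in fewer than 3 cells are removed first, then
cells with fewer than 200 or more than 3,000 detected genes. Detected
genes are counted on host+symbiont genes jointly, because filtering
precedes the host-gene subset. The filter is one pass in that order;
strict idempotence can fail on adversarial inputs where removing cells
drops a gene below its cell threshold, but holds on realistic data (and
is tested on the default generator output). "Expressed" means count ≥ 1.

## Embedding and clustering

Normalization is `ln(1 + 10⁴ · x / total)`. Highly variable genes are
ranked by variance of normalized values divided by a quadratic
mean-variance trend fitted in log–log space (deterministic, gene-id
tiebreak). Scaling is a per-gene z-score with the **population (n)
denominator**, clipped to ±10; zero-variance genes scale to 0. PCA is a
truncated SVD of the scaled matrix (ARPACK with a fixed start vector;
full LAPACK SVD for small problems), with each component's sign fixed so
its largest-magnitude loading is positive. Requesting more components
than the numerical rank is an error that reports the achievable rank.

Clustering builds a k-nearest-neighbor graph (k = 20 by default, each
cell in its own neighborhood) on the leading components, reweights edges
by shared-neighbor Jaccard overlap (pruned below 1/15), and runs Leiden
modularity optimization (RB configuration, resolution 0.55 for the full
dataset, 0.25–0.5 for per-cluster subsets) with a fixed seed. Labels are
renumbered by decreasing cluster size.

**Integration.** Cross-sample integration is a joint PCA on the merged
matrix rather than anchor-based correction: every downstream inference
re-runs PCA on per-cluster subsets, so no anchor heuristics are needed
there. One consequence required a correction: a strong within-cluster
state effect can split one population into two near-state-pure clusters
at the full-dataset stage. `merge_state_split_clusters` therefore merges
a pair of clusters when each is >90% one state, the dominant states are
opposite, and the two are mutually nearest by PCA centroid distance.
The rule is deliberately conservative — a genuinely state-specific
population such as an algal-hosting cluster has no opposite-state
mutual-nearest partner and is never merged.

Cluster markers use a Wilcoxon rank-sum test per gene (cluster vs rest)
restricted to |log2FC| ≥ 0.5, with log2FC computed on expm1-means with a
pseudocount of 1 (`log2((mean(expm1 x_in)+1)/(mean(expm1 x_out)+1))`),
BH-adjusted within cluster.

## Symbiont partitioning and gene-set scores

Symbiont fractions are computed on the full dual-genome matrix before
any host subsetting; classification is strictly greater-than 0.5 ("over
50%"). Gene-set read fractions default to the host-gene universe for
both numerator and denominator (the score is taken after the conceptual
host subset); flagging is strictly greater-than 4.5%. The Mann-Whitney U
GO enrichment takes per-gene scores — by default the signed significance
`−log10(p)·sign(log2FC)` of the whole-dataset state contrast — and
compares member vs non-member ranks per term (two-sided, normal
approximation with tie correction), BH across terms at FDR 0.1;
direction from the median difference; terms under 5 scored members are
dropped. GO-graph propagation is off: term maps are taken as given.

## State separation within a cluster

The cluster is re-embedded from scratch and the first 10 PCs are each
tested by one-way ANOVA of scores on state at α = 0.05 per PC, with no
multiplicity correction across the 10 components (each component is
read at face value; configurable). Driver genes are the top 10 positive
and top 10 negative loadings of each significant PC; de-duplication
across PCs is union-by-gene (a gene driving several PCs appears once,
keeping its largest-|loading| record). Genes without a Pfam domain —
including genes missing from the annotation table, which are logged —
are removed from the final table.

**Differential expression.** The default test is a minimal two-group NB
Wald test on raw counts: size factors by median-of-ratios with the
positive-counts geometric mean (defined on sparse data); gene-wise
dispersion by method of moments on size-factor-normalized counts with
the within-group pooled variance, floored at 1e-8 and capped at 20; the
Wald z is the log ratio of group means (with a symmetric continuity
shift `δ = (1/n₁ + 1/n₀)/2`) over its delta-method standard error. No
shrinkage is applied. A Wilcoxon rank-sum alternative on normalized
values bounds sensitivity to the NB assumptions. All-zero genes in the
subset are dropped with the count reported. Calibration (raw p ≈ uniform
in the planted null cluster; zero BH discoveries there) is checked by
the test suite and the acceptance script.

## Cross-species DEO comparison

DE gene lists are mapped through a (gene_a, orthogroup, gene_b) table —
many-to-many rows allowed, but one orthogroup per gene — into orthogroup
sets; genes without orthogroups are dropped and counted. The Venn
partition (shared / unique-A / unique-B) runs over a background of all
orthogroups in the table, and each group is tested per GO term with a
two-sided Fisher exact test (probability-mass rule: sum of outcomes no
more probable than observed), BH across terms. The background choice is
configurable; the default is the full orthogroup universe of the table.

## Phenotype metrics

Absorptance is `A = 1 − R` elementwise; the chlorophyll-a peak is read
at the measured wavelength nearest 675 nm (no interpolation). PAR-mean
reflectance is the unweighted mean of R over samples in 400–700 nm.
Density fold change is the ratio of mean symbiont densities
(cells/cm²); the two-group comparison is the tie-corrected
Kruskal-Wallis H with its chi-square p.

## Determinism and seeding

A single global seed fans out to per-stage seeds by stable hashing of
stage names (`blake2s`, reduced below 2³¹), so adding a stage never
perturbs earlier ones. ARPACK uses a fixed start vector; Leiden receives
an explicit seed; all TSV floats are written with a fixed format; the
manifest contains no timestamps. Two runs with the same configuration
and seed are byte-identical, which the acceptance script verifies.

## Validation problem sizes

The recovery study runs the default conditions (2 × 3,000 cells, 2,000
host + 300 symbiont genes, 6 clusters) over 10 fresh seeds; the oracle
sweeps cover all 2×2 tables with grand total ≤ 30, ~200 random ANOVA
inputs, and 50×30 PCA problems; null calibration uses 1,000 label
permutations, 200 simulated terms per enrichment test, and 500
replicates for the BH-FDR study. These sizes keep the full battery in
the minutes range on a single CPU while leaving Monte-Carlo error well
inside the asserted bands.

## Known limitations

The NB Wald test is unshrunken and slightly anti-conservative for very
low-count genes (bounded by the Wilcoxon alternative); the SNN merge
step only repairs two-way state splits; the MWU enrichment treats genes
as independent (no gene-gene correlation correction); the generator's
compositional renormalization induces tiny (<2%) spillover fold changes
on unplanted genes in the effect cluster. The co-expression joint score
is a visualization-grade summary (minimum of capped values), not a
calibrated statistic.
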