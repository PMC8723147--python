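# Methods

## The problem

In tissues with small transcriptional effect sizes — post-mortem brain in
psychiatric disorders being the canonical case — differential expression
analysis (DEA) recovers few genes, and genes that *regulate* or are
*regulated by* the disease signal without being differentially expressed
themselves are invisible to a standard pipeline.  `rnassist` ranks every
gene by how strongly it is tied, through the co-expression network, to the
genes that do carry differential-expression signal.  The top of that
ranking ("critical genes") is enriched for disease-relevant genes that a
DEG cutoff would discard.

## The procedure

1. **Network.**  An unsigned weighted gene co-expression network is built
   from expression: soft-power adjacency `a_ij = |cor(x_i, x_j)|^β`
   (default β = 6, the common soft-threshold default; exposed in config)
   turned into the topological overlap matrix

       TOM_ij = (Σ_{u≠i,j} a_iu a_uj + a_ij) / (min(k_i, k_j) + 1 − a_ij)

   with `TOM_ii = 1`.  A precomputed TOM may be supplied instead (dense or
   edge-triplet TSV).  Modules are detected with Louvain community
   detection on the weighted TOM graph (resolution 1.0, seeded).  Louvain
   is used instead of hierarchical clustering with tree cutting: it is
   O(n log n), parameter-light, and its assignments are less sensitive to
   the cutting height.  The classical module-merge step (merging modules
   whose eigengenes correlate above 75%) belongs to the hierarchical
   pipeline and is not re-implemented for Louvain modules.

2. **Embedding.**  The TOM graph is embedded into d = 64 dimensions by a
   weighted first-order objective with negative sampling: sampled edges
   (probability ∝ weight) pull endpoint coordinates so their dot product
   approaches the edge weight; a `negative_ratio = 0.15` fraction of
   uniformly random pairs is pushed toward dot product 0.  Defaults:
   100 epochs, learning rate 0.1 decaying linearly to 0, sampling budget
   75 positive samples per node per epoch.  Internally each epoch's budget
   is processed in 8 mini-batches with the per-node mean gradient as the
   step direction; this makes the step size independent of node degree and
   of the sampling budget, and the defaults converge to dot-product
   residuals of order 10⁻² on planted-module networks.  Residuals are
   clipped at ±5 for robustness.  Everything is driven by a single seeded
   generator, so runs are bit-reproducible.

3. **Embedding quality (advisory gate).**  The embedding is clustered with
   k-means (k = number of Louvain modules, k-means++ init, 10 restarts)
   and per-module statistics are compared with per-cluster statistics by
   Welch t-tests: the percentage of genes per group that differ across
   binned trait classes by one-way ANOVA, and the per-group
   eigengene–trait |Pearson r|.  Traits are binned into 4 near-equal-count
   classes (quartile edges by default; explicit edges such as the
   25/50/100 AUDIT boundaries can be supplied — interior bins are
   left-closed/right-open, so a value on an edge joins the upper class).
   Eigengenes are the first principal component of the z-scored module
   submatrix, oriented so the mean correlation with member genes is
   non-negative.  Large p-values mean the embedding preserved the
   network's trait structure.  The gate warns but never blocks: it is a
   diagnostic, not a filter.

4. **Impact labeling and classifiers.**  Genes whose |log2FC| falls in the
   top 8% are labeled *impact* (ties at the threshold included); the
   non-impact class is downsampled to parity; logistic regression
   (max_iter = 1000, coordinates standardized), random forest and XGBoost
   (library defaults) are each trained 3 times on stratified 80/20 splits.
   Per-dimension importances (|coefficients| for LR, impurity importances
   for the trees) are normalized to sum to 1 and averaged over repeats;
   the minimal descending prefix reaching 50% cumulative importance is
   each model's "top dimensions".  Averaging importances before selection
   is our aggregation choice (the repeat protocol does not dictate one);
   accuracies are reported as mean ± sd.  A retrain restricted to the top
   dimensions, under the identical protocol, reports the accuracy ratio
   retained by the selected subspace.

5. **Rankings.**  *Critical genes*: for each model's top-dimension
   subspace, Euclidean distances from every gene to every impact gene are
   computed; impact genes strictly within σ are counted, counts are summed
   over models and sorted (ties broken lexicographically for deterministic
   output).  σ defaults to the 5th percentile of the pooled gene-to-impact
   distance distribution per subspace — a scale-free rule that adapts to
   each subspace's geometry — or can be fixed explicitly.  *Neighbor
   genes* (the non-ML baseline): a gene's count is the number of impact
   genes with TOM edge weight strictly above ε; ε can be fixed or chosen
   so that the number of positive-count neighbor genes equals the number
   of positive-count critical genes (achievable sizes are the level sets
   of each gene's maximal impact-edge weight; with tied weights the
   nearest achievable size is returned with a flag).  In both algorithms a
   gene never counts itself — self-distance 0 / self-weight 1 would
   otherwise hand every impact gene a guaranteed count.

6. **Validation statistics.**  Exact upper-tail hypergeometric overlap
   tests against a declared universe (default: the aligned analysis
   universe); per-gene Pearson correlations of list members with traits,
   compared across lists on |r| (Welch t for 2 lists, one-way ANOVA with
   Tukey HSD beyond that — absolute values because the comparison targets
   the magnitude, not the direction); and cross-cohort correlation — the
   mean |r| between the top-n genes of two lists in an independent
   expression cohort (n = 50 by default; DEG-style lists ranked by
   |log2FC|, count-based lists by their ranking).

## The synthetic-data generator

The generator emulates the statistical regime the method targets, not any
particular dataset.  Genes load on per-module latent factors
(`x = λ f_m + √(1−λ²) ε`, λ = √within_module_cor, default 0.7), giving
block-structured co-expression.  Differentially expressed genes receive a
small case-group mean shift on the log2 scale (default 0.3, matching the
"everything under 0.4" small-effect regime) and are planted in 2 of the 8
modules; planted regulator genes load on the first DEG module's factor at
`regulator_to_deg_cor` (default 0.7) and receive **no** shift — they are
the ground-truth "hidden signal" the ranking should recover.  Traits are
noisy linear functions of mapped module factors, rescaled to a loosely
AUDIT-like range, with 5% of values dropped as missing.  The DEA table is
computed from the generated data by per-gene Welch t-tests with
Benjamini–Hochberg adjustment, standing in for an upstream DESeq2/limma
run.  Default scale: 2 000 genes, 60+60 samples, 8 modules — minutes-scale
end-to-end while keeping an 8% impact class meaningful (~160 genes).

What the generator does **not** model: library-size and batch effects,
count noise (values are Gaussian on a log-like scale), hub-gene degree
heterogeneity within modules, overlapping modules, and single-cell
structure.  Passing tests therefore demonstrate the algorithmic contract
and the statistical logic, not performance on any particular real
dataset.

A consequence of the small-effect regime worth knowing: with a 0.3 shift
and 60+60 samples, the sampling noise of the estimated log2FC (≈0.18) is
comparable to the effect, so roughly a third to a half of the top-8%
impact set are noise genes scattered over all modules, and the BH-adjusted
DEA finds few or no significant genes.  Classifier accuracies land around
55–65% rather than near-perfect, regulator recovery shows up as a rank
shift (planted regulators rank significantly better than random non-DEG
genes) rather than as dominance of the top of the list, and with the
default σ rule most genes carry at least one count — the *ranking*, not
the binary positive set, is the informative output.  This mirrors the
intended use: candidates are read off the top of the ranking.

## Numerical choices and degenerate inputs

- Canonical gene order is lexicographic everywhere; `align_universe`
  restricts all inputs to the shared universe in that order and reports
  dropped ids per source.  Missing adjusted p-values are treated as 1.0
  (never a DEG).  Floats are serialized with 10 significant digits, which
  round-trips the TSV formats bit-exactly.
- Dense TOM input must be symmetric within 1e-10 and is then exactly
  symmetrized; triplet input stores each undirected edge once.
- ANOVA on a gene with no within-class variance anywhere is counted as
  nonsignificant (the F statistic is 0/0; counting it as significant
  would inflate module percentages).
- Welch t-tests with (numerically) zero variance on both sides return
  p = 1 when the means agree and p = 0 otherwise.
- Eigengene orientation: sign fixed by the mean correlation with member
  genes; correlations with fewer than 3 complete pairs, or against a
  constant side, are reported as missing (NaN), never as 0.
- k-means and Louvain labels are renumbered by first occurrence in
  canonical gene order so labelings are stable across runs.
- Dimension-selection ties in importance are broken by dimension index.

## Known limitations

- σ and ε defaults make no claim of reproducing any published list size;
  they are explicit config knobs.
- The embedding is a from-scratch implementation of the first-order
  negative-sampling family; it matches the cited hyperparameter defaults
  but not any specific third-party implementation bit-for-bit.
- Module detection supports Louvain only (no dynamic tree cut), and no
  scale-free-topology fit is provided for choosing β.
- The pipeline assumes DEA and (optionally) the TOM are computed upstream
  when real data are used; it does not normalize counts or run DESeq2.
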