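# Methods

`prefexp` identifies genes preferentially expressed in one target tissue —
the motivating case is rice root hairs contrasted against whole roots within
a multi-organ microarray compendium — and characterizes the resulting gene
set in silico: annotation-repeat GO enrichment, promoter scanning for a
short cis-element, coexpression refinement of a protein–protein interaction
(PPI) network, and cross-species conservation statistics. This note records
the models, the parameter choices that matter, the numerical conventions,
and what the synthetic benchmarks do and do not establish.

## Selection of tissue-preferential genes

The input is a genes × samples matrix of log2 intensities with a
sample → tissue map and designated *target* (e.g. `root_hair`) and
*reference* (e.g. `root`) tissues. The chain is:

1. **Quantile normalization** (optional, default on). Single-channel array
   compendia assembled from multiple series need their sample distributions
   aligned; quantile normalization is the standard choice. Each column is
   ranked (ties averaged), and values are replaced by the across-column mean
   of the per-rank sorted values, fractional ranks interpolating between
   adjacent rank means.
2. **Replicate collapsing.** One column per tissue, the arithmetic mean of
   its replicate columns in log2 units. All later thresholds are defined on
   tissue-level values. Averaging before rather than after the fold rule is
   a deliberate convention: it makes every rule a statement about tissue
   means, and it is recorded here because the alternative order changes
   borderline calls.
3. **Expression filter.** Keep genes whose *maximum* tissue-level log2
   value is strictly greater than `expression_threshold` (default 8, a
   conventional presence cutoff for 44K-style single-channel arrays). The
   max-over-tissues reading is the permissive one: a gene expressed in any
   single tissue survives to be clustered.
4. **K-means clustering** of the surviving profiles (Euclidean distance,
   k-means++ initialization, `kmeans_restarts` = 10 restarts, best inertia
   kept, fixed seed; `n_clusters` = 12 by default). By default each gene's
   profile is mean-centered first (`center_profiles`): clustering then
   groups genes by expression *shape* across tissues rather than absolute
   level, which is what "expression pattern" clustering intends. Without
   centering, per-gene baseline differences dominate the Euclidean metric
   and a target-preferential pattern can be split across abundance bands.
   The target-preferential cluster is the one maximizing the centroid
   contrast `centroid[target] − max(centroid[other tissues])`; ties break
   to the lowest cluster index. This operationalizes "preferentially
   expressed" as a single explicit rule.
5. **Cross-tissue elimination.** Within the chosen cluster, keep a gene only
   if its target value exceeds its maximum over all tissues *other than the
   target and the reference* by `cross_tissue_margin` (default 1 log2 unit,
   i.e. two-fold — mirroring the fold rule below, since no sharper
   criterion is standard).
6. **Fold rule.** Keep genes at least `fold_min`-fold (default 2) higher in
   the target than in the reference: `t − r ≥ log2(fold_min)`, inclusive
   ("at least" reads as ≥).

Each stage records the genes it removed and why; the result telescopes
(every stage's output is a subset of its input) and is byte-reproducible
given the seed.

## Annotation-repeat GO enrichment

GO statistics are computed over annotation *repeats*: one gene–term pair is
one repeat. With `m` repeats of a term genome-wide, `k` repeats among the
queried genes, `Q` total repeats across the queried genes and `G` total
repeats genome-wide,

- expected repeats `E = m·Q/G` (kept unrounded internally),
- fold enrichment `k/E`,
- p-value `P(X ≥ k)` for `X ~ Hypergeometric(G, m, Q)`.

The repeat-based population is the one the reference count table pins down
numerically (its expected column is exactly `m·Q/G` on repeat counts); the
p-value is parameterized consistently with it. A gene-based variant
(distinct genes as the population) is available via `population="genes"`.
Terms are reported when `p ≤ 0.05` and `fold ≥ 2`, both inclusive, sorted
by fold. No multiple-testing correction is applied — the report column is
explicitly labelled "raw hypergeometric p" so the omission is visible.
`m` and `G` are always inputs, never recomputed, because they depend on the
annotation release used upstream.

Display rounding is decimal half-up at 2 dp and applies only at report
time. Published tables of this kind are not always internally consistent at
the printed precision (rounding conventions drift between cells); the
package therefore never round-trips printed values through its own
arithmetic — it recomputes from the integer counts.

## Promoter motif scanning

Promoters are fixed-length upstream windows (default 2 kb; genes near a
contig edge yield shorter windows). Position 0 is the farthest-upstream
base, so position `L − 1` abuts the transcription start; reports add
`distance_to_tss = L − offset − w`. The scanner slides the motif and its
reverse complement over every offset of the forward strand:

- **Consensus mode**: IUPAC consensus, hits have at most `max_mismatches`
  mismatches; an `N` in the promoter never matches.
- **Matrix mode**: length × 4 probability matrix scored as log-odds against
  a uniform background; hits score at least `score_fraction` (default 0.85)
  of the maximum attainable score. The 0.85 default is a conventional
  match-quality cutoff for short plant cis-elements; it is configurable
  because no single threshold is canonical.

All overlapping occurrences are reported; de-duplication is left to the
caller. The motif itself (e.g. the 16–17-nt root hair-specific element) is
always a user input — the package does not embed any published element
sequence. Scanner correctness is established by exact equivalence with an
independent naive double-loop scanner and by a strand-symmetry property
(scanning the reverse complement mirrors offsets via `L − w − offset` with
strands swapped).

## Network refinement

Each PPI edge gets the Pearson correlation (PCC) of its endpoints' tissue-
level expression profiles; correlations are computed across collapsed
tissue columns (one value per tissue), not across replicates, so the PCC
measures anatomical coexpression. Edges survive only with PCC strictly
greater than the threshold (default 0.5). Zero-variance profiles yield an
undefined (NaN) PCC and the edge is dropped. Edges with an endpoint absent
from the matrix are dropped and counted, not errored — interaction catalogs
routinely exceed array coverage. Nodes are flagged seed (member of the
preferential set) vs interactor and can carry functional-class labels from
a two-column mapping table. Retention is monotone in the threshold.

## Cross-species conservation

Given two species' preferential gene sets and an ortholog pair table
oriented (species 1, species 2): a gene *has an ortholog* if it appears in
at least one pair, and is *conserved* if at least one of its partners lies
in the other species' set. Many-to-many orthology counts each gene once.
Percentages are displayed at 1 dp, half-up. Orthology itself is consumed as
input (flat pairs), never computed.

## Synthetic data generator

The generator emulates the structure of a replicate, multi-organ,
single-channel log2-intensity compendium:

- **Compendium**: each gene draws one baseline level from
  `Normal(baseline_mean = 9, baseline_sd = 1)` shared across tissues
  (typical mid-range level and spread for normalized 44K-style intensities);
  planted preferential genes add `effect_log2` (default 2, matching the
  two-fold selection rule) to their target-tissue mean; each replicate array
  adds `Normal(0, noise_sd = 0.3)` measurement noise. Defaults: 2000 genes,
  10 tissues, 3 replicates per tissue, 100 planted genes.
- **Annotations**: planted genes carry one planted term with probability
  0.5 versus a background assignment rate of 0.02; `G` defaults to 39,571
  (a realistic genome-wide repeat total for rice GO Slim).
- **Promoters**: i.i.d. uniform A/C/G/T backgrounds with exact motif copies
  planted at recorded non-overlapping offsets on random strands. The
  default 16-mer consensus used in examples is synthetic, not a published
  element.
- **PPI**: planted edges touch planted genes; background edges connect
  non-planted genes; duplicate- and self-loop-free.

All generators are pure functions of (parameters, seed); each uses a
SHA-256-labelled substream of the master seed, so adding one generator to a
workflow never changes another's output.

**What the synthetic benchmarks do not show.** The compendium has no
cross-tissue biological variation beyond the planted target effect: a
background gene's true mean is identical in every tissue, so the only
tissue structure is the planted one. Real compendia have pervasive
tissue-specific programs, correlated genes, batch effects between merged
series, probe-level artifacts and heavier-tailed noise. Passing the
recovery benchmarks therefore shows the chain is correctly wired and can
separate a two-fold effect from 0.3-SD noise — not that the default
thresholds are optimal on real arrays. Similarly, uniform-background
promoters give the scanner's false-positive rate its closed-form binomial
expectation, which real promoters (GC skew, repeats) will exceed.

## Numerical choices and degenerate inputs

- Quantile normalization with one sample: returned unchanged with a
  warning, not an error.
- K-means requires at least as many genes as clusters; ties in the
  preferential-cluster contrast break to the lowest index for determinism.
- `fold_enrichment` with zero expectation: `+inf` if `k > 0`, NaN if
  `k = 0` (sentinels, never silently clamped).
- PCC is clipped into [−1, 1] against floating-point overshoot; an exactly
  −1-correlated edge is *not* retained at threshold −1 because retention is
  strict.
- GFF3 1-based inclusive coordinates are converted to 0-based half-open at
  the parsing boundary; promoter extraction truncates at contig edges and
  errors on missing contigs or strandless features.
- Expression tables are written with pandas' shortest round-trip float
  representation and read with `float_precision="round_trip"`, so a
  write→read cycle is bit-exact.

## Benchmark problem sizes

The recovery benchmark uses 2000 genes × 10 tissues × 3 replicates with 100
planted genes (20 seeds, median F1 reported) — large enough that the
planted pattern forms its own K-means cluster reliably, small enough to run
in seconds. Hypergeometric correctness is verified exhaustively for all
populations `G ≤ 20` (≈ 19,500 instances) against direct binomial-coefficient
enumeration. Scanner equivalence uses 100 random 2-kb promoters. These
sizes were chosen as the smallest at which each property is convincingly
exercised.

## Known limitations

- The expression filter's max-over-tissues reading, the margin rule's
  1-log2 default, and the centroid-contrast cluster rule are explicit
  operationalizations of informally stated practice; all are configurable,
  and other reasonable readings exist (per-sample filtering, quantile-based
  margins, cluster choice by membership of marker genes).
- K-means with a fixed k = 12 can split a small preferential pattern across
  clusters on small compendia (the selected cluster then loses recall);
  profile centering mitigates but does not eliminate this.
- GO enrichment treats terms as flat labels (GO Slim style): no graph
  propagation, no term–term dependence, no FDR.
- The PWM scanner's uniform background is a simplification; no higher-order
  background model is provided.
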