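# Methods

`samnet` implements the standard analysis chain for a two-group
microarray comparison — quantile normalization, SAM permutation
differential expression with q-value FDR, Fisher's-exact gene-set
over-representation, and two interaction-network rankings — together
with a synthetic-data generator that plants known structure at every
stage so the chain can be validated end to end without any external
download.

## Expression preparation

Input matrices are features × samples on a declared scale; all
statistics run on log2 intensities (`to_log2` converts linear data with
an optional pseudocount, default 0). Rows containing missing values are
dropped and counted in the log — the simplest defensible policy, since
probe-level imputation is out of scope. Quantile normalization replaces
each column's value at rank r with the across-column mean of the sorted
columns at rank r; tied values within a column receive the mean of the
reference values over their rank span (the convention used by the
standard microarray implementations). On tie-free data the transform is
idempotent to machine precision; with ties the tie-averaging step breaks
exact idempotence, which is inherent to that convention. A side effect
worth knowing: a gene that occupies the same rank in every column (for
example, the global maximum) comes out with identical values in all
samples and hence zero pooled variance; the s0 regulariser below keeps
its d score defined.

Fold changes are reported on the signed linear scale: with
R = 2^(mean_exp − mean_ctrl), the value is R when R ≥ 1 and −1/R
otherwise, so a halving prints as −2 and there are no values strictly
between −1 and 1.

## SAM differential expression

For gene i, d_i = r_i / (s_i + s0), where r_i is the difference of group
means (experimental − control, log2 units), s_i the pooled standard
error sqrt((1/n1 + 1/n2)·SS_within/(n1 + n2 − 2)), and s0 a fudge factor
that prevents low-variance genes from dominating. s0 is chosen by the
classic coefficient-of-variation minimisation: candidates are the
percentiles {0, 5, …, 100} of s, and the winner minimises the CV of the
median absolute deviation of d across s-quantile bins (10 bins by
default). A percentile strategy (default median of s) and a fixed value
are available as alternatives.

The null distribution relabels samples into two groups of the original
sizes. When the number of distinct assignments is at most
`n_permutations` (default 1000) they are all enumerated — for the 6 vs 6
design that is C(12,6) = 924, making the null fully deterministic;
otherwise a seeded sample of distinct assignments is drawn. Both members
of each complement pair are enumerated (they carry opposite signs; the
magnitudes pair up, so the pooled null is symmetric). s0 is fixed on the
observed data and reused for every permutation.

p-values are two-sided empirical tail probabilities against the null
pooled across genes and permutations, with an add-one correction:
p = (1 + #{|null| ≥ |d|}) / (1 + N). Pooling follows the original SAM
practice — 924 permutations per gene alone would give a p granularity of
only ~1/925.

q-values use discretised rejection regions: for each threshold Δ over
the sorted |d|, the observed positives are O(Δ) = #{|d| ≥ Δ} and the
expected false positives F(Δ) are the median across permutations of the
per-permutation count #{|d_null| ≥ Δ}, scaled by π0 and divided by O(Δ).
π0 is estimated as min(1, 2·mean(|d| ≤ median|d_null|)). A gene's q is
the minimum FDR over all thresholds it clears, which makes q monotone
non-increasing in |d|. DEGs require q < 0.05 and |signed fold change|
> 1.5 (both configurable); tables are ranked by increasing p, then q,
then gene id.

No attempt is made to reproduce any particular commercial platform's
q-value variant; the construction above is declared, not inferred.

## Enrichment

Over-representation uses the upper-tail hypergeometric probability
P[X ≥ k] for k DEGs among the n called, drawn from a universe of N genes
of which K belong to the set — the one-sided Fisher's exact test. The
universe is the genes present on the analysed matrix: the only
background the pipeline can know. Benjamini–Hochberg correction gives
each set an FDR; the significance gate defaults to FDR < 0.05 and can be
switched to raw p < 0.05 in the config, since both conventions are
common. When probes must be collapsed to symbols, the probe with the
smallest p represents the gene.

## Networks

The pathway network is the directed graph induced on the significant
pathways by an upstream→downstream relation list; relations touching
non-significant pathways are skipped and logged. The gene signal network
is the typed interaction graph (compound c, activation a, indirect ind,
inhibition inh, expression ex, binding b; each edge directed or not)
induced on the DEGs. Both graphs share one adjacency convention: an
undirected edge is stored once and expanded to both arcs in the 0/1
adjacency view, so it contributes one indegree and one outdegree to each
endpoint, and degree = indegree + outdegree throughout. Self-loops and
duplicate edges are dropped with a log message.

Betweenness is the unnormalised ordered-pair sum
B(i) = Σ_{s≠i≠t} σ_st(i)/σ_st over shortest paths in the adjacency view,
endpoints excluded, unit weights, fractional credit on ties, computed
with Brandes' algorithm (networkx). Ordered-pair counting is the natural
reading for a genuinely directed graph (an undirected 3-path gives the
middle node B = 2; a k-leaf star centre gives k(k−1)). Disconnected
pairs contribute 0. Edge types, including inhibition, are traversable
annotation only — no type-specific semantics are imposed.

Core pathways and hub genes are nodes of degree ≥ 1 (configurable),
ranked by decreasing degree (pathways) or decreasing betweenness
(genes); ties break by degree, then node id. Pathway up/down features
are the union of member-DEG directions (Up, Down, or Up|down).

## Synthetic data

`SimulationSpec` defaults define the emulated study conditions: 15,000
genes, 6 samples per group, 4.8% planted down- and 1.4% planted
up-regulated genes (mirroring a 720:205 down:up imbalance at its overall
rate), planted effect 1.5 log2 units (linear ≈ 2.83, clearing the
|FC| > 1.5 gate with margin, in line with the fold-change magnitudes
such comparisons report), within-group SD 0.25 log2 units, and baselines
Normal(8, 1.5) — typical log2 intensity ranges for oligonucleotide
arrays. Noise is Gaussian with equal group variances. The generator does
not emulate probe-level artefacts, batch effects, intensity-dependent
variance or gene–gene correlation, so passing tests demonstrate
correctness of the computation under the stated model, not robustness to
those real-data features.

Gene-set simulation draws background sets uniformly from the universe
and fills designated sets to a configured fraction (default 80%) with
planted DE genes. Relation-graph simulation plants a maximum-degree node
(pathway style) or a single bridge between two equal complete clusters
(gene style); with equal clusters the bridge's betweenness 2k² strictly
exceeds every anchor's 2(k²−1), so its rank-1 position is a theorem of
the construction, not a tendency.

## Pipeline and numerical choices

Stage order is fixed: normalization → SAM → enrichment (two
collections) → pathway network → gene network. All randomness fans out
from one config seed via fixed offsets, so a rerun is byte-identical.
The dendrogram export z-scores each gene and applies average linkage on
Euclidean distance (the common microarray heatmap convention;
configurable); volcano export uses the add-one permutation p, keeping
−log10 p finite. The 2^−ΔΔCt helper returns
2^−[(Ct_t,case − Ct_ref,case) − (Ct_t,ctrl − Ct_ref,ctrl)].

Problem sizes in the test-suite simulations (20 replicates at generator
defaults for recovery, 20 pure-null replicates at 5,000 genes for FDR
control, exhaustive oracles at ≤ 12 nodes/genes) were chosen so the full
chain is exercised at the emulated design's scale while the whole suite
stays comfortably runnable on a laptop.

## Known limitations

* Only the two-class unpaired SAM variant is implemented.
* Exact reproduction of any specific published DEG/pathway/hub tables
  additionally requires the originating annotation and interaction
  databases; the package's acceptance surface is the planted-truth
  recovery described above, with real GEO series-matrix input supported
  as an optional route.
* The q-value construction assumes the pooled null is exchangeable
  across genes; strong gene–gene correlation (absent from the generator)
  would widen its variance in real data.
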