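# Methods

## Problem setting

The package analyzes a multi-condition microbiome perturbation study with
three coupled inputs: a gene-by-sample expression matrix on the log2 scale
(rows keyed by EC-number gene functions, columns by
`<condition>_<site>_<replicate>` samples), per-condition detected-metabolite
lists, and a master metabolic network given as a reaction table (substrates,
products, EC annotations per reaction). Gene identity is the EC number
string: in a community metatranscriptome, reads from many taxa collapse onto
shared enzymatic functions, and the EC number is the natural unit that links
expression to the reaction network.

## Over-expression calling

Per perturbation and site, the fold change is the difference of group means
on the log2 scale, and the location test is Welch's two-sample t-test
(unequal variances; community expression replicates are rarely
homoskedastic). Raw p-values are adjusted with Benjamini–Hochberg. A gene is
over-expressed when `log2FC ≥ log2(fc_threshold)` **and**
`q ≤ q_threshold`, both boundaries inclusive. Defaults `fc_threshold = 2`,
`q_threshold = 0.05` are conventional omics choices and are configurable.

Degenerate cases are assigned deterministically: fewer than two replicates
in either group gives p = 1 with an `insufficient_replication` flag; when
both groups have zero variance the p-value is 1 for equal means and 0
otherwise (noiseless data leave no ambiguity). Exactly identical groups give
p = 1 via the equal-means rule even where the t statistic is 0/0.

## Minimal-subnetwork integration

"Connecting" a condition's omics evidence is formalized on the undirected
bipartite metabolite–reaction graph. Terminals are (1) detected metabolites
present in the network (absent identifiers are reported, never silently
dropped) and (2) every reaction whose EC annotation intersects the
over-expressed set — one EC may pull in several reactions. Reaction
directionality is deliberately ignored: the integration asks only whether
evidence is biochemically adjacent, not whether flux is feasible.

The minimal connecting subnetwork is a minimum-edge-count Steiner tree,
computed with the classical metric-closure 2-approximation: BFS shortest
paths between terminals (lexicographic neighbor order), minimum spanning
tree of the terminal distance graph (Kruskal, ties on the terminal pair),
path expansion, a lexicographic re-spanning of the expanded subgraph, and
iterative pruning of non-terminal leaves. Every tie-break is lexicographic
on node/edge identifiers, so outputs are bit-reproducible. Terminals split
across graph components yield one tree per terminal-bearing component (a
Steiner forest) plus a warning — environmental data routinely contain
unreachable metabolites — and an empty terminal set yields an empty,
flagged result rather than an error.

An exhaustive exact solver (`exact_steiner_oracle`, subset enumeration over
non-terminal nodes, guarded to ≤ 15-node graphs) provides an independent
optimum: since a minimal connected subgraph is a tree, minimizing edges is
minimizing nodes, so enumerating non-terminal subsets in increasing size
and taking the first connected induced subgraph is exact. The test suite
brackets the heuristic between the optimum and twice the optimum on random
instances, the guarantee the metric-closure construction carries.

A condition's gene set is the union of implicated EC sets over its sites
(site-specific profiles capture real spatial heterogeneity; union is the
permissive reading and the implemented default). **Unique genes** for a
condition are those appearing in no other condition's set — including the
control condition's set, which contains the genes implicated by the shared
metabolite core alone and thereby absorbs condition-independent plumbing.

## CLR co-expression network

Mutual information is estimated in bits with the B-spline estimator: each
profile is (by default) rank-transformed, scaled to [0, 1], and assigned
fuzzy membership weights over 10 bins using order-3 (quadratic) B-spline
basis functions on clamped uniform knots; marginal and joint entropies are
plug-in estimates over the weight histograms. Rank transformation guards
against the heavy abundance tails of community expression data and is
switchable. A hard equal-width-binning estimator is retained as a cheap
alternative and as the exact-arithmetic path for discrete test oracles.
Constant genes are excluded with a warning instead of propagating NaNs.

Two background-correction modes are provided because the field uses both
readings: `per_gene` (the canonical CLR default) rectifies each gene's
off-diagonal MI row against that row's mean and standard deviation and
combines the two per-gene scores as a root-sum-square; `global`
standardizes against the mean and standard deviation of all off-diagonal MI
scores. `per_gene` is the package default. Backgrounds with (numerically)
zero spread contribute zero scores, logged.

Edges are selected either by threshold (`Z ≥ z_threshold`, inclusive;
default 4.20, whose one-sided standard-normal tail is ≈ 1.33·10⁻⁵ < 5·10⁻⁵)
or by top-k ranking with lexicographic tie-breaks at the boundary. Both
paths exist because a fixed cutoff and a fixed edge budget are both common
practice; they coincide when k equals the super-threshold count. Centrality
analysis runs on the largest connected component (size ties broken by
smallest node id): betweenness on fragments is dominated by fragment size
rather than a gene's bridging role.

The degree distribution's scale-free character is summarized by an ordinary
least-squares line on (log10 degree, log10 frequency) over nonzero
frequencies, reported as (exponent, R²); at least three distinct degree
values are required for the fit to be defined. On preferential-attachment
graphs of ~1,000 nodes this unbinned estimator averages R² > 0.8 across
seeds, with noticeable seed-to-seed spread driven by singleton counts in
the degree tail.

## Centrality analysis

Betweenness is Brandes shortest-path betweenness on the undirected
unweighted component, normalized by 2/((n−1)(n−2)), endpoints excluded
(the standard convention); degree is the incident edge count. Group
summaries use arithmetic means, fold = group mean / network mean, and
strict `<` for below-average counts. The network-wide means default to the
analyzed component's own means but can be supplied externally so that a
labeled subset of rows (e.g. a published per-gene table) can be summarized
against its parent network's means.

Ratio scores for visualization follow the convention of plotting
log2(betweenness / median betweenness) against degree / median degree;
zero-betweenness genes are floored at one tenth of the smallest positive
value and flagged, and a zero median receives the same floor.

Seed-gene neighborhoods collect a seed set and every node adjacent to at
least one seed, with induced edges. With `drop_isolated_seeds`, a seed
whose closed neighborhood shares no member with the rest of the seed
cluster is excluded in a single pass — the rule used to omit a seed gene
not in proximity to its companions.

## Synthetic data: what it emulates and what it does not

The generator is the package's test bed and mirrors the perturbation-study
design: conditions dry/wet/glycine/control, 3 sites × 3 replicates by
default, log2 expression with a log-normal baseline (log2 mean 6, sd 1 —
matching the abundance skew typical of metatranscriptomes), replicate
noise sd 0.5, responsive fold change 4, and a master network of 100
reactions over 80 metabolites (expected 2 substrate and 2 product links
per reaction).

Ground truth is planted so each stage has a known answer:

* **Responsive genes.** Each perturbation receives a pendant chain of 5
  reactions attached to a core metabolite, annotated with fresh EC numbers
  disjoint across conditions; those ECs are shifted by
  log2(fold change) in their condition's samples. Chain metabolites and
  the attachment point are the condition's signature metabolite terminals.
* **Metabolite core.** A 20-metabolite core is detected once at rate 0.9
  and shared by every condition (detected metabolite pools in such studies
  are nearly condition-invariant); chain attachment points are treated as
  common core compounds and always detected, so their connection into the
  core is identical across conditions and never spuriously
  condition-unique.
* **Co-expression modules.** Five disjoint 10-gene modules share a latent
  per-sample factor with weight 2 (log2 units per factor sd), planted on
  genes outside the responsive sets so module recovery and responsive-gene
  recovery are separable.

All outputs are pure functions of `(config, seed)`: each artifact draws
from an independent named RNG stream derived from the root seed, so adding
or regenerating one artifact never perturbs another.

The generator does **not** emulate taxonomic structure, compositionality,
sequencing-depth variation, batch effects, missing metabolite extraction
biases, or the directed stoichiometry of real reaction maps. Passing tests
therefore demonstrate correctness of the algorithms under the planted
model, not robustness to every pathology of field data.

## Pipeline and determinism

`run_pipeline` sequences simulation (or validated reading of real inputs),
per-condition×site differential calling, integration, CLR network
inference, and centrality analysis, writing TSV/SIF/GraphML/JSON outputs
plus a manifest with the echoed configuration, per-stage output hashes and
timings. All writers iterate in sorted order; matplotlib's SVG hash salt
and date metadata are pinned; two runs with one seed are byte-identical
(manifest timings aside). Problem sizes in the test suite and acceptance
script (≈100–200 genes, ≤110-node master networks, 5–20 seeds per
Monte-Carlo check) were chosen so the planted effects are comfortably
detectable while whole-suite runs stay fast.

## Known limitations

* The Steiner formulation ignores stoichiometry and reaction
  directionality; it identifies adjacency-connected evidence, not feasible
  flux routes.
* Minimum-edge Steiner trees are not unique; the lexicographic tie-break
  makes one canonical choice rather than enumerating co-optimal solutions.
* The B-spline MI estimator's plug-in entropies are biased upward at small
  sample counts; CLR's background standardization absorbs most, but not
  all, of this bias.
* The unbinned log–log power-law fit is sensitive to the sparse degree
  tail; it is a descriptive summary, not a rigorous scale-free test.
* Group centrality comparisons are descriptive (means, folds, counts); no
  significance test is attached.
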