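# metaphenet

Integrated metabolic-network and gene co-expression network analysis for
multi-condition microbiome omics.

Soil (and other environmental) microbiomes respond to perturbations — drying,
wetting, nutrient amendment — with community-wide shifts in gene expression
and metabolite pools. `metaphenet` implements a two-model strategy for
identifying which gene functions (EC numbers, the unit of function across a
community) respond to *which* condition, and how central those functions are
to the community's overall transcriptional program:

1. **Minimal-subnetwork integration.** For each condition, the detected
   metabolites and the over-expressed EC functions (fold change ≥ a
   threshold and BH-adjusted p ≤ a threshold, Welch t-test on log2 values)
   are treated as terminals on a master metabolite–reaction graph. The
   smallest subnetwork connecting them — a minimum-edge Steiner tree,
   computed with the metric-closure 2-approximation — implicates a
   condition-specific set of reactions and their EC annotations.
   **Condition-unique genes** are those implicated in exactly one condition.
2. **CLR co-expression network.** Mutual information between all gene pairs
   (B-spline estimator, order 3, 10 bins) is converted to
   context-likelihood-of-relatedness Z-scores
   `Z_ij = sqrt(max(0, z_i(j))² + max(0, z_j(i))²)`; pairs with
   `Z ≥ Z_TH` (default 4.20, standard-normal tail < 5·10⁻⁵) or the top-k
   pairs become edges. Betweenness and degree centralities on the largest
   connected component locate the condition-unique genes in the global
   response.

A synthetic-data module generates the full input trio (expression matrix,
per-condition metabolite lists, master reaction network) with planted
ground truth — condition-responsive reaction chains, co-expression modules,
a shared metabolite core — so every stage is testable end to end.

## Worked example

```python
from metaphenet import SyntheticConfig, ClrConfig, RunConfig, run_pipeline

config = RunConfig(
    outdir="demo",
    seed=1,
    synthetic=SyntheticConfig(seed=1),   # dry/wet/glycine/control, 3 sites x 3 reps
    clr=ClrConfig(target_edges=400),     # top-400 co-expression edges
)
manifest = run_pipeline(config)
```

The run writes the simulated inputs, per-condition differential tables and
minimal subnetworks, the co-expression network (SIF/GraphML/TSV), and the
centrality tables into `demo/`. With this seed, `condition_genes.tsv`
flags exactly the 5 planted responsive ECs per perturbation as unique, and
`network_summary.json` reports

```json
{"n_nodes": 188, "n_edges": 400, "component_nodes": 159, "component_edges": 305}
```

`group_summary.tsv` then summarizes the unique genes' centralities on the
159-node main component — e.g. the dry-unique genes average betweenness
0.080, about 2.1-fold the network mean, because same-condition responsive
genes co-express and bridge the planted modules:

```
group    n_genes  mean_betweenness  mean_degree  fold_betweenness  fold_degree
dry      5        0.0800            5.2          2.06              1.36
glycine  5        0.0848            6.4          2.19              1.67
wet      5        0.0780            5.4          2.01              1.41
```

The same stages are available from the shell:

```sh
metaphenet simulate --seed 1 --outdir demo-inputs
metaphenet run -c config.yaml
metaphenet network --expression demo-inputs/expression.tsv --target-edges 400 --outdir net
```

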