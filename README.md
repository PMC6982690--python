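# herbnetscreen

Network-pharmacology screening for traditional-medicine herb pairs, built
around the rougui–fuzi (cinnamon twig / aconite root) screen against
cardio- and cerebrovascular disease (CCVD) gene sets.

Herbal formulas act through many compounds hitting many protein targets at
once, so single-target screens miss the mechanism. The network-pharmacology
approach instead (1) merges the herbs' compound inventories, (2) joins
compound–target interaction tables onto them, (3) intersects the hit
targets with disease gene sets to obtain the *potential targets* and the
*active compounds* that reach them, (4) tests the potential targets for
pathway/GO over-representation, (5) builds three graphs — the tripartite
compound–target–disease (C-T-D) network, the bipartite target–pathway
(T-P) network, and a confidence-filtered protein–protein interaction (PPI)
network — and (6) screens nodes by centrality.

The screening currency is three per-node centralities on an unweighted
simple graph with node set V and component size N_c:

- **DC** (degree centrality): the raw number of incident edges.
- **BC** (betweenness): `BC(v) = [ Σ_{s≠v≠t} σ_st(v)/σ_st ] / [(N_c−1)(N_c−2)/2]`,
  where σ_st counts shortest s–t paths and σ_st(v) those through v; pairs
  are unordered and confined to v's connected component.
- **CC** (closeness): `CC(v) = R_v / Σ_{u reachable} d(v,u)`, with R_v the
  number of nodes reachable from v (0 for an isolated node).

The screens, all strict inequalities:

- **key compounds** — C-T-D compound nodes with DC, BC *and* CC above the
  compound-role means;
- **hub genes** — PPI nodes with DC above the network-wide mean degree,
  after keeping only edges with combined confidence score > 0.4;
- **key pathways** — either the same triple-above-average rule over T-P
  pathway nodes, or an explicit curated list.

Enrichment is one-sided hypergeometric over-representation
(`P[X ≥ k]` for k of n query genes in a set covering K of N background
genes, summed exactly in log space) with Benjamini–Hochberg step-up FDR
control.

Because the original inputs were live database queries (TCMSP, OMIM,
PharmGKB, STRING) that cannot be redistributed, the package ships a seeded
synthetic-data generator that emulates their structure — overlapping herb
compound lists, a skewed many-to-many compound–target map, partially
overlapping disease gene sets, a uniformly scored sparse PPI graph — with
exact ground-truth bookkeeping, plus the published reference tables
(21 key-compound, 7 pathway and 8 hub-gene centrality rows, the three
key-pathway gene lists, and all stage counts) as desk-checkable fixtures.

## Worked example

Run the whole pipeline on a synthetic bundle shaped like the two-herb
study (65 + 100 compounds, 2 shared):

```python
from herbnetscreen import PipelineConfig, run_all

cfg = PipelineConfig(simulate={"seed": 7}, seed=7, filter_on="p_raw")
report = run_all(cfg, "runs/demo")
print(report["stage_summary"])
print(report["screening"]["n_key_compounds"],
      report["screening"]["hub_genes"])
```

prints

```
{'active_compounds': 71, 'common_targets': 108,
 'compounds_per_herb': {'fuzi': 65, 'rougui': 100},
 'merged_compounds': 163, 'pooled_targets': 202,
 'potential_targets': 40,
 'targets_per_herb': {'fuzi': 134, 'rougui': 176}}
15 ['G0007', 'G0012', 'G0053', 'G0093', 'G0130', 'G0002', 'G0108']
```

Reading: the two herb tables merge to 163 unique compounds; their
interactions pool to 202 distinct targets, of which 40 also occur in a
disease gene set (the potential targets), reached by 71 active compounds.
On the resulting C-T-D network, 15 compounds exceed the compound-role mean
on all three centralities; on the score-filtered PPI among the
pathway-annotated targets, 7 proteins exceed the mean degree and are
called hub genes. `runs/demo/` holds every intermediate (merged tables,
active-set JSON, enrichment TSV, SIF/GraphML networks, centrality tables,
screening JSON) plus `report.json` and a reproducibility manifest.

The same pipeline is available from the shell:

```sh
herbnetscreen simulate --seed 7 --out bundle/     # synthetic inputs
herbnetscreen run --config cfg.yaml --out runs/a  # full pipeline
herbnetscreen stage centrality --rundir runs/a    # one stage, resumable
herbnetscreen fixture --out ref/                  # published reference tables
herbnetscreen report --rundir runs/a              # re-render the summary
```

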