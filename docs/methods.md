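# Methods

## Pipeline model

The screen treats an herb pair as a two-layer bipartite system propagated
into disease space. Stage 1 merges per-herb compound tables keyed on the
stable compound identifier (display names vary between exports and are
never used for deduplication; on a name clash the first-seen name is kept
and a warning logged). Stage 2 joins compound–target interaction records
onto the merged table. Target prediction itself is upstream of this
package: interactions arrive as data, already produced by whatever
predictor or database generated them, and are only normalized to official
gene symbols through a lookup table (unmapped names pass through
uppercased with a warning — the package deliberately does not query a
symbol service).

Potential targets are defined by the *union* of the disease gene sets, not
a per-disease intersection: a target counts if any disease set contains
it, and its per-disease memberships are retained to become target–disease
edges later. Active compounds are those hitting at least one potential
target; compounds whose targets all fall outside disease space drop out.
These two definitions are mutually recursive invariants of the `ActiveSet`
type and are validated on construction.

## Enrichment

Over-representation uses the exact hypergeometric upper tail
`P[X ≥ k] = Σ_{i=k}^{min(K,n)} C(K,i)C(N−K,n−i)/C(N,n)`, evaluated by
summing log-binomials (`gammaln`) with `logsumexp`, so tails far below
double-precision underflow of individual terms remain accurate. When k is
at or below the support minimum the tail is exactly 1.

The background universe defaults to the union of all collection members —
the convention of the common enrichment tools — and can be overridden;
the query must be contained in it. Set sizes K are counted after
intersecting members with the background. Defaults `min_size=3`,
`max_size=500` exclude degenerate and near-universal sets. Multiplicity is
controlled by Benjamini–Hochberg step-up; filtering applies to adjusted
p-values by default, with a flag to filter on raw p instead (some screens
of this kind are reported at raw *P* < 0.05). Note the step-up map is not
idempotent as a function — re-adjusting adjusted values rescales them by
m/rank again — but its isotonic envelope is, and the property tests check
exactly that, along with rank-monotonicity and exact agreement with
`statsmodels`' `fdr_bh`.

Per-category caps (defaults 30 BP / 30 CC / 25 MF) and an explicit
exclusion list reproduce the common practice of reporting the top GO terms
per namespace and manually removing disease-irrelevant pathways; the
package makes the exclusion an explicit config item rather than encoding
any judgment of its own.

## Networks and centralities

All three networks are simple undirected graphs with role-typed nodes.
C-T-D edges are compound–target pairs restricted to active × potential
plus target–disease membership pairs; diseases never attach directly to
compounds. The T-P graph includes only the selected pathways, and targets
annotated to none of them are omitted, making each pathway's degree equal
to |members ∩ potential targets| by construction. The PPI filter keeps
edges with combined score strictly greater than the threshold (default
0.4, the medium-confidence convention for STRING-style scores; integer
0–999 scores are auto-detected on read and divided by 1000). Isolated
subset members are kept as nodes so they count toward the mean degree in
the hub screen.

Degree is reported raw; betweenness and closeness are normalized to [0,1]
the way Cytoscape's analyzer prints them: betweenness is the Brandes
pair-dependency sum over unordered pairs divided by (N_c−1)(N_c−2)/2
within each connected component (0 when the component has fewer than 3
nodes), and closeness is reachable-count over summed distances (0 for
isolated nodes). Cross-component pairs contribute nothing. A
`normalized=False` flag returns the raw sums instead. Betweenness and
closeness come from networkx, computed per component to pin the
normalization; tests verify both against an independent exhaustive
all-shortest-paths enumeration to 1e-9 on random graphs.

All screening comparisons are strictly greater-than: a node exactly at the
mean is not selected, so any regular graph yields no hubs and a set of
identical compounds yields no key compounds. Key-compound thresholds are
means over compound-role nodes only; the hub-gene threshold is the mean
degree over all PPI nodes. Selection ordering is DC descending, then BC
descending, then node id — deterministic under relabeling and edge order.
The key-pathway screen offers the same triple-above-average rule and an
explicit-list rule; the latter exists because curated pathway trios in
this literature are typically literature-informed and cannot be derived
from centralities alone (e.g. a pathway with DC below the pathway-mean DC
may still be selected on biological grounds).

## Synthetic data

The generator emulates the structure, not the content, of the database
exports: two herbs of 65 and 100 compounds sharing 2 (the study's
inventory shape); targets per compound drawn from a geometric distribution
truncated at 20 with mean 3.5, giving the heavy-tailed compound degrees
such screens report; a gene universe of 230 symbols sized so that the
expected count chain (≈210 pooled targets, ≈40 potential targets, ≈78
active compounds) sits near the study's 194/42/84; five disease sets of 60
genes each built so that a configurable fraction (default 0.20) of the
compound-hit targets is disease-linked, every linked target appears in at
least one set, and all filler comes from genes no compound hits — which
makes the generator's bookkeeping an *exact* oracle: the pipeline's
potential-target and active-compound sets must equal the planted ones,
and this is asserted at generation time. PPI scores are uniform on [0,1]
so the 0.4 filter removes a nontrivial fraction of edges.

One root seed is split into named substreams (compounds, interactions,
diseases, pathways, ppi, planted) via `numpy` seed sequences in a fixed
append-only order, so bundles are byte-reproducible across versions even
if later generator stages change.

Planted hubs receive edges up to `multiplier × expected background
degree`. On a sparse background (density ≈ 0.08) a multiplier of 5 puts
the planted degree far above the post-filter mean and recovery sensitivity
is 1.0 across seeds; at multiplier 1 the planted nodes are
indistinguishable from background and recovery sits at the base rate of
above-mean nodes. On dense backgrounds large multipliers saturate (a node
cannot exceed n−1 neighbors), so recovery experiments should use sparse
settings.

What the generator does *not* emulate: real compound chemistry and
ADME screening, true PPI topology (it is Erdős–Rényi, not scale-free),
correlated disease sets, GO DAG structure, or database version drift.
Passing tests therefore demonstrate the pipeline's arithmetic and rules
are correct, not that any particular biological conclusion transfers.

## Orchestration and determinism

Every stage serializes its output in public formats (TSV, GMT, SIF,
GraphML, JSON); the monolithic run is literally the composition of the
stage functions over a shared run directory, so stage-wise and end-to-end
execution are byte-identical by construction. Floating-point values are
written at full precision (`repr`) in intermediates and rounded to 4
decimals only in display. Reports are JSON with sorted keys; two runs with
the same config and seed produce byte-identical report files. The run
manifest records the config, its hash, the seed and the package version —
enough to reproduce the run exactly.

Problem sizes in the test and acceptance runs (bundles of 35–165
compounds, graphs of ≤ 30 nodes for oracle comparisons, 20-seed recovery
grids) were chosen so the full suite completes in well under a minute
while still exercising every rule at the study's scale where the study's
counts are the point.

## Known limitations

- Symbol normalization is a static lookup; synonym collisions or outdated
  symbols in real exports will pass through unmapped (with a warning)
  rather than being resolved.
- The published 21-compound key list is not a pure function of the stated
  rule and the published averages (one printed row falls below the stated
  closeness mean, and two printed columns appear swapped between table and
  text in the source material); the package implements the stated rule and
  treats the printed table as a fixture, without trying to reproduce the
  list membership exactly.
- The T-P "selected pathways" step accepts either enrichment output or an
  explicit list; there is no automated curation of disease relevance.
- Centralities are unweighted; PPI confidence scores gate edge inclusion
  but do not weight shortest paths.
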