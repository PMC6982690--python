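"""Network construction, centrality computation, and the threshold screens.

Three networks drive the screen:

* C-T-D — tripartite compound / target / disease graph: compound-target
  edges restricted to active compounds x potential targets, plus
  target-disease membership edges.
* T-P — bipartite graph of potential targets and the selected pathways;
  a pathway's degree equals the number of potential targets it annotates.
* PPI — protein-protein interactions among a gene subset, keeping edges
  whose combined confidence score is strictly above a threshold
  (0.4 by default, the STRING medium-confidence convention).

Centralities per node: DC is the raw degree; BC is Brandes betweenness
normalized by (Nc-1)(Nc-2)/2 within the node's connected component of size
Nc (0 when Nc < 3); CC is (reachable count) / (sum of shortest-path
distances to reachable nodes), 0 for isolated nodes. These match the
normalized values Cytoscape's network analyzer prints; raw counts are
available via a flag.

Screens (all strict inequalities): key compounds exceed the compound-role
means on all three centralities; hub genes exceed the network mean degree;
key pathways follow either the same triple-above-average rule over pathway
nodes or an explicit curated id list.
"""

from __future__ import annotations

import networkx as nx

from .models import (
    ActiveSet,
    CentralityRecord,
    GeneSetCollection,
    Network,
    Role,
    ScoredEdge,
    ScreeningThresholds,
)

__all__ = [
    "build_ctd",
    "build_tp",
    "build_ppi",
    "compute_centralities",
    "role_averages",
    "screen_key_compounds",
    "select_hub_nodes",
    "select_key_pathways",
]


def build_ctd(active: ActiveSet, compound_targets: dict[str, set[str]]) -> Network:
    """Compound-target-disease network.

    Nodes: active compounds, potential targets, and every disease set id
    referenced by a potential target. Edges: compound-target pairs
    restricted to active x potential, and target-disease membership pairs.
    Diseases connect to targets only, never directly to compounds.
    """
    net = Network()
    for c in sorted(active.active_compounds):
        net.add_node(c, Role.COMPOUND)
    for t in sorted(active.potential_targets):
        net.add_node(t, Role.TARGET)
    diseases = sorted(
        set().union(*active.target_to_diseases.values())
        if active.target_to_diseases
        else set()
    )
    for d in diseases:
        net.add_node(d, Role.DISEASE)
    for c in sorted(active.active_compounds):
        for t in sorted(compound_targets.get(c, set()) & active.potential_targets):
            net.add_edge(c, t)
    for t in sorted(active.potential_targets):
        for d in sorted(active.target_to_diseases.get(t, set())):
            net.add_edge(t, d)
    return net


def build_tp(
    potential_targets: set[str],
    pathways: GeneSetCollection,
    selected_pathways: list[str],
) -> Network:
    """Target-pathway bipartite network.

    Only the selected pathways enter; targets annotated to none of them are
    omitted, so each pathway node's degree equals |members ∩ targets|.
    """
    unknown = [p for p in selected_pathways if p not in pathways]
    if unknown:
        raise ValueError(f"unknown pathway id(s): {', '.join(unknown)}")
    net = Network()
    memberships: list[tuple[str, str]] = []
    for pid in selected_pathways:
        for t in sorted(pathways[pid].members & potential_targets):
            memberships.append((t, pid))
    for t in sorted({t for t, _ in memberships}):
        net.add_node(t, Role.TARGET)
    for pid in selected_pathways:
        if any(p == pid for _, p in memberships):
            net.add_node(pid, Role.PATHWAY)
    for t, pid in memberships:
        net.add_edge(t, pid)
    return net


def build_ppi(
    edges: list[ScoredEdge],
    node_subset: set[str],
    threshold: float = 0.4,
) -> Network:
    """PPI network on a gene subset, keeping edges with score > threshold.

    The comparison is strict. Subset members with no surviving edge are
    retained as isolated protein nodes so they still count toward the mean
    degree in the hub screen.
    """
    if not (0.0 <= threshold <= 1.0):
        raise ValueError(f"threshold {threshold} outside [0,1]")
    net = Network()
    for g in sorted(node_subset):
        net.add_node(g, Role.PROTEIN)
    for e in edges:
        if (
            e.combined_score > threshold
            and e.protein_a in node_subset
            and e.protein_b in node_subset
        ):
            net.add_edge(e.protein_a, e.protein_b)
    return net


def compute_centralities(net: Network, normalized: bool = True) -> list[CentralityRecord]:
    """DC, BC and CC for every node, in node order.

    Shortest paths are unweighted. BC and CC are computed within connected
    components; cross-component pairs contribute nothing. With
    ``normalized=False``, BC is the raw pair-dependency sum over unordered
    pairs and CC the raw sum of distances to reachable nodes (0 if none) —
    note raw CC is not bounded by 1, so the records are returned as plain
    dicts in that case.
    """
    g = net.graph
    bc: dict[str, float] = {}
    cc: dict[str, float] = {}
    for comp in nx.connected_components(g):
        sub = g.subgraph(comp)
        nc = len(comp)
        if normalized:
            if nc < 3:
                comp_bc = {n: 0.0 for n in comp}
            else:
                comp_bc = nx.betweenness_centrality(sub, normalized=True)
            # closeness: reachable count / distance sum, 0 for isolated
            comp_cc = (
                {n: 0.0 for n in comp}
                if nc == 1
                else nx.closeness_centrality(sub, wf_improved=False)
            )
        else:
            comp_bc = nx.betweenness_centrality(sub, normalized=False)
            comp_cc = {
                n: float(sum(nx.single_source_shortest_path_length(sub, n).values()))
                for n in comp
            }
        bc.update(comp_bc)
        cc.update(comp_cc)
    if not normalized:
        return [  # type: ignore[return-value]
            {"node_id": n, "role": net.role(n), "DC": g.degree(n),
             "BC": bc[n], "CC": cc[n]}
            for n in g.nodes
        ]
    return [
        CentralityRecord(node_id=n, role=net.role(n), DC=g.degree(n),
                         BC=bc[n], CC=cc[n])
        for n in g.nodes
    ]


def role_averages(
    records: list[CentralityRecord], role: Role | None
) -> ScreeningThresholds:
    """Arithmetic mean DC/BC/CC over records of one role (all roles when
    ``role`` is None), at full precision."""
    if role is not None:
        role = Role(role)
        subset = [r for r in records if r.role == role]
    else:
        subset = list(records)
    if not subset:
        raise ValueError(f"no centrality records with role {role}")
    m = len(subset)
    return ScreeningThresholds(
        mean_DC=sum(r.DC for r in subset) / m,
        mean_BC=sum(r.BC for r in subset) / m,
        mean_CC=sum(r.CC for r in subset) / m,
        role=role if role is not None else Role.PROTEIN,
    )


def _triple_above(
    records: list[CentralityRecord], thresholds: ScreeningThresholds
) -> list[CentralityRecord]:
    picked = [
        r
        for r in records
        if r.DC > thresholds.mean_DC
        and r.BC > thresholds.mean_BC
        and r.CC > thresholds.mean_CC
    ]
    picked.sort(key=lambda r: (-r.DC, -r.BC, r.node_id))
    return picked


def screen_key_compounds(
    records: list[CentralityRecord],
    thresholds: ScreeningThresholds | None = None,
) -> list[CentralityRecord]:
    """Compounds whose DC, BC and CC all strictly exceed the compound-role
    means, sorted by DC desc, BC desc, node_id."""
    compounds = [r for r in records if r.role == Role.COMPOUND]
    if thresholds is None:
        thresholds = role_averages(records, Role.COMPOUND)
    return _triple_above(compounds, thresholds)


def select_hub_nodes(records: list[CentralityRecord]) -> list[CentralityRecord]:
    """Nodes whose degree strictly exceeds the mean degree over all nodes of
    the network, sorted by DC desc (ties by node_id)."""
    if not records:
        return []
    mean_dc = sum(r.DC for r in records) / len(records)
    picked = [r for r in records if r.DC > mean_dc]
    picked.sort(key=lambda r: (-r.DC, r.node_id))
    return picked


def select_key_pathways(
    records: list[CentralityRecord],
    rule: str = "triple_above_average",
    explicit_ids: list[str] | None = None,
) -> list[str]:
    """Key pathways from pathway-role centralities.

    ``triple_above_average`` applies the same strict triple screen as key
    compounds, over pathway nodes; ``explicit`` returns a curated id list
    verbatim (literature-informed selections cannot be derived from the
    centralities alone).
    """
    if rule == "triple_above_average":
        pathway_records = [r for r in records if r.role == Role.PATHWAY]
        if not pathway_records:
            return []
        thresholds = role_averages(pathway_records, Role.PATHWAY)
        return [r.node_id for r in _triple_above(pathway_records, thresholds)]
    if rule == "explicit":
        if explicit_ids is None:
            raise ValueError("rule 'explicit' requires explicit_ids")
        return list(explicit_ids)
    raise ValueError(
        f"unknown key-pathway rule {rule!r}; use 'triple_above_average' or 'explicit'"
    )
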