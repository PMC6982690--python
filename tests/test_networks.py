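"""Network construction, centralities, and the threshold screens."""

from __future__ import annotations

import random

import networkx as nx
import pytest

from conftest import oracle_betweenness, oracle_closeness
from herbnetscreen.models import (
    ActiveSet,
    Category,
    CentralityRecord,
    GeneSet,
    GeneSetCollection,
    Network,
    Role,
    ScoredEdge,
    ScreeningThresholds,
)
from herbnetscreen.networks import (
    build_ctd,
    build_ppi,
    build_tp,
    compute_centralities,
    role_averages,
    screen_key_compounds,
    select_hub_nodes,
    select_key_pathways,
)
from herbnetscreen.reference import (
    COMPOUND_AVERAGES,
    PATHWAY_TABLE,
    key_compound_records,
    pathway_gene_sets,
    pathway_records,
)


def _star(n_leaves: int = 4) -> Network:
    net = Network()
    net.add_node("hub", Role.PROTEIN)
    for i in range(n_leaves):
        net.add_node(f"l{i}", Role.PROTEIN)
        net.add_edge("hub", f"l{i}")
    return net


def _random_net(seed: int, n_max: int = 30, p: float = 0.15) -> Network:
    rng = random.Random(seed)
    n = rng.randint(2, n_max)
    net = Network()
    for i in range(n):
        net.add_node(f"n{i}", Role.PROTEIN)
    for i in range(n):
        for j in range(i + 1, n):
            if rng.random() < p:
                net.add_edge(f"n{i}", f"n{j}")
    return net


# -------------------------------------------------------------- build_ctd


def _active(compound_targets, t2d) -> ActiveSet:
    potential = set(t2d)
    c2p = {c: ts & potential for c, ts in compound_targets.items() if ts & potential}
    return ActiveSet(
        active_compounds=set(c2p),
        potential_targets=potential,
        target_to_diseases={t: set(d) for t, d in t2d.items()},
        per_herb_targets={},
        compound_to_potential_targets=c2p,
    )


def test_ctd_empty():
    net = build_ctd(_active({}, {}), {})
    assert net.n_nodes == 0 and net.n_edges == 0


def test_ctd_hand_example():
    """c1-{T1,T2}, c2-{T1}; T1 in d1, T2 in d2: 6 nodes, 3+2 edges."""
    ct = {"c1": {"T1", "T2"}, "c2": {"T1"}}
    net = build_ctd(_active(ct, {"T1": {"d1"}, "T2": {"d2"}}), ct)
    assert net.n_nodes == 6
    assert net.n_edges == 5
    assert set(net.nodes(Role.DISEASE)) == {"d1", "d2"}
    # diseases attach to targets only
    for a, b in net.edges():
        roles = {net.role(a), net.role(b)}
        assert roles != {Role.COMPOUND, Role.DISEASE}


def test_ctd_study_scale_node_count():
    """84 active compounds + 42 targets + 5 diseases = 131 nodes."""
    rng = random.Random(0)
    targets = [f"T{i:02d}" for i in range(42)]
    ct = {}
    for i in range(84):
        ct[f"c{i:02d}"] = set(rng.sample(targets, rng.randint(1, 5)))
    # ensure every target hit at least once
    for j, t in enumerate(targets):
        ct[f"c{j % 84:02d}"].add(t)
    t2d = {t: {f"d{rng.randint(1, 5)}"} for t in targets}
    for j in range(5):
        t2d[targets[j]].add(f"d{j + 1}")
    net = build_ctd(_active(ct, t2d), ct)
    assert len(net.nodes(Role.COMPOUND)) == 84
    assert len(net.nodes(Role.TARGET)) == 42
    assert len(net.nodes(Role.DISEASE)) == 5
    assert net.n_nodes == 131


# --------------------------------------------------------------- build_tp


def test_tp_no_selection_empty():
    coll = pathway_gene_sets()
    net = build_tp({"F2"}, coll, [])
    assert net.n_nodes == 0


def test_tp_reference_gene_list_degrees():
    """The three key-pathway lists give pathway degrees 7, 5, 6."""
    coll = pathway_gene_sets()
    net = build_tp(coll.all_members(), coll, coll.ids())
    degrees = {p: net.graph.degree(p) for p in net.nodes(Role.PATHWAY)}
    assert degrees == {
        "Complement and coagulation cascades": 7,
        "Arachidonic acid metabolism": 5,
        "PI3K-Akt signaling pathway": 6,
    }


def test_tp_study_scale_node_count():
    """29 annotated targets x 7 pathways = 36 nodes."""
    rng = random.Random(1)
    targets = [f"T{i:02d}" for i in range(29)]
    sets = []
    for i in range(7):
        members = set(rng.sample(targets, rng.randint(4, 8)))
        sets.append(GeneSet(f"p{i}", "p", Category.PATHWAY, frozenset(members)))
    for j, t in enumerate(targets):  # every target annotated somewhere
        s = sets[j % 7]
        sets[j % 7] = GeneSet(s.set_id, "p", Category.PATHWAY, s.members | {t})
    coll = GeneSetCollection(sets)
    net = build_tp(set(targets) | {"UNRELATED"}, coll, coll.ids())
    assert net.n_nodes == 36
    assert len(net.nodes(Role.TARGET)) == 29


def test_tp_unknown_pathway_rejected():
    with pytest.raises(ValueError, match="unknown pathway"):
        build_tp({"F2"}, pathway_gene_sets(), ["nope"])


@pytest.mark.parametrize("seed", range(4))
def test_tp_pathway_degree_equals_intersection(seed):
    rng = random.Random(seed)
    genes = [f"G{i}" for i in range(25)]
    coll = GeneSetCollection(
        GeneSet(f"p{i}", "p", Category.PATHWAY,
                frozenset(rng.sample(genes, rng.randint(3, 10))))
        for i in range(5)
    )
    targets = set(rng.sample(genes, 12))
    net = build_tp(targets, coll, coll.ids())
    for pid in net.nodes(Role.PATHWAY):
        assert net.graph.degree(pid) == len(coll[pid].members & targets)


# -------------------------------------------------------------- build_ppi


def test_ppi_all_below_threshold_edgeless():
    edges = [ScoredEdge("A", "B", 0.2), ScoredEdge("B", "C", 0.4)]
    net = build_ppi(edges, {"A", "B", "C"}, threshold=0.4)
    assert net.n_edges == 0 and net.n_nodes == 3


def test_ppi_threshold_is_strict():
    """Scores 0.39 / 0.40 / 0.41 at threshold 0.4 keep exactly one edge."""
    edges = [
        ScoredEdge("A", "B", 0.39),
        ScoredEdge("B", "C", 0.40),
        ScoredEdge("C", "D", 0.41),
    ]
    net = build_ppi(edges, {"A", "B", "C", "D"}, threshold=0.4)
    assert net.edges() == [("C", "D")]


def test_ppi_empty_subset():
    net = build_ppi([ScoredEdge("A", "B", 0.9)], set())
    assert net.n_nodes == 0


@pytest.mark.parametrize("seed", range(3))
def test_ppi_monotone_in_threshold(seed):
    rng = random.Random(seed)
    names = [f"P{i}" for i in range(10)]
    edges = [
        ScoredEdge(a, b, rng.random())
        for a, b in [tuple(sorted(rng.sample(names, 2))) for _ in range(30)]
    ]
    subset = set(names)
    prev = None
    for thr in (0.1, 0.3, 0.5, 0.7, 0.9):
        cur = set(map(frozenset, build_ppi(edges, subset, thr).edges()))
        if prev is not None:
            assert cur <= prev
        prev = cur


# ---------------------------------------------------------- centralities


def test_star_closed_form():
    records = {r.node_id: r for r in compute_centralities(_star(4))}
    hub = records["hub"]
    assert (hub.DC, hub.BC, hub.CC) == (4, 1.0, 1.0)
    for i in range(4):
        leaf = records[f"l{i}"]
        assert leaf.BC == 0.0
        assert leaf.CC == pytest.approx(4 / 7)


def test_path_graph_closed_form():
    net = Network()
    for x in "abcd":
        net.add_node(x, Role.PROTEIN)
    net.add_edge("a", "b"); net.add_edge("b", "c"); net.add_edge("c", "d")
    rec = {r.node_id: r for r in compute_centralities(net)}
    assert rec["b"].BC == pytest.approx(2 / 3)
    assert rec["a"].CC == pytest.approx(0.5)
    assert rec["b"].CC == pytest.approx(0.75)


@pytest.mark.parametrize("n", [3, 5, 8])
def test_complete_graph(n):
    net = Network()
    for i in range(n):
        net.add_node(f"n{i}", Role.PROTEIN)
    for i in range(n):
        for j in range(i + 1, n):
            net.add_edge(f"n{i}", f"n{j}")
    for r in compute_centralities(net):
        assert r.BC == 0.0 and r.CC == 1.0 and r.DC == n - 1


def test_isolated_and_pair_components():
    net = Network()
    for x in ("a", "b", "solo"):
        net.add_node(x, Role.PROTEIN)
    net.add_edge("a", "b")
    rec = {r.node_id: r for r in compute_centralities(net)}
    assert rec["solo"].CC == 0.0 and rec["solo"].BC == 0.0
    assert rec["a"].CC == 1.0 and rec["a"].BC == 0.0


@pytest.mark.parametrize("seed", range(20))
def test_centralities_match_exhaustive_oracle(seed):
    """BC and CC agree with all-shortest-paths enumeration to 1e-9."""
    net = _random_net(seed, n_max=18)
    bc = oracle_betweenness(net.graph)
    cc = oracle_closeness(net.graph)
    for r in compute_centralities(net):
        assert r.BC == pytest.approx(bc[r.node_id], abs=1e-9)
        assert r.CC == pytest.approx(cc[r.node_id], abs=1e-9)


@pytest.mark.parametrize("seed", range(10))
def test_handshake_lemma(seed):
    net = _random_net(seed)
    records = compute_centralities(net)
    assert sum(r.DC for r in records) == 2 * net.n_edges


def test_raw_centralities_flag():
    rows = compute_centralities(_star(4), normalized=False)
    hub = next(r for r in rows if r["node_id"] == "hub")
    assert hub["BC"] == pytest.approx(6.0)  # C(4,2) leaf pairs
    assert hub["CC"] == pytest.approx(4.0)  # sum of distances


# ----------------------------------------------------------- the screens


def test_role_averages_single_record():
    rec = CentralityRecord("x", Role.PATHWAY, 3, 0.2, 0.4)
    t = role_averages([rec], Role.PATHWAY)
    assert (t.mean_DC, t.mean_BC, t.mean_CC) == (3, 0.2, 0.4)


def test_role_averages_reference_pathway_rows():
    """The seven published pathway rows average to 5.1429 / 0.3818 / 0.2141."""
    t = role_averages(pathway_records(), Role.PATHWAY)
    assert round(t.mean_DC, 4) == 5.1429
    assert round(t.mean_BC, 4) == 0.3818
    assert round(t.mean_CC, 4) == 0.2141


def test_role_averages_empty_role_rejected():
    with pytest.raises(ValueError):
        role_averages(pathway_records(), Role.COMPOUND)


def test_screen_identical_centralities_empty():
    records = [
        CentralityRecord(f"c{i}", Role.COMPOUND, 3, 0.1, 0.5) for i in range(5)
    ]
    assert screen_key_compounds(records) == []


def test_screen_oleic_acid_passes_published_averages():
    """Oleic acid (DC 17, BC 0.1394, CC 0.4577) clears the published means."""
    thresholds = ScreeningThresholds(
        mean_DC=COMPOUND_AVERAGES["mean_DC"],
        mean_BC=COMPOUND_AVERAGES["mean_BC"],
        mean_CC=COMPOUND_AVERAGES["mean_CC"],
        role=Role.COMPOUND,
    )
    picked = screen_key_compounds(key_compound_records(), thresholds)
    assert picked[0].node_id == "MOL000675"  # highest DC first


def test_screen_sorted_by_dc_then_bc():
    thresholds = ScreeningThresholds(0.0, -1.0, -1.0, Role.COMPOUND)
    records = [
        CentralityRecord("a", Role.COMPOUND, 2, 0.3, 0.5),
        CentralityRecord("b", Role.COMPOUND, 5, 0.1, 0.5),
        CentralityRecord("c", Role.COMPOUND, 5, 0.4, 0.5),
    ]
    picked = screen_key_compounds(records, thresholds)
    assert [r.node_id for r in picked] == ["c", "b", "a"]


def test_hub_regular_graph_empty():
    n = 6
    net = Network()
    for i in range(n):
        net.add_node(f"n{i}", Role.PROTEIN)
    for i in range(n):  # cycle: 2-regular
        net.add_edge(f"n{i}", f"n{(i + 1) % n}")
    assert select_hub_nodes(compute_centralities(net)) == []


def test_hub_star_center_only():
    picked = select_hub_nodes(compute_centralities(_star(4)))
    assert [r.node_id for r in picked] == ["hub"]


@pytest.mark.parametrize("seed", range(6))
def test_hub_matches_direct_recomputation(seed):
    net = _random_net(seed, n_max=20)
    records = compute_centralities(net)
    mean_dc = sum(r.DC for r in records) / len(records)
    expected = sorted(
        (r.node_id for r in records if r.DC > mean_dc),
    )
    assert sorted(r.node_id for r in select_hub_nodes(records)) == expected


def test_key_pathways_single_pathway_empty():
    records = [CentralityRecord("p1", Role.PATHWAY, 5, 0.3, 0.2)]
    assert select_key_pathways(records) == []


def test_key_pathways_reference_rows_default_rule():
    """Strict triple-above-average keeps complement cascades and PI3K-Akt."""
    picked = select_key_pathways(pathway_records())
    assert set(picked) == {
        "Complement and coagulation cascades",
        "PI3K-Akt signaling pathway",
    }


def test_key_pathways_explicit_rule_verbatim():
    ids = [
        "Complement and coagulation cascades",
        "Arachidonic acid metabolism",
        "PI3K-Akt signaling pathway",
    ]
    assert select_key_pathways([], rule="explicit", explicit_ids=ids) == ids


def test_key_pathways_unknown_rule_rejected():
    with pytest.raises(ValueError, match="rule"):
        select_key_pathways(pathway_records(), rule="bogus")


@pytest.mark.parametrize("seed", range(4))
def test_screens_invariant_to_relabeling(seed):
    """Renaming nodes permutes, but does not change, the screened sets."""
    net = _random_net(seed, n_max=15)
    records = compute_centralities(net)
    mapping = {n: f"x_{n}" for n in net.nodes()}
    renamed = Network()
    for n in net.nodes():
        renamed.add_node(mapping[n], net.role(n))
    for a, b in net.edges():
        renamed.add_edge(mapping[a], mapping[b])
    records2 = compute_centralities(renamed)
    hubs1 = {mapping[r.node_id] for r in select_hub_nodes(records)}
    hubs2 = {r.node_id for r in select_hub_nodes(records2)}
    assert hubs1 == hubs2
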