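"""Seeded generators emulating the database-derived inputs.

The real pipeline consumes live database exports (herb compound tables,
compound-target interactions, disease gene sets, pathway annotations,
scored PPI edges). This module fabricates structurally faithful stand-ins
so every stage is testable offline: two herbs with overlapping compound
lists, a many-to-many compound-target bipartite map with a skewed
targets-per-compound distribution, partially overlapping disease gene
sets, and a sparse uniformly-scored PPI graph. Ground-truth bookkeeping
(which compounds and targets were planted as "active"/"potential", which
proteins were planted as hubs) is recorded at generation time and verified
against the emitted tables, so it can serve as an exact oracle downstream.

One root seed feeds independent named substreams per table, so adding a
generator stage never perturbs earlier streams.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np

from . import io as hio
from .models import (
    Category,
    CompoundRecord,
    CompoundTable,
    GeneSet,
    GeneSetCollection,
    InteractionRecord,
    ScoredEdge,
)
from .stages import attach_targets, map_to_diseases, merge_and_deduplicate

__all__ = ["SimConfig", "SimBundle", "generate_bundle", "plant_and_recover",
           "RecoveryReport"]

# fixed substream order; append-only so existing streams stay stable
_STREAMS = ("compounds", "interactions", "diseases", "pathways", "ppi", "planted")


@dataclass
class SimConfig:
    """Generator settings.

    Defaults mirror the rougui-fuzi study conditions where those are known:
    two herbs of 65 and 100 compounds sharing 2; a skewed (truncated
    geometric) targets-per-compound distribution; five disease gene sets
    covering about a fifth of the compound-hit targets (the study's 42-of-194
    reduction); uniform PPI confidence scores so the 0.4 threshold filter is
    exercised nontrivially.
    """

    seed: int = 0
    herbs: list[tuple[str, int]] = field(
        default_factory=lambda: [("fuzi", 65), ("rougui", 100)]
    )
    n_shared_compounds: int = 2
    target_universe_size: int = 230
    targets_per_compound_mean: float = 3.5
    targets_per_compound_max: int = 20
    n_diseases: int = 5
    disease_set_size: int = 60
    overlap_fraction: float = 0.20
    n_pathways: int = 19
    pathway_size: int = 8
    ppi_edge_density: float = 0.4
    ppi_score_low: float = 0.0
    ppi_score_high: float = 1.0
    planted_hub_role: str | None = None  # "protein" or "compound"
    planted_hub_count: int = 0
    planted_hub_multiplier: float = 1.0

    def validate(self) -> None:
        if any(n < 0 for _, n in self.herbs):
            raise ValueError("herb compound counts must be non-negative")
        if self.herbs and self.n_shared_compounds > min(n for _, n in self.herbs):
            raise ValueError(
                f"n_shared_compounds={self.n_shared_compounds} exceeds the "
                f"smallest herb size {min(n for _, n in self.herbs)}"
            )
        for name in ("n_shared_compounds", "target_universe_size", "n_diseases",
                     "disease_set_size", "n_pathways", "pathway_size",
                     "planted_hub_count"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be non-negative")
        for name in ("overlap_fraction", "ppi_edge_density"):
            v = getattr(self, name)
            if not (0.0 <= v <= 1.0):
                raise ValueError(f"{name}={v} outside [0,1]")
        if self.planted_hub_role not in (None, "protein", "compound"):
            raise ValueError("planted_hub_role must be None, 'protein' or 'compound'")
        if self.planted_hub_multiplier < 0:
            raise ValueError("planted_hub_multiplier must be non-negative")


@dataclass
class SimBundle:
    """Generated tables plus ground-truth bookkeeping."""

    config: SimConfig
    compound_tables: list[CompoundTable]
    interactions: list[InteractionRecord]
    diseases: GeneSetCollection
    pathways: GeneSetCollection
    ppi_edges: list[ScoredEdge]
    truth: dict

    def write(self, outdir: str | Path) -> dict[str, Path]:
        """Serialize every table in the formats the readers consume.

        Deterministic: identical bundles produce byte-identical files.
        """
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        paths: dict[str, Path] = {}
        for table, (label, _) in zip(self.compound_tables, self.config.herbs):
            p = outdir / f"compounds_{label}.tsv"
            hio.write_compound_table(table, p)
            paths[f"compounds_{label}"] = p
        paths["interactions"] = outdir / "interactions.tsv"
        hio.write_interactions(self.interactions, paths["interactions"])
        paths["diseases"] = outdir / "diseases.gmt"
        hio.write_gmt(self.diseases, paths["diseases"])
        paths["pathways"] = outdir / "pathways.gmt"
        hio.write_gmt(self.pathways, paths["pathways"])
        paths["ppi"] = outdir / "ppi_edges.tsv"
        hio.write_scored_edges(self.ppi_edges, paths["ppi"])
        return paths


def _streams(seed: int) -> dict[str, np.random.Generator]:
    children = np.random.SeedSequence(seed).spawn(len(_STREAMS))
    return {name: np.random.default_rng(ss) for name, ss in zip(_STREAMS, children)}


def _truncated_geometric(rng: np.random.Generator, mean: float, max_k: int) -> int:
    """Geometric (support 1, 2, ...) with the stated mean, truncated above."""
    if mean <= 1.0:
        return 1
    p = 1.0 / mean
    k = int(rng.geometric(p))
    return min(k, max_k)


def generate_bundle(config: SimConfig) -> SimBundle:
    """Generate a full input bundle; deterministic for a fixed seed."""
    config.validate()
    rngs = _streams(config.seed)

    # --- compounds: shared ids first, then per-herb exclusives -------------
    n_herbs = len(config.herbs)
    shared_ids = [f"MOL{i:06d}" for i in range(1, config.n_shared_compounds + 1)]
    next_id = config.n_shared_compounds + 1
    tables: list[CompoundTable] = []
    all_ids: list[str] = list(shared_ids)
    for label, n in config.herbs:
        ids = list(shared_ids[: min(config.n_shared_compounds, n)])
        n_excl = n - len(ids)
        excl = [f"MOL{i:06d}" for i in range(next_id, next_id + n_excl)]
        next_id += n_excl
        ids.extend(excl)
        all_ids.extend(excl)
        tables.append(
            CompoundTable(
                CompoundRecord(cid, f"compound-{cid[3:].lstrip('0') or '0'}",
                               frozenset({label}))
                for cid in ids
            )
        )

    merged = merge_and_deduplicate(tables) if tables else CompoundTable()

    # --- targets / interactions -------------------------------------------
    universe = [f"G{i:04d}" for i in range(1, config.target_universe_size + 1)]
    rng_i = rngs["interactions"]
    interactions: list[InteractionRecord] = []
    planted_compounds: list[str] = []
    compound_ids = merged.ids()
    if config.planted_hub_role == "compound" and compound_ids:
        k = min(config.planted_hub_count, len(compound_ids))
        planted_compounds = sorted(
            rngs["planted"].choice(compound_ids, size=k, replace=False).tolist()
        )
    for cid in compound_ids:
        if not universe:
            break
        k = _truncated_geometric(
            rng_i, config.targets_per_compound_mean, config.targets_per_compound_max
        )
        if cid in planted_compounds:
            k = min(
                len(universe),
                max(k, int(round(config.planted_hub_multiplier
                                 * config.targets_per_compound_mean))),
            )
        k = min(k, len(universe))
        targets = rng_i.choice(universe, size=k, replace=False)
        for t in sorted(targets.tolist()):
            interactions.append(InteractionRecord(cid, t))

    hit_targets = sorted({r.target_symbol for r in interactions})

    # --- disease gene sets -------------------------------------------------
    rng_d = rngs["diseases"]
    n_linked = int(round(config.overlap_fraction * len(hit_targets)))
    linked = (
        sorted(rng_d.choice(hit_targets, size=n_linked, replace=False).tolist())
        if n_linked
        else []
    )
    non_hit = [g for g in universe if g not in set(hit_targets)]
    disease_sets: list[GeneSet] = []
    if config.n_diseases:
        # every disease-linked target lands in >=1 set (round-robin), the
        # rest of each set is filler from genes no compound hits
        assignment: dict[int, set[str]] = {i: set() for i in range(config.n_diseases)}
        for j, t in enumerate(linked):
            assignment[j % config.n_diseases].add(t)
            # targets may recur in other sets too
            extra = rng_d.random(config.n_diseases) < 0.3
            for i in np.flatnonzero(extra):
                assignment[int(i)].add(t)
        for i in range(config.n_diseases):
            members = set(assignment[i])
            n_fill = max(0, config.disease_set_size - len(members))
            n_fill = min(n_fill, len(non_hit))
            if n_fill:
                members |= set(rng_d.choice(non_hit, size=n_fill, replace=False).tolist())
            if members:
                disease_sets.append(
                    GeneSet(f"disease_{i + 1}", f"synthetic disease set {i + 1}",
                            Category.DISEASE, frozenset(members))
                )
    diseases = GeneSetCollection(disease_sets)

    # --- pathway annotation sets -------------------------------------------
    rng_p = rngs["pathways"]
    pathway_sets: list[GeneSet] = []
    for i in range(config.n_pathways):
        size = min(config.pathway_size, len(universe))
        if not size:
            continue
        # bias half of each pathway toward disease-linked targets so the
        # target-pathway network and the enrichment stage are non-trivial
        n_from_linked = min(len(linked), size // 2)
        members: set[str] = set()
        if n_from_linked:
            members |= set(rng_p.choice(linked, size=n_from_linked, replace=False).tolist())
        pool = [g for g in universe if g not in members]
        members |= set(
            rng_p.choice(pool, size=size - len(members), replace=False).tolist()
        )
        pathway_sets.append(
            GeneSet(f"pathway_{i + 1:02d}", f"synthetic pathway {i + 1}",
                    Category.PATHWAY, frozenset(members))
        )
    pathways = GeneSetCollection(pathway_sets)

    # --- PPI ----------------------------------------------------------------
    rng_ppi = rngs["ppi"]
    ppi_nodes = linked
    planted_hubs: list[str] = []
    edge_scores: dict[tuple[str, str], float] = {}

    def _score() -> float:
        return float(rng_ppi.uniform(config.ppi_score_low, config.ppi_score_high))

    for i, a in enumerate(ppi_nodes):
        for b in ppi_nodes[i + 1:]:
            if rng_ppi.random() < config.ppi_edge_density:
                edge_scores[(a, b)] = _score()
    if config.planted_hub_role == "protein" and ppi_nodes:
        k = min(config.planted_hub_count, len(ppi_nodes))
        planted_hubs = sorted(
            rngs["planted"].choice(ppi_nodes, size=k, replace=False).tolist()
        )
        base_degree = config.ppi_edge_density * max(0, len(ppi_nodes) - 1)
        want = int(round(config.planted_hub_multiplier * base_degree))
        for h in planted_hubs:
            partners = [g for g in ppi_nodes if g != h]
            rng_ppi.shuffle(partners)
            have = sum(1 for pair in edge_scores if h in pair)
            for g in partners:
                if have >= want:
                    break
                pair = (h, g) if h <= g else (g, h)
                if pair not in edge_scores:
                    edge_scores[pair] = _score()
                    have += 1
    ppi_edges = [
        ScoredEdge(a, b, s) for (a, b), s in sorted(edge_scores.items())
    ]

    # --- ground truth, verified against the tables -------------------------
    truth: dict = {
        "planted_potential_targets": linked,
        "planted_hub_proteins": planted_hubs,
        "planted_hub_compounds": planted_compounds,
        "counts": {
            "compounds_total": sum(n for _, n in config.herbs),
            "compounds_merged": len(merged),
            "targets_hit": len(hit_targets),
        },
    }
    if len(diseases) and compound_ids:
        compound_targets = attach_targets(merged, interactions)
        active = map_to_diseases(compound_targets, diseases, merged)
        if active.potential_targets != set(linked):
            raise AssertionError("bookkeeping drift: potential targets != planted")
        truth["planted_active_compounds"] = sorted(active.active_compounds)
        truth["counts"]["active_compounds"] = len(active.active_compounds)
        truth["counts"]["potential_targets"] = len(active.potential_targets)
    else:
        truth["planted_active_compounds"] = []

    return SimBundle(
        config=config,
        compound_tables=tables,
        interactions=interactions,
        diseases=diseases,
        pathways=pathways,
        ppi_edges=ppi_edges,
        truth=truth,
    )


@dataclass
class RecoveryReport:
    """Outcome of a plant-and-recover run."""

    planted: list[str]
    recovered: list[str]
    sensitivity: float
    n_selected: int

    def as_dict(self) -> dict:
        return asdict(self)


def plant_and_recover(config: SimConfig, ppi_threshold: float = 0.4) -> RecoveryReport:
    """Run the screen on a bundle with planted signal and report recovery.

    For ``planted_hub_role='protein'`` the screen is the PPI hub rule
    (degree strictly above the network mean); for ``'compound'`` it is the
    triple-above-average key-compound rule on the C-T-D network.
    Sensitivity = recovered / planted (1.0 vacuously when nothing planted).
    """
    from .networks import (
        build_ctd,
        build_ppi,
        compute_centralities,
        screen_key_compounds,
        select_hub_nodes,
    )

    bundle = generate_bundle(config)
    merged = merge_and_deduplicate(bundle.compound_tables)
    compound_targets = attach_targets(merged, bundle.interactions)
    if config.planted_hub_role == "compound":
        active = map_to_diseases(compound_targets, bundle.diseases, merged)
        net = build_ctd(active, compound_targets)
        records = compute_centralities(net)
        selected = {r.node_id for r in screen_key_compounds(records)}
        planted = bundle.truth["planted_hub_compounds"]
    else:
        subset = set(bundle.truth["planted_potential_targets"])
        net = build_ppi(bundle.ppi_edges, subset, threshold=ppi_threshold)
        records = compute_centralities(net)
        selected = {r.node_id for r in select_hub_nodes(records)}
        planted = bundle.truth["planted_hub_proteins"]
    recovered = sorted(set(planted) & selected)
    sensitivity = len(recovered) / len(planted) if planted else 1.0
    return RecoveryReport(
        planted=list(planted),
        recovered=recovered,
        sensitivity=sensitivity,
        n_selected=len(selected),
    )
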