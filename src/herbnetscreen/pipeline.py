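"""End-to-end orchestration: configuration, staged execution, reporting.

A run is a sequence of stages over a run directory; every intermediate is
serialized in the same public formats the readers consume (TSV, GMT,
GraphML, JSON), so each stage is independently inspectable and re-runnable
and the monolithic run is, by construction, the composition of the stages.
"""

from __future__ import annotations

import csv
import dataclasses
import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Any

import yaml

from . import __version__
from . import io as hio
from .enrichment import run_ora, top_terms
from .models import ActiveSet, Category, CompoundTable, Network, Role
from .networks import (
    build_ctd,
    build_ppi,
    build_tp,
    compute_centralities,
    role_averages,
    screen_key_compounds,
    select_hub_nodes,
    select_key_pathways,
)
from .stages import attach_targets, map_to_diseases, merge_and_deduplicate, stage_summary
from .synthetic import SimConfig, generate_bundle

logger = logging.getLogger(__name__)

__all__ = ["PipelineConfig", "run_all", "run_stage", "render_report", "STAGES"]

STAGES = ("simulate", "ingest", "map", "enrich", "network", "centrality", "screen")


@dataclass
class PipelineConfig:
    """Structured run configuration (YAML on disk).

    Exactly one of ``inputs`` (paths to real tables) or ``simulate``
    (generator settings) must be present.
    """

    inputs: dict[str, Any] | None = None
    simulate: dict[str, Any] | None = None
    seed: int = 0
    # enrichment settings
    alpha: float = 0.05
    filter_on: str = "p_adj"
    min_size: int = 3
    max_size: int = 500
    per_category_limits: dict[str, int] = field(
        default_factory=lambda: {"BP": 30, "CC": 30, "MF": 25}
    )
    excluded_set_ids: list[str] = field(default_factory=list)
    n_selected_pathways: int = 7
    selected_pathway_ids: list[str] | None = None
    # network settings
    ppi_threshold: float = 0.4
    key_pathway_rule: str = "triple_above_average"
    key_pathway_ids: list[str] = field(default_factory=list)

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        raw = yaml.safe_load(Path(path).read_text(encoding="utf-8")) or {}
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(raw) - known
        if unknown:
            raise ValueError(f"unknown config key(s): {', '.join(sorted(unknown))}")
        cfg = cls(**raw)
        cfg.validate(base=Path(path).parent)
        return cfg

    def validate(self, base: Path | None = None) -> None:
        if (self.inputs is None) == (self.simulate is None):
            raise ValueError("config needs exactly one of 'inputs' or 'simulate'")
        if self.inputs is not None:
            required = ("compounds", "interactions", "diseases", "pathways", "ppi")
            missing = [k for k in required if k not in self.inputs]
            if missing:
                raise ValueError(f"inputs missing key(s): {', '.join(missing)}")
            for key, value in self.inputs.items():
                paths = value if isinstance(value, list) else [value]
                for p in paths:
                    p = Path(p)
                    if base is not None and not p.is_absolute():
                        p = base / p
                    if not p.exists():
                        raise FileNotFoundError(f"input {key}: {p} does not exist")

    def sim_config(self) -> SimConfig:
        raw = dict(self.simulate or {})
        raw.setdefault("seed", self.seed)
        if "herbs" in raw:
            raw["herbs"] = [tuple(h) for h in raw["herbs"]]
        return SimConfig(**raw)

    def digest(self) -> str:
        blob = json.dumps(dataclasses.asdict(self), sort_keys=True, default=str)
        return hashlib.sha256(blob.encode()).hexdigest()[:16]


def _dump_json(obj: Any, path: Path) -> None:
    path.write_text(json.dumps(obj, indent=2, sort_keys=True) + "\n", encoding="utf-8")


def _load_json(path: Path) -> Any:
    return json.loads(path.read_text(encoding="utf-8"))


# ----------------------------------------------------------------- stages


def stage_simulate(config: PipelineConfig, rundir: Path) -> None:
    bundle = generate_bundle(config.sim_config())
    indir = rundir / "inputs"
    paths = bundle.write(indir)
    _dump_json(
        {
            "herbs": [list(h) for h in bundle.config.herbs],
            "files": {k: p.name for k, p in paths.items()},
            "truth": bundle.truth,
        },
        rundir / "simulation.json",
    )


def _input_paths(config: PipelineConfig, rundir: Path) -> dict[str, list[Path]]:
    """Resolve input files, from config paths or the simulate stage output."""
    if config.inputs is not None:
        out: dict[str, list[Path]] = {}
        for key, value in config.inputs.items():
            paths = value if isinstance(value, list) else [value]
            out[key] = [Path(p) for p in paths]
        return out
    sim = _load_json(rundir / "simulation.json")
    indir = rundir / "inputs"
    files = sim["files"]
    return {
        "compounds": [
            indir / files[k] for k in sorted(files) if k.startswith("compounds_")
        ],
        "interactions": [indir / files["interactions"]],
        "diseases": [indir / files["diseases"]],
        "pathways": [indir / files["pathways"]],
        "ppi": [indir / files["ppi"]],
    }


def stage_ingest(config: PipelineConfig, rundir: Path) -> None:
    """Read, normalize and re-serialize the input tables."""
    paths = _input_paths(config, rundir)
    symbol_map = None
    if "symbol_map" in paths:
        symbol_map = hio.read_symbol_map(paths["symbol_map"][0])
    tables = [hio.read_compound_table(p) for p in paths["compounds"]]
    merged = merge_and_deduplicate(tables)
    interactions = hio.read_interactions(paths["interactions"][0], symbol_map)
    hio.write_compound_table(merged, rundir / "merged_compounds.tsv")
    hio.write_interactions(interactions, rundir / "interactions_normalized.tsv")
    diseases = hio.read_gmt(paths["diseases"][0], Category.DISEASE, symbol_map,
                            allow_empty=True)
    pathways = hio.read_gmt(paths["pathways"][0], Category.PATHWAY, symbol_map,
                            allow_empty=True)
    hio.write_gmt(diseases, rundir / "diseases.gmt")
    hio.write_gmt(pathways, rundir / "pathways.gmt")
    edges = hio.read_scored_edges(paths["ppi"][0])
    hio.write_scored_edges(edges, rundir / "ppi_edges.tsv")


def _active_set_to_json(active: ActiveSet) -> dict:
    return {
        "active_compounds": sorted(active.active_compounds),
        "potential_targets": sorted(active.potential_targets),
        "target_to_diseases": {
            t: sorted(d) for t, d in sorted(active.target_to_diseases.items())
        },
        "per_herb_targets": {
            h: sorted(t) for h, t in sorted(active.per_herb_targets.items())
        },
        "compound_to_potential_targets": {
            c: sorted(t)
            for c, t in sorted(active.compound_to_potential_targets.items())
        },
    }


def _active_set_from_json(raw: dict) -> ActiveSet:
    return ActiveSet(
        active_compounds=set(raw["active_compounds"]),
        potential_targets=set(raw["potential_targets"]),
        target_to_diseases={t: set(d) for t, d in raw["target_to_diseases"].items()},
        per_herb_targets={h: set(t) for h, t in raw["per_herb_targets"].items()},
        compound_to_potential_targets={
            c: set(t) for c, t in raw["compound_to_potential_targets"].items()
        },
    )


def stage_map(config: PipelineConfig, rundir: Path) -> None:
    """Attach targets and intersect with the disease gene sets."""
    merged = hio.read_compound_table(rundir / "merged_compounds.tsv")
    interactions = hio.read_interactions(rundir / "interactions_normalized.tsv")
    diseases = hio.read_gmt(rundir / "diseases.gmt", Category.DISEASE)
    compound_targets = attach_targets(merged, interactions)
    active = map_to_diseases(compound_targets, diseases, merged)
    _dump_json(_active_set_to_json(active), rundir / "active_set.json")
    with (rundir / "triples.tsv").open("w", newline="", encoding="utf-8") as fh:
        writer = csv.writer(fh, delimiter="\t", lineterminator="\n")
        writer.writerow(["compound_id", "target_symbol", "disease_id"])
        for c in sorted(active.active_compounds):
            for t in sorted(active.compound_to_potential_targets.get(c, set())):
                for d in sorted(active.target_to_diseases.get(t, set())):
                    writer.writerow([c, t, d])
    summary = stage_summary(active, merged, compound_targets)
    _dump_json(summary.as_dict(), rundir / "stage_summary.json")


def stage_enrich(config: PipelineConfig, rundir: Path) -> None:
    """ORA of the potential targets against the pathway collection."""
    active = _active_set_from_json(_load_json(rundir / "active_set.json"))
    pathways = hio.read_gmt(rundir / "pathways.gmt", Category.PATHWAY)
    background = pathways.all_members() | active.potential_targets
    results = run_ora(
        active.potential_targets,
        pathways,
        background=background,
        alpha=config.alpha,
        min_size=config.min_size,
        max_size=config.max_size,
        filter_on=config.filter_on,
    )
    results = [r for r in results if r.set_id not in set(config.excluded_set_ids)]
    limits = {Category(c): v for c, v in config.per_category_limits.items()}
    results = top_terms(results, limits)
    with (rundir / "enrichment.tsv").open("w", newline="", encoding="utf-8") as fh:
        writer = csv.writer(fh, delimiter="\t", lineterminator="\n")
        writer.writerow(
            ["set_id", "category", "k", "K", "n", "N", "p_raw", "p_adj", "hits"]
        )
        for r in results:
            writer.writerow(
                [r.set_id, r.category.value, r.k, r.K, r.n, r.N,
                 repr(r.p_raw), repr(r.p_adj), ",".join(sorted(r.hits))]
            )
    if config.selected_pathway_ids is not None:
        selected = list(config.selected_pathway_ids)
    else:
        selected = [
            r.set_id
            for r in results
            if r.category == Category.PATHWAY and r.k > 0
        ][: config.n_selected_pathways]
    _dump_json({"selected_pathways": selected}, rundir / "selected_pathways.json")


def stage_network(config: PipelineConfig, rundir: Path) -> None:
    """Build the C-T-D, T-P and PPI networks and export them."""
    active = _active_set_from_json(_load_json(rundir / "active_set.json"))
    merged = hio.read_compound_table(rundir / "merged_compounds.tsv")
    interactions = hio.read_interactions(rundir / "interactions_normalized.tsv")
    compound_targets = attach_targets(merged, interactions)
    ctd = build_ctd(active, compound_targets)

    pathways = hio.read_gmt(rundir / "pathways.gmt", Category.PATHWAY)
    selected = _load_json(rundir / "selected_pathways.json")["selected_pathways"]
    tp = build_tp(active.potential_targets, pathways, selected)

    # PPI over the targets annotated to the selected pathways
    tp_targets = set(tp.nodes(Role.TARGET))
    edges = hio.read_scored_edges(rundir / "ppi_edges.tsv")
    ppi = build_ppi(edges, tp_targets, threshold=config.ppi_threshold)

    for name, net in (("ctd", ctd), ("tp", tp), ("ppi", ppi)):
        hio.write_network(net, rundir / f"{name}.graphml", "GraphML")
        hio.write_network(net, rundir / f"{name}.sif", "SIF")


def stage_centrality(config: PipelineConfig, rundir: Path) -> None:
    for name in ("ctd", "tp", "ppi"):
        net = hio.read_network(rundir / f"{name}.graphml", "GraphML")
        records = compute_centralities(net)
        hio.write_centrality_table(records, rundir / f"centrality_{name}.tsv")


def stage_screen(config: PipelineConfig, rundir: Path) -> None:
    ctd_records = hio.read_centrality_table(rundir / "centrality_ctd.tsv")
    tp_records = hio.read_centrality_table(rundir / "centrality_tp.tsv")
    ppi_records = hio.read_centrality_table(rundir / "centrality_ppi.tsv")

    compounds_present = any(r.role == Role.COMPOUND for r in ctd_records)
    thresholds = (
        role_averages(ctd_records, Role.COMPOUND) if compounds_present else None
    )
    key_compounds = (
        screen_key_compounds(ctd_records, thresholds) if compounds_present else []
    )
    hubs = select_hub_nodes(ppi_records)
    key_pathways = select_key_pathways(
        tp_records,
        rule=config.key_pathway_rule,
        explicit_ids=config.key_pathway_ids or None,
    )
    payload = {
        "key_compounds": [
            {"node_id": r.node_id, "DC": r.DC, "BC": r.BC, "CC": r.CC}
            for r in key_compounds
        ],
        "hub_genes": [
            {"node_id": r.node_id, "DC": r.DC, "BC": r.BC, "CC": r.CC}
            for r in hubs
        ],
        "key_pathways": key_pathways,
        "thresholds": {
            "compound_means": (
                {
                    "DC": thresholds.mean_DC,
                    "BC": thresholds.mean_BC,
                    "CC": thresholds.mean_CC,
                }
                if thresholds is not None
                else None
            ),
            "ppi_mean_DC": (
                sum(r.DC for r in ppi_records) / len(ppi_records)
                if ppi_records
                else None
            ),
            "ppi_score_threshold": config.ppi_threshold,
        },
    }
    _dump_json(payload, rundir / "screening.json")


_STAGE_FUNCS = {
    "simulate": stage_simulate,
    "ingest": stage_ingest,
    "map": stage_map,
    "enrich": stage_enrich,
    "network": stage_network,
    "centrality": stage_centrality,
    "screen": stage_screen,
}


def run_stage(stage: str, config: PipelineConfig, rundir: str | Path) -> None:
    """Run exactly one stage against a run directory."""
    if stage not in _STAGE_FUNCS:
        raise ValueError(f"unknown stage {stage!r}; stages are: {', '.join(STAGES)}")
    rundir = Path(rundir)
    rundir.mkdir(parents=True, exist_ok=True)
    logger.info("[%s] running", stage)
    try:
        _STAGE_FUNCS[stage](config, rundir)
    except Exception:
        (rundir / "FAILED").write_text(stage + "\n", encoding="utf-8")
        logger.error("[%s] failed", stage)
        raise
    logger.info("[%s] done", stage)


def run_all(config: PipelineConfig, rundir: str | Path) -> dict:
    """Execute every stage in order and write the final report.

    Returns the report dict; the run directory holds every intermediate
    plus ``report.json`` and a reproducibility manifest.
    """
    rundir = Path(rundir)
    rundir.mkdir(parents=True, exist_ok=True)
    stages = list(STAGES) if config.simulate is not None else [
        s for s in STAGES if s != "simulate"
    ]
    for stage in stages:
        run_stage(stage, config, rundir)
    report = render_report(rundir)
    _dump_json(report, rundir / "report.json")
    _dump_json(
        {
            "config": dataclasses.asdict(config),
            "config_digest": config.digest(),
            "seed": config.seed,
            "version": __version__,
        },
        rundir / "manifest.json",
    )
    return report


def render_report(rundir: str | Path) -> dict:
    """Assemble the human-readable run summary from the stage outputs."""
    rundir = Path(rundir)
    missing = [
        f for f in ("stage_summary.json", "screening.json", "enrichment.tsv")
        if not (rundir / f).exists()
    ]
    if missing:
        raise FileNotFoundError(
            f"incomplete run in {rundir}: missing {', '.join(missing)}"
        )
    summary = _load_json(rundir / "stage_summary.json")
    screening = _load_json(rundir / "screening.json")
    with (rundir / "enrichment.tsv").open(newline="", encoding="utf-8") as fh:
        n_enriched = sum(1 for _ in csv.DictReader(fh, delimiter="\t"))
    counts: dict[str, Any] = {"enriched_sets": n_enriched}
    for name in ("ctd", "tp", "ppi"):
        path = rundir / f"{name}.graphml"
        if path.exists():
            net = hio.read_network(path, "GraphML")
            counts[f"{name}_nodes"] = net.n_nodes
            counts[f"{name}_edges"] = net.n_edges
    return {
        "stage_summary": summary,
        "network_counts": counts,
        "screening": {
            "n_key_compounds": len(screening["key_compounds"]),
            "n_hub_genes": len(screening["hub_genes"]),
            "n_key_pathways": len(screening["key_pathways"]),
            "key_compounds": [r["node_id"] for r in screening["key_compounds"]],
            "hub_genes": [r["node_id"] for r in screening["hub_genes"]],
            "key_pathways": screening["key_pathways"],
            "thresholds": screening["thresholds"],
        },
    }
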