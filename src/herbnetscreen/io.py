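"""Readers and writers for the pipeline's external formats.

Tables are UTF-8, tab-separated, with a mandatory header row; gene sets use
the Broad GMT convention; networks export to SIF (Cytoscape) and GraphML.
"""

from __future__ import annotations

import csv
import logging
from pathlib import Path
from typing import Iterable, Sequence

import networkx as nx

from .models import (
    Category,
    CentralityRecord,
    CompoundRecord,
    CompoundTable,
    GeneSet,
    GeneSetCollection,
    InteractionRecord,
    Network,
    Role,
    ScoredEdge,
    SymbolMap,
)

logger = logging.getLogger(__name__)

__all__ = [
    "FormatError",
    "read_compound_table",
    "write_compound_table",
    "read_interactions",
    "write_interactions",
    "read_symbol_map",
    "read_gmt",
    "write_gmt",
    "read_scored_edges",
    "write_scored_edges",
    "write_network",
    "read_network",
    "write_centrality_table",
    "read_centrality_table",
]


class FormatError(ValueError):
    """A file does not conform to its declared dialect."""


def _require_columns(header: Sequence[str], required: Sequence[str], path: Path) -> None:
    missing = [c for c in required if c not in header]
    if missing:
        raise FormatError(f"{path}: missing required column(s) {', '.join(missing)}")


def read_compound_table(path: str | Path) -> CompoundTable:
    """Read a per-herb compound TSV (compound_id, name, herb).

    Rows sharing a compound_id merge into one record holding the union of
    herbs; record order is first appearance. Duplicate (compound_id, herb)
    rows are deduplicated with a warning.
    """
    path = Path(path)
    order: list[str] = []
    names: dict[str, str] = {}
    herbs: dict[str, set[str]] = {}
    seen_rows: set[tuple[str, str]] = set()
    with path.open(newline="", encoding="utf-8") as fh:
        reader = csv.DictReader(fh, delimiter="\t")
        if reader.fieldnames is None:
            raise FormatError(f"{path}: empty file, header row required")
        _require_columns(reader.fieldnames, ("compound_id", "name", "herb"), path)
        for row in reader:
            cid, name, herb = row["compound_id"], row["name"], row["herb"]
            if (cid, herb) in seen_rows:
                logger.warning("%s: duplicate row (%s, %s) dropped", path, cid, herb)
                continue
            seen_rows.add((cid, herb))
            if cid not in names:
                order.append(cid)
                names[cid] = name
                herbs[cid] = set()
            elif names[cid] != name:
                logger.warning(
                    "%s: compound %s has conflicting names %r / %r; keeping first",
                    path, cid, names[cid], name,
                )
            herbs[cid].add(herb)
    return CompoundTable(
        CompoundRecord(cid, names[cid], frozenset(herbs[cid])) for cid in order
    )


def write_compound_table(table: CompoundTable, path: str | Path) -> None:
    """Write one row per (compound, herb), herbs in sorted order."""
    path = Path(path)
    with path.open("w", newline="", encoding="utf-8") as fh:
        writer = csv.writer(fh, delimiter="\t", lineterminator="\n")
        writer.writerow(["compound_id", "name", "herb"])
        for rec in table:
            for herb in sorted(rec.herbs):
                writer.writerow([rec.compound_id, rec.name, herb])


def read_interactions(
    path: str | Path, symbol_map: SymbolMap | None = None
) -> list[InteractionRecord]:
    """Read a compound-target TSV (compound_id, target_symbol).

    Symbols are normalized through ``symbol_map`` (pass-through uppercasing
    when none is given); duplicate pairs after normalization collapse.
    """
    path = Path(path)
    symbol_map = symbol_map or SymbolMap()
    out: list[InteractionRecord] = []
    seen: set[tuple[str, str]] = set()
    with path.open(newline="", encoding="utf-8") as fh:
        reader = csv.DictReader(fh, delimiter="\t")
        if reader.fieldnames is None:
            raise FormatError(f"{path}: empty file, header row required")
        _require_columns(reader.fieldnames, ("compound_id", "target_symbol"), path)
        for row in reader:
            sym = symbol_map.normalize(row["target_symbol"])
            key = (row["compound_id"], sym)
            if key in seen:
                continue
            seen.add(key)
            out.append(InteractionRecord(row["compound_id"], sym))
    return out


def write_interactions(records: Iterable[InteractionRecord], path: str | Path) -> None:
    with Path(path).open("w", newline="", encoding="utf-8") as fh:
        writer = csv.writer(fh, delimiter="\t", lineterminator="\n")
        writer.writerow(["compound_id", "target_symbol"])
        for rec in records:
            writer.writerow([rec.compound_id, rec.target_symbol])


def read_symbol_map(path: str | Path) -> SymbolMap:
    """Read a raw-name -> official-symbol TSV (raw_name, official_symbol)."""
    path = Path(path)
    mapping: dict[str, str] = {}
    with path.open(newline="", encoding="utf-8") as fh:
        reader = csv.DictReader(fh, delimiter="\t")
        if reader.fieldnames is None:
            raise FormatError(f"{path}: empty file, header row required")
        _require_columns(reader.fieldnames, ("raw_name", "official_symbol"), path)
        for row in reader:
            raw = row["raw_name"]
            if raw in mapping and mapping[raw] != row["official_symbol"].upper():
                raise FormatError(f"{path}: raw name {raw!r} maps to two symbols")
            mapping[raw] = row["official_symbol"]
    return SymbolMap(mapping)


def read_gmt(
    path: str | Path,
    category: Category | str = Category.PATHWAY,
    symbol_map: SymbolMap | None = None,
    allow_empty: bool = False,
) -> GeneSetCollection:
    """Read a GMT file: ``set_id TAB description TAB member1 TAB ...``.

    All sets get the supplied ``category``; members are normalized through
    ``symbol_map`` when one is given (plain uppercasing otherwise) and
    within-line duplicates collapse.
    """
    path = Path(path)
    category = Category(category)
    sets: list[GeneSet] = []
    with path.open(encoding="utf-8") as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line:
                continue
            fields = line.split("\t")
            if len(fields) < 3:
                raise FormatError(
                    f"{path}:{lineno}: GMT line needs >=3 tab-separated fields"
                )
            set_id, description, *raw_members = fields
            if symbol_map is not None:
                members = frozenset(symbol_map.normalize(m) for m in raw_members if m)
            else:
                members = frozenset(m.upper() for m in raw_members if m)
            if not members and not allow_empty:
                raise FormatError(f"{path}:{lineno}: gene set {set_id!r} has no members")
            sets.append(GeneSet(set_id, description, category, members))
    return GeneSetCollection(sets)


def write_gmt(collection: GeneSetCollection, path: str | Path) -> None:
    """Write GMT with members in sorted order (deterministic on disk)."""
    with Path(path).open("w", encoding="utf-8") as fh:
        for gs in collection:
            fields = [gs.set_id, gs.description, *sorted(gs.members)]
            fh.write("\t".join(fields) + "\n")


def read_scored_edges(path: str | Path) -> list[ScoredEdge]:
    """Read a STRING-style scored edge TSV (protein_a, protein_b, combined_score).

    Pairs are canonicalized (lexicographic endpoint order); duplicate pairs
    keep the maximum score. STRING's 0-999 integer score dialect is
    auto-detected (any score > 1) and divided by 1000.
    """
    path = Path(path)
    rows: list[tuple[str, str, float]] = []
    with path.open(newline="", encoding="utf-8") as fh:
        reader = csv.DictReader(fh, delimiter="\t")
        if reader.fieldnames is None:
            raise FormatError(f"{path}: empty file, header row required")
        _require_columns(reader.fieldnames, ("protein_a", "protein_b", "combined_score"), path)
        for row in reader:
            try:
                score = float(row["combined_score"])
            except ValueError as exc:
                raise FormatError(f"{path}: unparseable score {row['combined_score']!r}") from exc
            rows.append((row["protein_a"], row["protein_b"], score))
    if any(s > 1.0 for _, _, s in rows):
        if any(s < 0.0 or s > 999.0 for _, _, s in rows):
            bad = [s for _, _, s in rows if s < 0.0 or s > 999.0]
            raise FormatError(f"{path}: scores outside both [0,1] and 0-999 dialects: {bad[:3]}")
        logger.info("%s: integer-scale scores detected; dividing by 1000", path)
        rows = [(a, b, s / 1000.0) for a, b, s in rows]
    if any(s < 0.0 for _, _, s in rows):
        raise FormatError(f"{path}: negative combined_score")
    best: dict[tuple[str, str], float] = {}
    order: list[tuple[str, str]] = []
    for a, b, s in rows:
        pair = (a, b) if a <= b else (b, a)
        if pair not in best:
            order.append(pair)
            best[pair] = s
        else:
            best[pair] = max(best[pair], s)
    return [ScoredEdge(a, b, best[(a, b)]) for a, b in order]


def write_scored_edges(edges: Iterable[ScoredEdge], path: str | Path) -> None:
    with Path(path).open("w", newline="", encoding="utf-8") as fh:
        writer = csv.writer(fh, delimiter="\t", lineterminator="\n")
        writer.writerow(["protein_a", "protein_b", "combined_score"])
        for e in edges:
            writer.writerow([e.protein_a, e.protein_b, repr(e.combined_score)])


_SIF_SUFFIX = {".sif"}


def write_network(net: Network, path: str | Path, format: str | None = None) -> None:
    """Export a network to SIF or GraphML.

    SIF lines read ``a <rolepair> b`` (e.g. ``compound-target``); isolated
    nodes are written as bare single-field lines, per Cytoscape convention.
    GraphML carries the role as a node attribute and round-trips exactly.
    """
    path = Path(path)
    if format is None:
        format = "SIF" if path.suffix.lower() in _SIF_SUFFIX else "GraphML"
    fmt = format.lower()
    if fmt == "sif":
        lines = []
        connected: set[str] = set()
        for a, b in sorted(net.edges()):
            ra, rb = net.role(a).value, net.role(b).value
            # orient the relation label consistently: sort by role name
            if ra <= rb:
                lines.append(f"{a}\t{ra}-{rb}\t{b}")
            else:
                lines.append(f"{b}\t{rb}-{ra}\t{a}")
            connected |= {a, b}
        for n in sorted(set(net.nodes()) - connected):
            lines.append(n)
        path.write_text("\n".join(lines) + ("\n" if lines else ""), encoding="utf-8")
    elif fmt == "graphml":
        g = nx.Graph()
        for n in net.nodes():
            g.add_node(n, role=net.role(n).value)
        g.add_edges_from(net.edges())
        nx.write_graphml(g, path)
    else:
        raise ValueError(f"unknown network format {format!r}; use SIF or GraphML")


def read_network(path: str | Path, format: str | None = None) -> Network:
    """Read a network back from SIF or GraphML.

    SIF relation labels encode the role pair, so roles are recoverable;
    GraphML carries them as node attributes.
    """
    path = Path(path)
    if format is None:
        format = "SIF" if path.suffix.lower() in _SIF_SUFFIX else "GraphML"
    fmt = format.lower()
    net = Network()
    if fmt == "sif":
        for line in path.read_text(encoding="utf-8").splitlines():
            if not line.strip():
                continue
            fields = line.split("\t")
            if len(fields) == 1:
                # isolated node: role unknown from SIF alone; default protein
                net.add_node(fields[0], Role.PROTEIN)
            elif len(fields) >= 3:
                a, relation, b = fields[0], fields[1], fields[2]
                role_a, role_b = relation.split("-", 1)
                net.add_node(a, Role(role_a))
                net.add_node(b, Role(role_b))
                net.add_edge(a, b)
            else:
                raise FormatError(f"{path}: malformed SIF line {line!r}")
    elif fmt == "graphml":
        g = nx.read_graphml(path)
        for n, data in g.nodes(data=True):
            net.add_node(str(n), Role(data["role"]))
        for a, b in g.edges():
            net.add_edge(str(a), str(b))
    else:
        raise ValueError(f"unknown network format {format!r}; use SIF or GraphML")
    return net


def write_centrality_table(records: Iterable[CentralityRecord], path: str | Path) -> None:
    """TSV with columns node_id, role, DC, BC, CC (full float precision)."""
    with Path(path).open("w", newline="", encoding="utf-8") as fh:
        writer = csv.writer(fh, delimiter="\t", lineterminator="\n")
        writer.writerow(["node_id", "role", "DC", "BC", "CC"])
        for rec in records:
            writer.writerow([rec.node_id, rec.role.value, rec.DC, repr(rec.BC), repr(rec.CC)])


def read_centrality_table(path: str | Path) -> list[CentralityRecord]:
    path = Path(path)
    out: list[CentralityRecord] = []
    with path.open(newline="", encoding="utf-8") as fh:
        reader = csv.DictReader(fh, delimiter="\t")
        if reader.fieldnames is None:
            raise FormatError(f"{path}: empty file, header row required")
        _require_columns(reader.fieldnames, ("node_id", "role", "DC", "BC", "CC"), path)
        for row in reader:
            out.append(
                CentralityRecord(
                    node_id=row["node_id"],
                    role=Role(row["role"]),
                    DC=int(row["DC"]),
                    BC=float(row["BC"]),
                    CC=float(row["CC"]),
                )
            )
    return out
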