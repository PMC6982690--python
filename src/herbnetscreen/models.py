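"""Domain types for the herb-pair network-pharmacology screen.

The pipeline's currency is small, explicit value objects: compound and
interaction rows as they come out of TCMSP-style exports, named gene sets
(diseases, GO terms, pathways), scored protein-protein edges, and a simple
undirected network whose nodes carry a biological role.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from enum import Enum
from typing import Iterable, Iterator, Mapping

import networkx as nx

__all__ = [
    "Role",
    "Category",
    "CompoundRecord",
    "CompoundTable",
    "InteractionRecord",
    "SymbolMap",
    "GeneSet",
    "GeneSetCollection",
    "ScoredEdge",
    "Network",
    "ActiveSet",
    "EnrichmentResult",
    "CentralityRecord",
    "ScreeningThresholds",
    "ScreeningResult",
]


class Role(str, Enum):
    """Biological role of a network node."""

    COMPOUND = "compound"
    TARGET = "target"
    DISEASE = "disease"
    PATHWAY = "pathway"
    PROTEIN = "protein"


class Category(str, Enum):
    """Gene-set category: the three GO namespaces, pathways, and diseases."""

    BP = "BP"
    CC = "CC"
    MF = "MF"
    PATHWAY = "PATHWAY"
    DISEASE = "DISEASE"


@dataclass(frozen=True)
class CompoundRecord:
    """One herb-pair compound: a stable id (TCMSP MOL style), a display
    name, and the set of herbs it was listed under."""

    compound_id: str
    name: str
    herbs: frozenset[str]

    def __post_init__(self) -> None:
        if not self.compound_id:
            raise ValueError("compound_id must be non-empty")
        if not self.herbs:
            raise ValueError(f"compound {self.compound_id!r}: herbs must be non-empty")


class CompoundTable:
    """Ordered collection of :class:`CompoundRecord`, unique by compound_id.

    Order is first-appearance order, which the readers and mergers preserve.
    """

    def __init__(self, records: Iterable[CompoundRecord] = ()) -> None:
        self._records: dict[str, CompoundRecord] = {}
        for rec in records:
            if rec.compound_id in self._records:
                raise ValueError(f"duplicate compound_id {rec.compound_id!r}")
            self._records[rec.compound_id] = rec

    def __len__(self) -> int:
        return len(self._records)

    def __iter__(self) -> Iterator[CompoundRecord]:
        return iter(self._records.values())

    def __contains__(self, compound_id: str) -> bool:
        return compound_id in self._records

    def __getitem__(self, compound_id: str) -> CompoundRecord:
        return self._records[compound_id]

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, CompoundTable):
            return NotImplemented
        return list(self) == list(other)

    def ids(self) -> list[str]:
        return list(self._records)

    def herbs(self) -> set[str]:
        out: set[str] = set()
        for rec in self:
            out |= rec.herbs
        return out


@dataclass(frozen=True)
class InteractionRecord:
    """One compound-target edge (gene symbol already official/uppercase)."""

    compound_id: str
    target_symbol: str

    def __post_init__(self) -> None:
        if not self.compound_id or not self.target_symbol:
            raise ValueError("compound_id and target_symbol must be non-empty")


class SymbolMap:
    """Raw protein/gene name -> official symbol lookup.

    Stands in for the manual UniProt correction step: a plain table. Unmapped
    names pass through uppercased (callers may log a warning).
    """

    def __init__(self, mapping: Mapping[str, str] | None = None) -> None:
        self._map: dict[str, str] = {}
        if mapping:
            for raw, sym in mapping.items():
                self._map[raw] = sym.upper()

    def normalize(self, raw: str) -> str:
        return self._map.get(raw, raw.upper())

    def __len__(self) -> int:
        return len(self._map)

    def __contains__(self, raw: str) -> bool:
        return raw in self._map


@dataclass(frozen=True)
class GeneSet:
    """A named gene set: disease gene list, GO term, or pathway."""

    set_id: str
    description: str
    category: Category
    members: frozenset[str]

    def __post_init__(self) -> None:
        if not self.set_id:
            raise ValueError("set_id must be non-empty")

    def __len__(self) -> int:
        return len(self.members)


class GeneSetCollection:
    """Ordered list of :class:`GeneSet` with unique ids and an optional
    explicit background universe."""

    def __init__(
        self,
        sets: Iterable[GeneSet] = (),
        background: frozenset[str] | None = None,
    ) -> None:
        self._sets: dict[str, GeneSet] = {}
        for gs in sets:
            if gs.set_id in self._sets:
                raise ValueError(f"duplicate set_id {gs.set_id!r}")
            self._sets[gs.set_id] = gs
        self.background = background

    def __len__(self) -> int:
        return len(self._sets)

    def __iter__(self) -> Iterator[GeneSet]:
        return iter(self._sets.values())

    def __contains__(self, set_id: str) -> bool:
        return set_id in self._sets

    def __getitem__(self, set_id: str) -> GeneSet:
        return self._sets[set_id]

    def ids(self) -> list[str]:
        return list(self._sets)

    def all_members(self) -> set[str]:
        out: set[str] = set()
        for gs in self:
            out |= gs.members
        return out


@dataclass(frozen=True)
class ScoredEdge:
    """STRING-style protein pair with a combined confidence score in [0,1].

    Endpoints are stored lexicographically ordered so the unordered pair is
    canonical.
    """

    protein_a: str
    protein_b: str
    combined_score: float

    def __post_init__(self) -> None:
        if self.protein_a == self.protein_b:
            raise ValueError(f"self-loop on {self.protein_a!r}")
        if not (0.0 <= self.combined_score <= 1.0):
            raise ValueError(f"combined_score {self.combined_score} outside [0,1]")
        if self.protein_a > self.protein_b:
            a, b = self.protein_b, self.protein_a
            object.__setattr__(self, "protein_a", a)
            object.__setattr__(self, "protein_b", b)

    @property
    def pair(self) -> tuple[str, str]:
        return (self.protein_a, self.protein_b)


class Network:
    """Undirected simple graph with role-typed nodes.

    Thin wrapper around :class:`networkx.Graph`; the wrapper enforces the
    invariants the screening rules rely on (no self-loops, declared
    endpoints, one role per node id).
    """

    def __init__(self) -> None:
        self.graph = nx.Graph()

    def add_node(self, node_id: str, role: Role) -> None:
        existing = self.graph.nodes.get(node_id)
        if existing is not None and existing["role"] != Role(role):
            raise ValueError(
                f"node {node_id!r} already declared with role {existing['role']}"
            )
        self.graph.add_node(node_id, role=Role(role))

    def add_edge(self, a: str, b: str) -> None:
        if a == b:
            raise ValueError(f"self-loop on {a!r}")
        for end in (a, b):
            if end not in self.graph:
                raise ValueError(f"edge endpoint {end!r} is not a declared node")
        self.graph.add_edge(a, b)

    def role(self, node_id: str) -> Role:
        return self.graph.nodes[node_id]["role"]

    def nodes(self, role: Role | None = None) -> list[str]:
        if role is None:
            return list(self.graph.nodes)
        role = Role(role)
        return [n for n, d in self.graph.nodes(data=True) if d["role"] == role]

    def edges(self) -> list[tuple[str, str]]:
        return [tuple(sorted(e)) for e in self.graph.edges]

    @property
    def n_nodes(self) -> int:
        return self.graph.number_of_nodes()

    @property
    def n_edges(self) -> int:
        return self.graph.number_of_edges()

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, Network):
            return NotImplemented
        return (
            set(self.graph.nodes) == set(other.graph.nodes)
            and all(self.role(n) == other.role(n) for n in self.graph.nodes)
            and {frozenset(e) for e in self.graph.edges}
            == {frozenset(e) for e in other.graph.edges}
        )


@dataclass
class ActiveSet:
    """Stage-2 output: compounds and targets surviving the disease mapping.

    potential_targets = (union of compound target sets) intersected with the
    union of the disease gene sets; active_compounds = compounds hitting at
    least one potential target.
    """

    active_compounds: set[str]
    potential_targets: set[str]
    target_to_diseases: dict[str, set[str]]
    per_herb_targets: dict[str, set[str]]
    compound_to_potential_targets: dict[str, set[str]] = field(default_factory=dict)

    def validate(self) -> None:
        for t in self.potential_targets:
            if not self.target_to_diseases.get(t):
                raise ValueError(f"potential target {t!r} maps to no disease set")
        hit = set()
        for c in self.active_compounds:
            targets = self.compound_to_potential_targets.get(c, set())
            if not targets & self.potential_targets:
                raise ValueError(f"active compound {c!r} hits no potential target")
            hit |= targets
        if self.active_compounds and hit & self.potential_targets != self.potential_targets:
            raise ValueError("some potential targets are hit by no active compound")


@dataclass(frozen=True)
class EnrichmentResult:
    """One gene set's over-representation statistics.

    k of the n query genes fall in the set, which covers K of the N
    background genes; p_raw is the hypergeometric upper tail P[X >= k],
    p_adj its Benjamini-Hochberg adjustment across the collection.
    """

    set_id: str
    category: Category
    k: int
    K: int
    n: int
    N: int
    p_raw: float
    p_adj: float
    hits: frozenset[str]

    def __post_init__(self) -> None:
        if not (0 <= self.k <= min(self.K, self.n) and self.K <= self.N and self.n <= self.N):
            raise ValueError(
                f"{self.set_id}: inconsistent counts k={self.k} K={self.K} "
                f"n={self.n} N={self.N}"
            )
        if self.p_adj < self.p_raw - 1e-12:
            raise ValueError(f"{self.set_id}: p_adj {self.p_adj} < p_raw {self.p_raw}")


@dataclass(frozen=True)
class CentralityRecord:
    """Per-node degree (raw count), betweenness and closeness (normalized)."""

    node_id: str
    role: Role
    DC: int
    BC: float
    CC: float

    def __post_init__(self) -> None:
        if self.DC < 0:
            raise ValueError("degree must be non-negative")
        for label, v in (("BC", self.BC), ("CC", self.CC)):
            if not (-1e-12 <= v <= 1.0 + 1e-12) or math.isnan(v):
                raise ValueError(f"{label}={v} outside [0,1]")


@dataclass(frozen=True)
class ScreeningThresholds:
    """Role-wise mean centralities; the screens compare strictly above."""

    mean_DC: float
    mean_BC: float
    mean_CC: float
    role: Role


@dataclass
class ScreeningResult:
    """Final screen: key compounds, hub genes, key pathways, and the
    thresholds that produced them."""

    key_compounds: list[CentralityRecord]
    hub_genes: list[CentralityRecord]
    key_pathways: list[str]
    compound_thresholds: ScreeningThresholds | None = None
    hub_threshold: float | None = None
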