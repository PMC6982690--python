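"""Stage 1-2 of the screen: merge herb compound lists, attach targets, and
intersect with disease gene sets.

The herb pair's compound inventories overlap (shared constituents) and the
compound-target map is many-to-many: one compound can hit several targets
and one target can be hit by several compounds. "Potential targets" are the
compound-hit genes that also appear in at least one disease gene set;
"active compounds" are the compounds hitting at least one potential target.
"""

from __future__ import annotations

import logging
from collections import Counter
from dataclasses import dataclass

from .models import (
    ActiveSet,
    Category,
    CompoundRecord,
    CompoundTable,
    GeneSetCollection,
    InteractionRecord,
)

logger = logging.getLogger(__name__)

__all__ = ["merge_and_deduplicate", "attach_targets", "map_to_diseases",
           "stage_summary", "StageSummary"]


def merge_and_deduplicate(tables: list[CompoundTable]) -> CompoundTable:
    """Union compound tables by compound_id, merging herb sets.

    Deduplication keys on the stable compound_id, never the display name
    (names for the same MOL id vary between herb exports); on a name clash
    the first-seen name wins with a warning. Idempotent, and commutative up
    to record order.
    """
    order: list[str] = []
    names: dict[str, str] = {}
    herbs: dict[str, set[str]] = {}
    for table in tables:
        for rec in table:
            if rec.compound_id not in names:
                order.append(rec.compound_id)
                names[rec.compound_id] = rec.name
                herbs[rec.compound_id] = set(rec.herbs)
            else:
                if names[rec.compound_id] != rec.name:
                    logger.warning(
                        "compound %s: conflicting names %r / %r; keeping first",
                        rec.compound_id, names[rec.compound_id], rec.name,
                    )
                herbs[rec.compound_id] |= rec.herbs
    return CompoundTable(
        CompoundRecord(cid, names[cid], frozenset(herbs[cid])) for cid in order
    )


def attach_targets(
    compounds: CompoundTable, interactions: list[InteractionRecord]
) -> dict[str, set[str]]:
    """Join compound-target interactions onto the compound table.

    Every compound in the table appears as a key (empty set when it has no
    interaction — such compounds drop out later at the disease mapping).
    Interactions referencing unknown compound ids are logged and dropped.
    """
    out: dict[str, set[str]] = {rec.compound_id: set() for rec in compounds}
    dropped = 0
    for rec in interactions:
        if rec.compound_id not in out:
            dropped += 1
            continue
        out[rec.compound_id].add(rec.target_symbol)
    if dropped:
        logger.warning("dropped %d interaction(s) referencing unknown compounds", dropped)
    return out


def per_herb_targets(
    compounds: CompoundTable, compound_targets: dict[str, set[str]]
) -> dict[str, set[str]]:
    """Union of target sets over each herb's compounds."""
    out: dict[str, set[str]] = {herb: set() for herb in compounds.herbs()}
    for rec in compounds:
        for herb in rec.herbs:
            out[herb] |= compound_targets.get(rec.compound_id, set())
    return out


def map_to_diseases(
    compound_targets: dict[str, set[str]],
    diseases: GeneSetCollection,
    compounds: CompoundTable | None = None,
) -> ActiveSet:
    """Intersect compound-hit targets with the pooled disease gene sets.

    The disease union (not a per-disease intersection) defines the potential
    targets; per-disease membership is kept for the target-disease edges of
    the compound-target-disease network.
    """
    if len(diseases) == 0:
        raise ValueError("disease collection is empty; nothing to map against")
    for gs in diseases:
        if gs.category != Category.DISEASE:
            raise ValueError(f"gene set {gs.set_id!r} has category {gs.category}, "
                             "expected DISEASE")
    disease_union = diseases.all_members()
    all_hit = set().union(*compound_targets.values()) if compound_targets else set()
    potential = all_hit & disease_union
    c2p = {
        cid: targets & potential
        for cid, targets in compound_targets.items()
        if targets & potential
    }
    active = set(c2p)
    t2d = {
        t: {gs.set_id for gs in diseases if t in gs.members}
        for t in potential
    }
    herb_targets = (
        per_herb_targets(compounds, compound_targets) if compounds is not None else {}
    )
    aset = ActiveSet(
        active_compounds=active,
        potential_targets=potential,
        target_to_diseases=t2d,
        per_herb_targets=herb_targets,
        compound_to_potential_targets=c2p,
    )
    aset.validate()
    return aset


@dataclass(frozen=True)
class StageSummary:
    """Counts echoing the stage-1/2 narrative."""

    compounds_per_herb: dict[str, int]
    merged_compounds: int
    targets_per_herb: dict[str, int]
    common_targets: int
    pooled_targets: int
    active_compounds: int
    potential_targets: int

    def as_dict(self) -> dict:
        return {
            "compounds_per_herb": dict(sorted(self.compounds_per_herb.items())),
            "merged_compounds": self.merged_compounds,
            "targets_per_herb": dict(sorted(self.targets_per_herb.items())),
            "common_targets": self.common_targets,
            "pooled_targets": self.pooled_targets,
            "active_compounds": self.active_compounds,
            "potential_targets": self.potential_targets,
        }


def stage_summary(
    active: ActiveSet,
    compounds: CompoundTable | None = None,
    compound_targets: dict[str, set[str]] | None = None,
) -> StageSummary:
    """Count table for reports.

    ``pooled_targets`` is the size of the union of all compound target sets;
    with two herbs it satisfies the inclusion-exclusion identity
    |A| + |B| - |A ∩ B|.
    """
    per_herb_compounds: Counter[str] = Counter()
    if compounds is not None:
        for rec in compounds:
            for herb in rec.herbs:
                per_herb_compounds[herb] += 1
    pooled = (
        len(set().union(*compound_targets.values())) if compound_targets else 0
    )
    herb_t = active.per_herb_targets
    common = 0
    if len(herb_t) == 2:
        a, b = herb_t.values()
        common = len(a & b)
    elif len(herb_t) > 2:
        common = len(set.intersection(*herb_t.values()))
    return StageSummary(
        compounds_per_herb=dict(per_herb_compounds),
        merged_compounds=len(compounds) if compounds is not None else 0,
        targets_per_herb={h: len(t) for h, t in herb_t.items()},
        common_targets=common,
        pooled_targets=pooled,
        active_compounds=len(active.active_compounds),
        potential_targets=len(active.potential_targets),
    )
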