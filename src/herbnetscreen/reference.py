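"""Published reference values for the rougui-fuzi CCVD screen.

These are the curated, desk-checkable outputs of the original database
screen of the cinnamon-twig / aconite herb pair against cardio- and
cerebrovascular disease (CCVD) gene sets: the 21 key compounds with their
C-T-D centralities, the 7 selected pathways with their T-P centralities,
the 8 PPI hub genes, the three key-pathway gene lists, and the headline
counts of every stage. They serve as fixtures: the live database snapshots
behind them are not redistributable, but the printed numbers let the
screening arithmetic (averages, threshold rules, network degrees) be
verified exactly.
"""

from __future__ import annotations

import json
from pathlib import Path

from . import io as hio
from .models import (
    Category,
    CentralityRecord,
    GeneSet,
    GeneSetCollection,
    Role,
)

__all__ = [
    "KEY_COMPOUND_TABLE",
    "PATHWAY_TABLE",
    "HUB_GENE_TABLE",
    "PATHWAY_GENE_SETS",
    "REFERENCE_COUNTS",
    "key_compound_records",
    "pathway_records",
    "hub_gene_records",
    "pathway_gene_sets",
    "emit_reference_fixture",
]

# 21 key compounds: (MOL id, name, DC, BC, CC) from the C-T-D network.
KEY_COMPOUND_TABLE: list[tuple[str, str, int, float, float]] = [
    ("MOL000675", "Oleic acid", 17, 0.1394, 0.4577),
    ("MOL002526", "delta-Guaijene", 8, 0.0242, 0.304),
    ("MOL000911", "Terpilene", 8, 0.0248, 0.3916),
    ("MOL000126", "(-)-Nopinene", 6, 0.0398, 0.4362),
    ("MOL000069", "Palmitic acid", 6, 0.0332, 0.3779),
    ("MOL000118", "(L)-Alpha-terpineol", 5, 0.0119, 0.3892),
    ("MOL000254", "Eugenol", 5, 0.0297, 0.4305),
    ("MOL003521", "Isohomogenol", 5, 0.0083, 0.3869),
    ("MOL000677", "(1R,4R)-4-Isopropyl-1,6-dimethyltetralin", 5, 0.0067, 0.3916),
    ("MOL002392", "Deltoin", 5, 0.0093, 0.3916),
    ("MOL002417", "Fuzitine", 5, 0.0086, 0.3801),
    ("MOL000431", "Coumarin", 5, 0.0127, 0.3757),
    ("MOL003525", "Pyruvophenone", 5, 0.0253, 0.3631),
    ("MOL000198", "(R)-Linalool", 4, 0.0075, 0.3736),
    ("MOL000131", "Linoleic acid", 4, 0.0181, 0.414),
    ("MOL001393", "Myristic acid", 4, 0.0146, 0.3693),
    ("MOL000932", "Alpha-farnesene", 4, 0.0121, 0.3652),
    ("MOL000991", "Cinnamaldehyde", 4, 0.0121, 0.3652),
    ("MOL002295", "Cinnamic acid", 3, 0.0141, 0.4037),
    ("MOL000249", "Methylcinnamate", 3, 0.0141, 0.4037),
    ("MOL003531", "3-Methoxycinnamaldehyde", 3, 0.0141, 0.4037),
]

# 7 selected CCVD pathways: (name, DC, BC, CC) from the T-P network.
PATHWAY_TABLE: list[tuple[str, int, float, float]] = [
    ("Complement and coagulation cascades", 7, 0.5017, 0.2381),
    ("Neuroactive ligand-receptor interaction", 6, 0.2193, 0.1795),
    ("PI3K-Akt signaling pathway", 6, 0.5513, 0.2518),
    ("Arachidonic acid metabolism", 5, 0.2185, 0.2000),
    ("Cholesterol metabolism", 4, 0.1664, 0.1515),
    ("PPAR signaling pathway", 4, 0.3479, 0.1977),
    ("NF-kappa B signaling pathway", 4, 0.6673, 0.2800),
]

# 8 hub genes: (symbol, DC, BC, CC) from the PPI network.
HUB_GENE_TABLE: list[tuple[str, int, float, float]] = [
    ("PTGS2", 14, 0.2411, 0.8500),
    ("INS", 12, 0.1764, 0.7727),
    ("IL4", 11, 0.0701, 0.7391),
    ("TLR4", 11, 0.0734, 0.7391),
    ("F3", 10, 0.0361, 0.7083),
    ("PLG", 10, 0.0361, 0.7083),
    ("SERPINE1", 10, 0.0361, 0.7083),
    ("F2", 9, 0.0275, 0.6800),
]

# Gene memberships of the three key pathways (7, 5 and 6 genes).
PATHWAY_GENE_SETS: dict[str, list[str]] = {
    "Complement and coagulation cascades": [
        "F10", "F3", "F2", "SERPINE1", "F7", "PLG", "PLAU",
    ],
    "Arachidonic acid metabolism": [
        "PTGS2", "PTGS1", "PLA2G2A", "LTA4H", "ALOX5",
    ],
    "PI3K-Akt signaling pathway": [
        "IFNB1", "IL4", "INS", "PTEN", "RXRA", "TLR4",
    ],
}

# Headline counts of every stage of the original screen.
REFERENCE_COUNTS: dict[str, int] = {
    "candidate_compounds": 165,
    "merged_compounds": 163,
    "fuzi_compounds": 65,
    "rougui_compounds": 100,
    "shared_compounds": 2,
    "fuzi_targets": 58,
    "rougui_targets": 181,
    "common_targets": 45,
    "pooled_targets": 194,
    "active_compounds": 84,
    "potential_targets": 42,
    "disease_sets": 5,
    "ctd_nodes": 131,
    "ctd_edges": 293,
    "go_bp_terms": 30,
    "go_cc_terms": 30,
    "go_mf_terms": 25,
    "kegg_pathways": 19,
    "selected_pathways": 7,
    "tp_targets": 29,
    "tp_nodes": 36,
    "tp_edges": 41,
    "ppi_nodes": 18,
    "ppi_edges": 67,
    "hub_genes": 8,
}

# Published C-T-D compound-role centrality averages.
COMPOUND_AVERAGES = {"mean_DC": 2.7619, "mean_BC": 0.0068, "mean_CC": 0.3464}


def key_compound_records() -> list[CentralityRecord]:
    return [
        CentralityRecord(mol, Role.COMPOUND, dc, bc, cc)
        for mol, _name, dc, bc, cc in KEY_COMPOUND_TABLE
    ]


def pathway_records() -> list[CentralityRecord]:
    return [
        CentralityRecord(name, Role.PATHWAY, dc, bc, cc)
        for name, dc, bc, cc in PATHWAY_TABLE
    ]


def hub_gene_records() -> list[CentralityRecord]:
    return [
        CentralityRecord(sym, Role.PROTEIN, dc, bc, cc)
        for sym, dc, bc, cc in HUB_GENE_TABLE
    ]


def pathway_gene_sets() -> GeneSetCollection:
    """The three key-pathway gene lists as a pathway collection."""
    return GeneSetCollection(
        GeneSet(name, name, Category.PATHWAY, frozenset(members))
        for name, members in PATHWAY_GENE_SETS.items()
    )


def emit_reference_fixture(outdir: str | Path) -> dict[str, Path]:
    """Write the reference tables to ``outdir``.

    Emits the pathway GMT (gene lists of sizes 7, 5, 6), three centrality
    TSVs (key compounds, pathways, hub genes), and a JSON count manifest.
    """
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    paths: dict[str, Path] = {}

    paths["pathway_gmt"] = outdir / "key_pathways.gmt"
    hio.write_gmt(pathway_gene_sets(), paths["pathway_gmt"])

    paths["key_compounds"] = outdir / "key_compounds.tsv"
    hio.write_centrality_table(key_compound_records(), paths["key_compounds"])

    paths["pathways"] = outdir / "pathway_centralities.tsv"
    hio.write_centrality_table(pathway_records(), paths["pathways"])

    paths["hub_genes"] = outdir / "hub_genes.tsv"
    hio.write_centrality_table(hub_gene_records(), paths["hub_genes"])

    paths["counts"] = outdir / "reference_counts.json"
    paths["counts"].write_text(
        json.dumps(REFERENCE_COUNTS, indent=2, sort_keys=True) + "\n",
        encoding="utf-8",
    )
    return paths
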