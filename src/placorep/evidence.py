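"""Evidence-tier integration for pathway orthologs.

Each candidate gene for a pathway node collects independent support lines,
reported as a tier subset rather than a collapsed score:

* tier 1 — domain composition: every expected domain of the node observed;
* tier 2 — KEGG annotation: the gene's KO maps to the node;
* tier 3 — two of the three gene-mapping sources agree (EggNOG OG,
  OrthoMCL OG, best Swiss-Prot hit on the node's allow-list);
* tier 4 — phylogenetic validation (an input flag; tree inference is
  upstream of this package).

A gene with a non-empty tier set but missing expected domains is reported
``present_with_missing_domains`` — the uncertain-homology case.
"""

from __future__ import annotations

from dataclasses import dataclass
from importlib import resources
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import yaml

from .architecture import ProteinArchitecture
from .io import MappingTables

__all__ = [
    "EvidenceRecord",
    "SupportLabel",
    "PathwayNode",
    "assign_support",
    "pathway_report",
    "builtin_roster",
    "load_roster",
    "records_from_tables",
]

_STATUS_ORDER = {"present": 2, "present_with_missing_domains": 1, "absent": 0}


@dataclass(frozen=True)
class EvidenceRecord:
    """Per-gene support evidence for one pathway node."""

    gene_id: str
    pathway_node: str
    expected_domains: frozenset[str]
    observed_domains: frozenset[str]
    kegg_support: bool = False
    eggnog_support: bool = False
    orthomcl_support: bool = False
    swissprot_support: bool = False
    phylo_support: bool = False


@dataclass(frozen=True)
class SupportLabel:
    gene_id: str
    pathway_node: str
    tiers: frozenset[int]
    missing_domains: frozenset[str]
    status: str


@dataclass(frozen=True)
class PathwayNode:
    """Roster entry: a reference-pathway node and how each evidence source
    is matched to it."""

    name: str
    expected_domains: frozenset[str] = frozenset()
    ko: str | None = None
    eggnog_og: str | None = None
    orthomcl_og: str | None = None
    swissprot_accs: frozenset[str] = frozenset()


def assign_support(rec: EvidenceRecord) -> SupportLabel:
    """Compute the tier subset for one evidence record.

    Pure and idempotent: tiers depend only on the record's fields, exactly
    as the four-tier legend defines them.
    """
    tiers: set[int] = set()
    missing = rec.expected_domains - rec.observed_domains
    if rec.expected_domains and not missing:
        tiers.add(1)
    if rec.kegg_support:
        tiers.add(2)
    if sum((rec.eggnog_support, rec.orthomcl_support, rec.swissprot_support)) >= 2:
        tiers.add(3)
    if rec.phylo_support:
        tiers.add(4)
    if not tiers:
        status = "absent"
    elif missing:
        status = "present_with_missing_domains"
    else:
        status = "present"
    return SupportLabel(
        gene_id=rec.gene_id,
        pathway_node=rec.pathway_node,
        tiers=frozenset(tiers),
        missing_domains=frozenset(missing),
        status=status,
    )


def pathway_report(
    labels: Sequence[SupportLabel], node_roster: Sequence[PathwayNode]
) -> dict:
    """Per-node best status across candidate genes.

    Roster nodes with no supporting gene are reported absent.  A label for
    a node outside the roster is an error.
    """
    roster_names = [n.name for n in node_roster]
    known = set(roster_names)
    for lab in labels:
        if lab.pathway_node not in known:
            raise ValueError(f"unknown pathway node {lab.pathway_node!r}")
    report: dict[str, dict] = {
        name: {"status": "absent", "genes": []} for name in roster_names
    }
    for lab in sorted(labels, key=lambda l: (l.pathway_node, l.gene_id)):
        entry = report[lab.pathway_node]
        entry["genes"].append(
            {
                "gene_id": lab.gene_id,
                "tiers": sorted(lab.tiers),
                "missing_domains": sorted(lab.missing_domains),
                "status": lab.status,
            }
        )
        if _STATUS_ORDER[lab.status] > _STATUS_ORDER[entry["status"]]:
            entry["status"] = lab.status
    return report


# ---------------------------------------------------------------------------
# roster + record construction
# ---------------------------------------------------------------------------

def load_roster(path: str | Path) -> list[PathwayNode]:
    doc = yaml.safe_load(Path(path).read_text())
    nodes = []
    for d in doc["nodes"]:
        nodes.append(
            PathwayNode(
                name=d["name"],
                expected_domains=frozenset(d.get("expected_domains", [])),
                ko=d.get("ko"),
                eggnog_og=d.get("eggnog"),
                orthomcl_og=d.get("orthomcl"),
                swissprot_accs=frozenset(d.get("swissprot", [])),
            )
        )
    return nodes


def builtin_roster() -> list[PathwayNode]:
    """The packaged TLR-pathway roster (MyD88-dependent branch only; the
    MyD88-independent branch is assumed to have emerged in chordates)."""
    with resources.as_file(
        resources.files("placorep").joinpath("data/tlr_roster.yaml")
    ) as p:
        return load_roster(p)


def records_from_tables(
    roster: Sequence[PathwayNode],
    archs: Iterable[ProteinArchitecture],
    tables: MappingTables,
    phylo: Iterable[tuple[str, str]] = (),
) -> list[EvidenceRecord]:
    """Build evidence records for every (gene, node) candidate pair.

    A gene is a candidate for a node when any mapping source points to it:
    its KO equals the node's KO, either orthologous-group id matches, or
    its best Swiss-Prot hit is on the node's allow-list.  Observed domains
    come from the gene's architecture keys.
    """
    keys_by_gene: Mapping[str, frozenset[str]] = {
        a.protein_id: a.keys for a in archs
    }
    phylo_set = set(phylo)
    records: list[EvidenceRecord] = []
    for node in roster:
        candidates: set[str] = set()
        for gene, ko in tables.kegg_ko.items():
            if node.ko is not None and ko == node.ko:
                candidates.add(gene)
        for gene, og in tables.eggnog_og.items():
            if node.eggnog_og is not None and og == node.eggnog_og:
                candidates.add(gene)
        for gene, og in tables.orthomcl_og.items():
            if node.orthomcl_og is not None and og == node.orthomcl_og:
                candidates.add(gene)
        for gene, acc in tables.swissprot_best.items():
            if acc in node.swissprot_accs:
                candidates.add(gene)
        for gene in sorted(candidates):
            records.append(
                EvidenceRecord(
                    gene_id=gene,
                    pathway_node=node.name,
                    expected_domains=node.expected_domains,
                    observed_domains=keys_by_gene.get(gene, frozenset()),
                    kegg_support=tables.kegg_ko.get(gene) == node.ko
                    and node.ko is not None,
                    eggnog_support=tables.eggnog_og.get(gene) == node.eggnog_og
                    and node.eggnog_og is not None,
                    orthomcl_support=tables.orthomcl_og.get(gene) == node.orthomcl_og
                    and node.orthomcl_og is not None,
                    swissprot_support=tables.swissprot_best.get(gene)
                    in node.swissprot_accs,
                    phylo_support=(gene, node.name) in phylo_set,
                )
            )
    return records


def write_report_tsv(path: str | Path, report: Mapping[str, dict]) -> None:
    lines = ["node\tstatus\tgenes"]
    for node, entry in report.items():
        genes = ";".join(
            f"{g['gene_id']}(tiers={','.join(map(str, g['tiers']))})"
            for g in entry["genes"]
        )
        lines.append(f"{node}\t{entry['status']}\t{genes}")
    Path(path).write_text("".join(line + "\n" for line in lines))
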