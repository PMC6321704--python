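"""Tandem gene-cluster detection on scaffold gene orderings.

Cluster membership is defined on gene adjacency (per-scaffold ordinal
ranks), not base-pair distance: a cluster is a maximal run of family
members in which successive members have at most ``max_gap`` intervening
non-member genes.  Runs shorter than ``min_cluster_size`` are reported
separately as singletons.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Sequence

from .io import GeneLocus

__all__ = ["GeneCluster", "ClusterReport", "find_clusters"]


@dataclass(frozen=True)
class GeneCluster:
    scaffold: str
    family: str
    members: tuple[str, ...]  # gene ids ordered by ordinal

    @property
    def size(self) -> int:
        return len(self.members)


@dataclass(frozen=True)
class ClusterReport:
    family: str
    clusters: tuple[GeneCluster, ...]
    singletons: tuple[str, ...]

    @property
    def sizes(self) -> tuple[int, ...]:
        return tuple(c.size for c in self.clusters)


def find_clusters(
    loci: Sequence[GeneLocus],
    members: Iterable[str],
    max_gap: int = 1,
    min_cluster_size: int = 2,
    family: str = "",
) -> ClusterReport:
    """Detect genomic clusters of ``members`` among ``loci``.

    Deterministic and invariant under permutation of the loci input and
    relabelling of gene ids; a member without a locus is an error naming
    the gene.
    """
    member_set = set(members)
    by_id = {l.gene_id for l in loci}
    missing = sorted(member_set - by_id)
    if missing:
        raise ValueError(f"members without a locus: {', '.join(missing)}")
    per_scaffold: dict[str, list[GeneLocus]] = {}
    for l in loci:
        if l.gene_id in member_set:
            per_scaffold.setdefault(l.scaffold, []).append(l)
    clusters: list[GeneCluster] = []
    singletons: list[str] = []
    for scaffold in sorted(per_scaffold):
        ranked = sorted(per_scaffold[scaffold], key=lambda l: l.ordinal)
        run: list[GeneLocus] = [ranked[0]]
        for locus in ranked[1:]:
            if locus.ordinal - run[-1].ordinal <= max_gap + 1:
                run.append(locus)
            else:
                _close_run(run, scaffold, family, min_cluster_size, clusters, singletons)
                run = [locus]
        _close_run(run, scaffold, family, min_cluster_size, clusters, singletons)
    return ClusterReport(
        family=family, clusters=tuple(clusters), singletons=tuple(singletons)
    )


def _close_run(run, scaffold, family, min_cluster_size, clusters, singletons):
    if len(run) >= min_cluster_size:
        clusters.append(
            GeneCluster(
                scaffold=scaffold,
                family=family,
                members=tuple(l.gene_id for l in run),
            )
        )
    else:
        singletons.extend(l.gene_id for l in run)


def write_cluster_tsv(path: str | Path, report: ClusterReport) -> None:
    """Cluster report TSV plus a per-family summary line."""
    lines = ["scaffold\tfamily\tsize\tmembers"]
    for c in report.clusters:
        lines.append(
            f"{c.scaffold}\t{report.family}\t{c.size}\t{','.join(c.members)}"
        )
    for gid in report.singletons:
        lines.append(f"-\t{report.family}\t1\t{gid}")
    sizes = report.sizes
    if sizes:
        summary = (
            f"# {report.family or 'family'}: {len(sizes)} clusters, "
            f"sizes {min(sizes)}-{max(sizes)}, {len(report.singletons)} singletons"
        )
    else:
        summary = f"# {report.family or 'family'}: 0 clusters, {len(report.singletons)} singletons"
    lines.append(summary)
    Path(path).write_text("".join(line + "\n" for line in lines))
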