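"""Per-taxon best-hit selection and ortholog-group assembly.

Groups are assembled per query with no reciprocality requirement: for each
query gene, the hit with the lowest e-value in each subject taxon (at the
stated cutoff) represents that taxon.  E-value ties break by higher
bitscore, then lexicographically smaller subject id — a documented,
configurable convention; hits to the query's own taxon are included unless
excluded explicitly.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Mapping, Sequence

from .io import HitRecord, write_fasta

__all__ = ["OrthologGroup", "best_hit_per_taxon", "build_groups", "emit_group_fasta"]

DEFAULT_CUTOFF = 1e-10


@dataclass(frozen=True)
class OrthologGroup:
    """Per-query collection of per-taxon best-hit representatives."""

    query_id: str
    representatives: tuple[tuple[str, HitRecord], ...]  # (taxon, hit), sorted

    def taxa(self) -> tuple[str, ...]:
        return tuple(t for t, _ in self.representatives)


def _better(a: HitRecord, b: HitRecord) -> bool:
    """True when ``a`` outranks ``b``: lower e-value, then higher bitscore,
    then smaller subject id."""
    return (a.evalue, -a.bitscore, a.subject_id) < (b.evalue, -b.bitscore, b.subject_id)


def best_hit_per_taxon(
    hits: Sequence[HitRecord],
    cutoff: float = DEFAULT_CUTOFF,
    exclude_taxa: Iterable[str] = (),
) -> dict[str, HitRecord]:
    """The minimal-e-value hit per subject taxon among hits passing ``cutoff``.

    Taxa with no passing hit are absent from the result.
    """
    if len({h.query_id for h in hits}) > 1:
        raise ValueError("best_hit_per_taxon expects hits of a single query")
    excluded = set(exclude_taxa)
    best: dict[str, HitRecord] = {}
    for h in hits:
        if h.evalue > cutoff or h.subject_taxon in excluded:
            continue
        cur = best.get(h.subject_taxon)
        if cur is None or _better(h, cur):
            best[h.subject_taxon] = h
    return best


def build_groups(
    all_hits: Sequence[HitRecord],
    queries: Sequence[str],
    cutoff: float = DEFAULT_CUTOFF,
    exclude_taxa: Iterable[str] = (),
) -> list[OrthologGroup]:
    """One group per query, in the order queries are given.

    Deterministic and insensitive to hit-row order.  A subject may
    represent its taxon in several groups: selection is strictly
    per-query, with no global uniqueness.
    """
    by_query: dict[str, list[HitRecord]] = {q: [] for q in queries}
    for h in all_hits:
        if h.query_id in by_query:
            by_query[h.query_id].append(h)
    groups = []
    for q in queries:
        best = best_hit_per_taxon(by_query[q], cutoff=cutoff, exclude_taxa=exclude_taxa)
        groups.append(
            OrthologGroup(
                query_id=q,
                representatives=tuple(sorted(best.items())),
            )
        )
    return groups


def emit_group_fasta(
    group: OrthologGroup, sequences: Mapping[str, str], path: str | Path
) -> None:
    """Write one FASTA record per representative, headers ``TAXON|localid``.

    An empty group yields an empty FASTA file (success, not an error);
    unresolvable representative ids are an error listing every missing id.
    """
    missing = [h.subject_id for _, h in group.representatives if h.subject_id not in sequences]
    if missing:
        raise KeyError(
            f"group {group.query_id}: sequences missing for {', '.join(missing)}"
        )
    write_fasta(
        path, {h.subject_id: sequences[h.subject_id] for _, h in group.representatives}
    )


def write_group_manifest(path: str | Path, groups: Sequence[OrthologGroup]) -> None:
    lines = ["query\ttaxon\tsubject\tevalue\tbitscore"]
    for g in groups:
        for taxon, h in g.representatives:
            lines.append(
                f"{g.query_id}\t{taxon}\t{h.subject_id}\t{h.evalue:g}\t{h.bitscore:g}"
            )
    Path(path).write_text("".join(line + "\n" for line in lines))
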