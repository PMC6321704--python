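"""Per-protein domain architectures.

InterProScan reports redundant hits for the same domain from several member
databases.  :func:`build_architecture` normalises them into one ordered list
of merged domain spans per protein, keyed by InterPro accession where one
exists and by ``analysis:signature`` otherwise, so downstream rules count
domains rather than hits.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

from .io import DomainHit, TopologyCall

#: fraction of the shorter interval that two same-accession hits must share
#: before they are considered one domain occurrence
MERGE_OVERLAP = 0.30

REGIONS = frozenset(
    {"n_terminal", "central", "c_terminal", "extracellular", "intracellular"}
)


@dataclass(frozen=True, slots=True)
class DomainSpan:
    """One merged domain occurrence: an interval, its accession key and the
    member-database signatures that supported it."""

    start: int
    end: int
    key: str
    signatures: frozenset[str] = frozenset()

    @property
    def midpoint(self) -> float:
        return (self.start + self.end) / 2


@dataclass(frozen=True, slots=True)
class ProteinArchitecture:
    """A protein's ordered domain string plus membrane topology."""

    protein_id: str
    length: int
    domains: tuple[DomainSpan, ...]
    has_signal_peptide: bool
    tm_segments: tuple[tuple[int, int], ...] = ()

    @property
    def tm_count(self) -> int:
        return len(self.tm_segments)

    @property
    def keys(self) -> frozenset[str]:
        return frozenset(d.key for d in self.domains)

    def count(self, key: str) -> int:
        return sum(1 for d in self.domains if d.key == key)

    def spans(self, keys: Iterable[str]) -> tuple[DomainSpan, ...]:
        wanted = frozenset(keys)
        return tuple(d for d in self.domains if d.key in wanted)


def build_architecture(
    hits: Sequence[DomainHit], topo: TopologyCall
) -> ProteinArchitecture:
    """Merge a protein's domain hits into an ordered architecture.

    Hits sharing an accession key whose intervals reciprocally overlap by
    more than :data:`MERGE_OVERLAP` of the shorter interval collapse into a
    single span; disjoint repeats of the same domain stay separate.
    """
    for h in hits:
        if h.protein_id != topo.protein_id:
            raise ValueError(
                f"hit for {h.protein_id} mixed into architecture of {topo.protein_id}"
            )
    by_key: dict[str, list[DomainHit]] = {}
    for h in hits:
        by_key.setdefault(h.key, []).append(h)
    spans: list[DomainSpan] = []
    for key in sorted(by_key):
        merged: list[tuple[int, int, set[str]]] = []
        for h in sorted(by_key[key], key=lambda h: (h.start, h.end)):
            sig = f"{h.analysis}:{h.signature_acc}"
            if merged:
                s0, e0, sigs = merged[-1]
                overlap = min(e0, h.end) - max(s0, h.start) + 1
                shorter = min(e0 - s0 + 1, h.end - h.start + 1)
                if overlap > MERGE_OVERLAP * shorter:
                    merged[-1] = (s0, max(e0, h.end), sigs | {sig})
                    continue
            merged.append((h.start, h.end, {sig}))
        for s, e, sigs in merged:
            spans.append(DomainSpan(start=s, end=e, key=key, signatures=frozenset(sigs)))
    spans.sort(key=lambda d: (d.start, d.end, d.key))
    return ProteinArchitecture(
        protein_id=topo.protein_id,
        length=topo.length,
        domains=tuple(spans),
        has_signal_peptide=topo.has_signal_peptide,
        tm_segments=topo.tm_segments,
    )


def build_proteome(
    hits: Iterable[DomainHit], topologies: Iterable[TopologyCall]
) -> list[ProteinArchitecture]:
    """One architecture per topology record; proteins without domain hits
    yield an empty-domain architecture."""
    grouped: dict[str, list[DomainHit]] = {}
    for h in hits:
        grouped.setdefault(h.protein_id, []).append(h)
    return [
        build_architecture(grouped.get(t.protein_id, []), t) for t in topologies
    ]


def domain_region(arch: ProteinArchitecture, span: DomainSpan) -> frozenset[str]:
    """Region labels for one domain span — total and deterministic.

    Linear position uses the thirds-of-length convention on the span
    midpoint.  Membrane sidedness is assigned only for membrane proteins:
    the stretch before the first TM segment is extracellular for type-I
    single-pass proteins (signal peptide present) and for 7-TM receptors,
    intracellular otherwise, and alternates across each TM crossing.  A
    span whose midpoint falls inside a TM segment gets no sidedness.
    """
    regions: set[str] = set()
    mid = span.midpoint
    if 3 * mid <= arch.length:
        regions.add("n_terminal")
    elif 3 * mid > 2 * arch.length:
        regions.add("c_terminal")
    else:
        regions.add("central")
    if arch.tm_count >= 1:
        inside_tm = any(s <= mid <= e for s, e in arch.tm_segments)
        if not inside_tm:
            crossings = sum(1 for _, e in arch.tm_segments if e < mid)
            first_side_out = arch.has_signal_peptide or arch.tm_count == 7
            side_out = first_side_out == (crossings % 2 == 0)
            regions.add("extracellular" if side_out else "intracellular")
    return frozenset(regions)


def observed_keys(archs: Iterable[ProteinArchitecture]) -> Mapping[str, frozenset[str]]:
    """Convenience: protein_id -> set of accession keys."""
    return {a.protein_id: a.keys for a in archs}
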