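"""Deliberately naive re-implementations used as independent oracles.

These scan every clause exhaustively with straightforward loops and are
kept free of the library's evaluation code paths.
"""

from __future__ import annotations

from placorep.architecture import ProteinArchitecture
from placorep.io import HitRecord, MappingTables
from placorep.rules import FamilyRule


def naive_region(arch: ProteinArchitecture, start: int, end: int) -> set[str]:
    mid = (start + end) / 2.0
    L = arch.length
    out = set()
    if mid <= L / 3.0:
        out.add("n_terminal")
    elif mid > 2.0 * L / 3.0:
        out.add("c_terminal")
    else:
        out.add("central")
    if len(arch.tm_segments) >= 1:
        if not any(s <= mid <= e for s, e in arch.tm_segments):
            n_before = 0
            for s, e in arch.tm_segments:
                if e < mid:
                    n_before += 1
            outside_first = arch.has_signal_peptide or len(arch.tm_segments) == 7
            if n_before % 2 == 0:
                out.add("extracellular" if outside_first else "intracellular")
            else:
                out.add("intracellular" if outside_first else "extracellular")
    return out


def naive_rule_passes(
    arch: ProteinArchitecture, rule: FamilyRule, tables: MappingTables | None
) -> bool:
    if rule.any_of:
        return any(naive_rule_passes(arch, sub, tables) for sub in rule.any_of)
    keys = {d.key for d in arch.domains}
    for group in rule.require_any:
        if not any(k in group for k in keys):
            return False
    for k in keys:
        if k in rule.forbid:
            return False
    for key, lo, hi in rule.require_count:
        n = len([d for d in arch.domains if d.key == key])
        if n < lo or (hi is not None and n > hi):
            return False
    tm_count = len(arch.tm_segments)
    if rule.tm != "none":
        parts = rule.tm.split(":")
        if parts[0] == "exactly" and tm_count != int(parts[1]):
            return False
        if parts[0] == "at_least" and tm_count < int(parts[1]):
            return False
        if parts[0] == "range" and not (int(parts[1]) <= tm_count <= int(parts[2])):
            return False
    if rule.sp == "yes" and not arch.has_signal_peptide:
        return False
    if rule.sp == "no" and arch.has_signal_peptide:
        return False
    if rule.min_length is not None and arch.length < rule.min_length:
        return False
    if rule.max_length is not None and arch.length > rule.max_length:
        return False
    for group, region in rule.positions:
        found = False
        for d in arch.domains:
            if d.key in group and region in naive_region(arch, d.start, d.end):
                found = True
        if not found:
            return False
    if rule.panther_any:
        label = tables.panther_family.get(arch.protein_id) if tables else None
        if label not in rule.panther_any:
            return False
    return True


def naive_classify(
    archs, rules_, tables=None
) -> dict[str, set[str]]:
    """protein_id -> set of family labels, by exhaustive clause scanning."""
    out: dict[str, set[str]] = {}
    for arch in archs:
        labels = set()
        for rule in rules_:
            if naive_rule_passes(arch, rule, tables):
                labels.add(rule.name)
        out[arch.protein_id] = labels
    return out


def naive_best_hits(hits: list[HitRecord], cutoff: float) -> dict[str, HitRecord]:
    """Sort-free full scan: for each taxon, compare every passing pair."""
    passing = [h for h in hits if h.evalue <= cutoff]
    best: dict[str, HitRecord] = {}
    for taxon in {h.subject_taxon for h in passing}:
        candidates = [h for h in passing if h.subject_taxon == taxon]
        winner = candidates[0]
        for h in candidates[1:]:
            if h.evalue < winner.evalue:
                winner = h
            elif h.evalue == winner.evalue:
                if h.bitscore > winner.bitscore:
                    winner = h
                elif h.bitscore == winner.bitscore and h.subject_id < winner.subject_id:
                    winner = h
        best[taxon] = winner
    return best
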