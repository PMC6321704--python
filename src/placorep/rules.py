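"""Declarative family-classification rules and their evaluation.

A :class:`FamilyRule` states what a protein's architecture must look like
to join a gene family: accession groups that must be present, forbidden
accessions, occurrence counts, transmembrane and signal-peptide
constraints, positional constraints over a closed region vocabulary, and
length bounds.  Rules may be disjunctions (``any_of``) and may carry
subclass rules evaluated only on proteins that pass the parent.

The packaged rule set transcribes the six InterPro screens used to
inventory the placozoan innate-immunity repertoire: TIR/SEFIR adaptors,
LRR single-pass receptor candidates, SRCR/CTLD/CD36 scavenger receptors
(with the 7-TM GPCR-CTLD subclass), secreted lectins and intelectins,
NACHT/NB-ARC NOD-like receptors and Apaf-1 architectures, arrestins, and
absence screens for RIG-I, cGAS, STING and complement factors.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import yaml

from . import vocab
from .architecture import REGIONS, ProteinArchitecture, domain_region
from .io import MappingTables

__all__ = [
    "FamilyRule",
    "RuleResult",
    "Classification",
    "evaluate_rule",
    "builtin_ruleset",
    "load_ruleset",
    "classify_proteome",
    "summarize",
]


@dataclass(frozen=True)
class FamilyRule:
    """Declarative classification rule for one family (or subclass)."""

    name: str
    require_any: tuple[frozenset[str], ...] = ()
    require_count: tuple[tuple[str, int, int | None], ...] = ()
    forbid: frozenset[str] = frozenset()
    tm: str = "none"  # none | exactly:k | at_least:k | range:a:b
    sp: str = "any"  # yes | no | any
    min_length: int | None = None
    max_length: int | None = None
    positions: tuple[tuple[frozenset[str], str], ...] = ()
    panther_any: frozenset[str] = frozenset()
    any_of: tuple["FamilyRule", ...] = ()
    subclasses: tuple["FamilyRule", ...] = ()
    absence_screen: bool = False
    description: str = ""

    def __post_init__(self) -> None:
        for group in self.require_any:
            if not group:
                raise ValueError(f"rule {self.name}: empty require_any group")
        for _, region in self.positions:
            if region not in REGIONS:
                raise ValueError(f"rule {self.name}: unknown region {region!r}")


@dataclass(frozen=True)
class RuleResult:
    """Outcome of evaluating one rule: pass/fail plus per-clause diagnostics."""

    name: str
    passed: bool
    clauses: tuple[tuple[str, bool], ...] = ()
    routes: tuple["RuleResult", ...] = ()

    @property
    def first_failing(self) -> str | None:
        for clause, ok in self.clauses:
            if not ok:
                return clause
        return None


def _tm_allows(constraint: str, tm_count: int) -> bool:
    if constraint == "none":
        return True
    kind, *args = constraint.split(":")
    if kind == "exactly":
        return tm_count == int(args[0])
    if kind == "at_least":
        return tm_count >= int(args[0])
    if kind == "range":
        return int(args[0]) <= tm_count <= int(args[1])
    raise ValueError(f"unknown tm constraint {constraint!r}")


def evaluate_rule(
    arch: ProteinArchitecture,
    rule: FamilyRule,
    tables: MappingTables | None = None,
) -> RuleResult:
    """Pure, deterministic evaluation of ``rule`` on one architecture.

    Returns a :class:`RuleResult` whose ``clauses`` record every clause in
    canonical order, so diagnostics can name the first failing clause.  A
    disjunctive rule passes when any route does; each route's result is
    kept under ``routes``.
    """
    if rule.any_of:
        routes = tuple(evaluate_rule(arch, sub, tables) for sub in rule.any_of)
        return RuleResult(
            name=rule.name, passed=any(r.passed for r in routes), routes=routes
        )

    keys = arch.keys
    clauses: list[tuple[str, bool]] = []
    for i, group in enumerate(rule.require_any):
        clauses.append((f"require_any[{i}]", bool(keys & group)))
    if rule.forbid:
        clauses.append(("forbid", not (keys & rule.forbid)))
    for key, lo, hi in rule.require_count:
        n = arch.count(key)
        clauses.append((f"require_count:{key}", lo <= n and (hi is None or n <= hi)))
    if rule.tm != "none":
        clauses.append(("tm", _tm_allows(rule.tm, arch.tm_count)))
    if rule.sp != "any":
        clauses.append(("sp", arch.has_signal_peptide == (rule.sp == "yes")))
    if rule.min_length is not None:
        clauses.append(("min_length", arch.length >= rule.min_length))
    if rule.max_length is not None:
        clauses.append(("max_length", arch.length <= rule.max_length))
    for group, region in rule.positions:
        ok = any(
            region in domain_region(arch, span) for span in arch.spans(group)
        )
        clauses.append((f"position:{region}", ok))
    if rule.panther_any:
        label = (tables.panther_family.get(arch.protein_id) if tables else None)
        clauses.append(("panther", label in rule.panther_any))
    return RuleResult(
        name=rule.name,
        passed=all(ok for _, ok in clauses),
        clauses=tuple(clauses),
    )


# ---------------------------------------------------------------------------
# rule-set loading
# ---------------------------------------------------------------------------

def _expand(entry, groups: Mapping[str, list[str]]) -> list[str]:
    items = [entry] if isinstance(entry, str) else list(entry)
    out: list[str] = []
    for item in items:
        if item.startswith("@"):
            name = item[1:]
            if name not in groups:
                raise ValueError(f"unknown accession group @{name}")
            out.extend(groups[name])
        else:
            out.append(item)
    return out


def _sp_value(v) -> str:
    # YAML 1.1 reads bare yes/no as booleans; accept both spellings
    if isinstance(v, bool):
        return "yes" if v else "no"
    return str(v)


def _rule_from_dict(d: Mapping, groups: Mapping[str, list[str]]) -> FamilyRule:
    return FamilyRule(
        name=d["name"],
        require_any=tuple(
            frozenset(_expand(g, groups)) for g in d.get("require_any", [])
        ),
        require_count=tuple(
            (k, int(lo), None if hi is None else int(hi))
            for k, lo, hi in d.get("require_count", [])
        ),
        forbid=frozenset(_expand(d["forbid"], groups)) if "forbid" in d else frozenset(),
        tm=str(d.get("tm", "none")),
        sp=_sp_value(d.get("sp", "any")),
        min_length=d.get("min_length"),
        max_length=d.get("max_length"),
        positions=tuple(
            (frozenset(_expand(keys, groups)), region)
            for keys, region in d.get("positions", [])
        ),
        panther_any=frozenset(d.get("panther_any", [])),
        any_of=tuple(_rule_from_dict(s, groups) for s in d.get("any_of", [])),
        subclasses=tuple(_rule_from_dict(s, groups) for s in d.get("subclasses", [])),
        absence_screen=bool(d.get("absence_screen", False)),
        description=str(d.get("description", "")),
    )


def load_ruleset(path: str | Path) -> list[FamilyRule]:
    """Load a YAML rule document (``groups`` + ``rules`` sections)."""
    doc = yaml.safe_load(Path(path).read_text())
    groups = {k: list(v) for k, v in (doc.get("groups") or {}).items()}
    return [_rule_from_dict(d, groups) for d in doc["rules"]]


def builtin_ruleset() -> list[FamilyRule]:
    """The packaged rule set transcribing the published screens."""
    with resources.as_file(
        resources.files("placorep").joinpath("data/rules.yaml")
    ) as p:
        return load_ruleset(p)


# ---------------------------------------------------------------------------
# proteome-level classification
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class Classification:
    """All labels one protein received, with per-rule diagnostics."""

    protein_id: str
    labels: frozenset[str]
    subclasses: tuple[tuple[str, str], ...]  # (family, subclass) pairs
    flags: frozenset[str]
    diagnostics: Mapping[str, RuleResult] = field(default_factory=dict, hash=False)


def _protein_flags(arch: ProteinArchitecture) -> frozenset[str]:
    flags: set[str] = set()
    if vocab.TIR in arch.keys and vocab.LRR in arch.keys and arch.length >= 2000:
        # the two ~3000-AA LRR+TIR proteins: no receptor class is claimed
        flags.add("giant_lrr_tir")
    if arch.tm_count == 1 and not arch.has_signal_peptide:
        flags.add("single_tm_no_sp_orientation")
    sr_classes = sum(
        1 for k in (vocab.SRCR, vocab.CTLD, vocab.CD36) if k in arch.keys
    )
    if sr_classes >= 2:
        flags.add("sr_class_overlap")
    return frozenset(flags)


def classify_proteome(
    archs: Sequence[ProteinArchitecture],
    rules: Sequence[FamilyRule],
    tables: MappingTables | None = None,
) -> list[Classification]:
    """Evaluate every rule on every protein.

    Multi-labelling is permitted (a protein receives every label whose rule
    passes); subclass rules are evaluated only on proteins carrying the
    parent label.  The result is deterministic and per-protein, hence
    invariant under permutation of the input.
    """
    out: list[Classification] = []
    for arch in archs:
        labels: set[str] = set()
        subclasses: list[tuple[str, str]] = []
        diagnostics: dict[str, RuleResult] = {}
        for rule in rules:
            res = evaluate_rule(arch, rule, tables)
            diagnostics[rule.name] = res
            if not res.passed:
                continue
            labels.add(rule.name)
            for sub in rule.subclasses:
                sres = evaluate_rule(arch, sub, tables)
                diagnostics[f"{rule.name}/{sub.name}"] = sres
                if sres.passed:
                    subclasses.append((rule.name, sub.name))
        out.append(
            Classification(
                protein_id=arch.protein_id,
                labels=frozenset(labels),
                subclasses=tuple(sorted(subclasses)),
                flags=_protein_flags(arch),
                diagnostics=diagnostics,
            )
        )
    return out


def summarize(
    classifications: Sequence[Classification],
    archs: Sequence[ProteinArchitecture],
    rules: Sequence[FamilyRule],
) -> dict:
    """Per-family counts, subclass counts, absence-screen results and the
    derived FReD/intelectin route counts, as a JSON-ready dict."""
    by_id = {a.protein_id: a for a in archs}
    fam_counts: dict[str, int] = {}
    sub_counts: dict[str, dict[str, int]] = {}
    screens: dict[str, dict] = {}
    for rule in rules:
        n = sum(1 for c in classifications if rule.name in c.labels)
        if rule.absence_screen:
            screens[rule.name] = {
                "count": n,
                "proteins": sorted(
                    c.protein_id for c in classifications if rule.name in c.labels
                ),
            }
        else:
            fam_counts[rule.name] = n
            if rule.subclasses:
                sub_counts[rule.name] = {
                    sub.name: sum(
                        1
                        for c in classifications
                        if (rule.name, sub.name) in c.subclasses
                    )
                    for sub in rule.subclasses
                }
    fred_ssf = sum(
        1
        for c in classifications
        if "FReD_model" in c.labels and vocab.SSF_FRED in by_id[c.protein_id].keys
    )
    itln_panther_only = sum(
        1
        for c in classifications
        if "intelectin" in c.labels and vocab.SSF_FRED not in by_id[c.protein_id].keys
    )
    flag_counts: dict[str, int] = {}
    for c in classifications:
        for f in c.flags:
            flag_counts[f] = flag_counts.get(f, 0) + 1
    return {
        "n_proteins": len(classifications),
        "families": dict(sorted(fam_counts.items())),
        "subclasses": {k: dict(sorted(v.items())) for k, v in sorted(sub_counts.items())},
        "absence_screens": dict(sorted(screens.items())),
        "fred_ssf56496": fred_ssf,
        "intelectin_panther_only": itln_panther_only,
        "flags": dict(sorted(flag_counts.items())),
    }


def write_classification_tsv(
    path: str | Path, classifications: Iterable[Classification]
) -> None:
    """TSV report: protein_id, labels, subclasses, flags."""
    lines = ["protein_id\tlabels\tsubclasses\tflags"]
    for c in classifications:
        lines.append(
            "\t".join(
                [
                    c.protein_id,
                    ";".join(sorted(c.labels)),
                    ";".join(f"{fam}:{sub}" for fam, sub in c.subclasses),
                    ";".join(sorted(c.flags)),
                ]
            )
        )
    Path(path).write_text("".join(line + "\n" for line in lines))
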