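"""Rule evaluation, the packaged rule set and proteome classification."""

import random

import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from naive_oracle import naive_classify
from placorep import vocab
from placorep.architecture import DomainSpan, ProteinArchitecture
from placorep.io import MappingTables
from placorep.rules import (
    FamilyRule,
    builtin_ruleset,
    classify_proteome,
    evaluate_rule,
    summarize,
)

SR_RULE = FamilyRule(
    name="scavenger_receptor",
    require_any=(frozenset({vocab.SRCR, vocab.CTLD, vocab.CD36}),),
    tm="at_least:1",
)


def _arch(pid="p", length=600, keys=(), sp=False, tm=(), spans=None):
    if spans is None:
        spans = []
        pos = 30
        for k in keys:
            spans.append(DomainSpan(start=pos, end=pos + 60, key=k))
            pos += 80
    return ProteinArchitecture(
        protein_id=pid, length=length, domains=tuple(spans),
        has_signal_peptide=sp, tm_segments=tuple(tm),
    )


class TestEvaluateRule:
    def test_srcr_with_tm_passes_sr_rule(self):
        arch = _arch(keys=[vocab.SRCR, vocab.SRCR], tm=[(400, 420)])
        res = evaluate_rule(arch, SR_RULE)
        assert res.passed and res.first_failing is None

    def test_ctld_without_tm_fails_on_tm_clause(self):
        arch = _arch(keys=[vocab.CTLD])
        res = evaluate_rule(arch, SR_RULE)
        assert not res.passed
        assert res.first_failing == "tm"

    def test_empty_architecture_fails_any_requiring_rule(self):
        res = evaluate_rule(_arch(keys=[]), SR_RULE)
        assert not res.passed

    def test_empty_architecture_passes_unconstrained_rule(self):
        assert evaluate_rule(_arch(keys=[]), FamilyRule(name="anything")).passed

    def test_evaluation_is_pure(self):
        arch = _arch(keys=[vocab.SRCR], tm=[(400, 420)])
        assert evaluate_rule(arch, SR_RULE) == evaluate_rule(arch, SR_RULE)

    def test_panther_clause_reads_mapping_table(self):
        rule = FamilyRule(name="itln", panther_any=frozenset({vocab.PANTHER_INTELECTIN}))
        tables = MappingTables(panther_family={"p": vocab.PANTHER_INTELECTIN})
        assert evaluate_rule(_arch(), rule, tables).passed
        assert not evaluate_rule(_arch(pid="q"), rule, tables).passed


class TestBuiltinRuleset:
    def test_nlr_rule_requires_central_nod_domains(self, ruleset):
        nlr = next(r for r in ruleset if r.name == "NLR")
        group, region = nlr.positions[0]
        assert group == {vocab.NACHT, vocab.NB_ARC}
        assert region == "central"

    def test_gpcr_ctld_subclass_requires_seven_tm(self, ruleset):
        sr = next(r for r in ruleset if r.name == "scavenger_receptor")
        gpcr = next(s for s in sr.subclasses if s.name == "GPCR_CTLD")
        assert gpcr.tm == "exactly:7"

    def test_rig_i_screen_matches_nothing_without_its_accession(self, ruleset):
        rig = next(r for r in ruleset if r.name == "RIG_I")
        assert rig.absence_screen
        arch = _arch(keys=[vocab.TIR, vocab.NB_ARC, vocab.CTLD])
        assert not evaluate_rule(arch, rig).passed

    def test_intelectin_is_a_disjunction_of_two_routes(self, ruleset):
        itln = next(r for r in ruleset if r.name == "intelectin")
        assert {s.name for s in itln.any_of} == {"by_architecture", "by_panther"}


class TestClassifyProteome:
    def test_short_secreted_fred_is_fred_model_and_intelectin(self, ruleset):
        arch = _arch(
            length=250,
            spans=[DomainSpan(start=30, end=95, key=vocab.SSF_FRED)],
            sp=True,
        )
        (c,) = classify_proteome([arch], ruleset)
        assert {"FReD_model", "intelectin"} <= c.labels

    def test_apaf1_architecture_is_both_nlr_and_apaf1(self, ruleset):
        spans = [
            DomainSpan(start=30, end=120, key=vocab.CARD),
            DomainSpan(start=450, end=620, key=vocab.NB_ARC),
            DomainSpan(start=800, end=880, key=vocab.WD40),
        ]
        arch = _arch(length=1000, spans=spans)
        (c,) = classify_proteome([arch], ruleset)
        assert {"NLR", "Apaf1_like"} <= c.labels

    def test_empty_proteome_gives_empty_classification(self, ruleset):
        assert classify_proteome([], ruleset) == []

    def test_no_protein_is_both_membrane_sr_and_secreted_ctld(
        self, h2_classifications
    ):
        for c in h2_classifications:
            assert not (
                "scavenger_receptor" in c.labels and "secreted_CTLD" in c.labels
            )

    def test_sr_subclasses_partition_the_family(self, h2_classifications, h2_summary):
        sub = h2_summary["subclasses"]["scavenger_receptor"]
        overlapping = [c for c in h2_classifications if "sr_class_overlap" in c.flags]
        assert not overlapping
        assert (
            sub["SRCR_type"] + sub["CTLD_type"] + sub["CD36_type"]
            == h2_summary["families"]["scavenger_receptor"]
        )

    def test_counts_invariant_under_protein_permutation(
        self, h2_archs, h2_tables, ruleset, h2_summary
    ):
        shuffled = list(h2_archs)
        random.Random(1).shuffle(shuffled)
        cl = classify_proteome(shuffled, ruleset, h2_tables)
        assert summarize(cl, shuffled, ruleset)["families"] == h2_summary["families"]


# -- randomised oracle equivalence ------------------------------------------

_KEYS = [
    vocab.TIR, vocab.SEFIR, vocab.LRR, vocab.SRCR, vocab.CTLD, vocab.CD36,
    vocab.SSF_FRED, vocab.NB_ARC, vocab.NACHT, vocab.CARD, vocab.DD,
    vocab.WD40, vocab.TPR, vocab.ANK, vocab.KINASE,
]


@st.composite
def random_arch(draw, pid_index: int):
    length = draw(st.integers(min_value=120, max_value=2500))
    n_domains = draw(st.integers(min_value=0, max_value=6))
    spans = []
    for _ in range(n_domains):
        start = draw(st.integers(min_value=1, max_value=length - 30))
        end = draw(st.integers(min_value=start, max_value=min(length, start + 400)))
        spans.append(DomainSpan(start=start, end=end, key=draw(st.sampled_from(_KEYS))))
    spans.sort(key=lambda d: (d.start, d.end, d.key))
    tm_count = draw(st.sampled_from([0, 0, 1, 1, 2, 7]))
    width = max(12, length // (3 * tm_count) if tm_count else 12)
    tm = []
    pos = max(30, length // (tm_count + 1)) if tm_count else 0
    for i in range(tm_count):
        s = min(length - 1, pos + i * (width + 25))
        e = min(length, s + width)
        if tm and s <= tm[-1][1]:
            break
        tm.append((s, e))
    return ProteinArchitecture(
        protein_id=f"r{pid_index}",
        length=length,
        domains=tuple(spans),
        has_signal_peptide=draw(st.booleans()),
        tm_segments=tuple(tm),
    )


@st.composite
def random_proteome(draw):
    n = draw(st.integers(min_value=0, max_value=12))
    return [draw(random_arch(i)) for i in range(n)]


@given(random_proteome())
@settings(max_examples=60, derandomize=True, deadline=None)
def test_engine_agrees_with_naive_exhaustive_oracle(archs):
    """Engine labels equal a clause-by-clause exhaustive re-evaluation."""
    ruleset = builtin_ruleset()
    engine = {
        c.protein_id: set(c.labels) for c in classify_proteome(archs, ruleset)
    }
    assert engine == naive_classify(archs, ruleset)


@given(random_arch(0), st.sampled_from(_KEYS))
@settings(max_examples=60, derandomize=True, deadline=None)
def test_adding_a_domain_never_removes_forbid_free_labels(arch, key):
    """Monotonicity: extra hits cannot revoke a label whose rule has no
    forbid set and no maximum count."""
    ruleset = [
        r for r in builtin_ruleset()
        if not r.forbid and not r.any_of
        and all(hi is None for _, _, hi in r.require_count)
    ]
    before = {r.name for r in ruleset if evaluate_rule(arch, r).passed}
    extra = DomainSpan(start=1, end=min(40, arch.length), key=key)
    grown = ProteinArchitecture(
        protein_id=arch.protein_id,
        length=arch.length,
        domains=tuple(sorted(arch.domains + (extra,), key=lambda d: (d.start, d.end, d.key))),
        has_signal_peptide=arch.has_signal_peptide,
        tm_segments=arch.tm_segments,
    )
    after = {r.name for r in ruleset if evaluate_rule(grown, r).passed}
    assert before <= after
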