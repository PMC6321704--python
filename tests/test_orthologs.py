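"""Best-hit selection and ortholog-group assembly."""

import random

import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from naive_oracle import naive_best_hits
from placorep.io import HitRecord, parse_blast_tab, read_fasta
from placorep.orthologs import best_hit_per_taxon, build_groups, emit_group_fasta


def _hit(query="q1", subject="taxA|s1", evalue=1e-20, bitscore=100.0):
    return HitRecord(
        query_id=query,
        subject_id=subject,
        subject_taxon=subject.split("|")[0],
        percent_identity=50.0,
        align_length=100,
        evalue=evalue,
        bitscore=bitscore,
        extra=("0", "0", "1", "100", "1", "100"),
    )


class TestBestHitPerTaxon:
    def test_cutoff_excludes_weak_hits(self):
        hits = [_hit(evalue=1e-20), _hit(subject="taxA|s2", evalue=1e-5)]
        best = best_hit_per_taxon(hits, cutoff=1e-10)
        assert best["taxA"].subject_id == "taxA|s1"

    def test_evalue_tie_broken_by_higher_bitscore(self):
        hits = [
            _hit(subject="taxB|s1", evalue=1e-15, bitscore=80),
            _hit(subject="taxB|s2", evalue=1e-15, bitscore=95),
        ]
        assert best_hit_per_taxon(hits)["taxB"].bitscore == 95

    def test_full_tie_broken_by_smaller_subject_id(self):
        hits = [
            _hit(subject="taxB|s2", evalue=1e-15, bitscore=95),
            _hit(subject="taxB|s1", evalue=1e-15, bitscore=95),
        ]
        assert best_hit_per_taxon(hits)["taxB"].subject_id == "taxB|s1"

    def test_no_hits_gives_empty_map(self):
        assert best_hit_per_taxon([]) == {}

    def test_taxon_with_no_passing_hit_is_absent(self):
        assert best_hit_per_taxon([_hit(evalue=1e-3)]) == {}

    def test_mixed_queries_rejected(self):
        with pytest.raises(ValueError):
            best_hit_per_taxon([_hit(query="q1"), _hit(query="q2")])

    def test_raising_cutoff_never_removes_passing_representatives(self):
        rng = random.Random(5)
        hits = [
            _hit(
                subject=f"tax{rng.randint(0, 3)}|s{i}",
                evalue=10 ** -rng.uniform(1, 40),
                bitscore=rng.randint(40, 300),
            )
            for i in range(60)
        ]
        low = best_hit_per_taxon(hits, cutoff=1e-20)
        high = best_hit_per_taxon(hits, cutoff=1e-5)
        for taxon, rep in low.items():
            assert high[taxon].evalue <= rep.evalue


class TestBuildGroups:
    def test_one_group_per_query_in_order(self):
        hits = [_hit(), _hit(subject="taxB|s1"), _hit(query="q2", subject="taxC|s9")]
        groups = build_groups(hits, ["q1", "q2"])
        assert [g.query_id for g in groups] == ["q1", "q2"]
        assert groups[0].taxa() == ("taxA", "taxB")

    def test_subject_may_represent_its_taxon_in_several_groups(self):
        hits = [_hit(query="q1"), _hit(query="q2")]
        g1, g2 = build_groups(hits, ["q1", "q2"])
        assert g1.representatives[0][1].subject_id == g2.representatives[0][1].subject_id

    def test_query_with_no_passing_hit_gets_empty_group(self):
        (g,) = build_groups([_hit(evalue=1.0)], ["q1"])
        assert g.representatives == ()

    def test_insensitive_to_hit_row_order(self):
        rng = random.Random(11)
        hits = [
            _hit(
                query=f"q{rng.randint(1, 3)}",
                subject=f"tax{rng.randint(0, 4)}|s{i}",
                evalue=10 ** -rng.uniform(1, 40),
                bitscore=rng.randint(40, 300),
            )
            for i in range(200)
        ]
        shuffled = hits[:]
        rng.shuffle(shuffled)
        queries = ["q1", "q2", "q3"]
        assert build_groups(hits, queries) == build_groups(shuffled, queries)


@given(st.data())
@settings(max_examples=50, derandomize=True, deadline=None)
def test_selection_equals_brute_force_on_random_tables(data):
    """Equivalence with a sort-free full-scan selector."""
    n = data.draw(st.integers(min_value=0, max_value=120))
    evalues = st.sampled_from([1e-30, 1e-20, 1e-15, 1e-12, 1e-8, 1e-3])
    bits = st.sampled_from([50.0, 75.0, 75.0, 120.0])
    hits = [
        _hit(
            subject=f"tax{data.draw(st.integers(min_value=0, max_value=4))}|s{i % 7}",
            evalue=data.draw(evalues),
            bitscore=data.draw(bits),
        )
        for i in range(n)
    ]
    assert best_hit_per_taxon(hits, cutoff=1e-10) == naive_best_hits(hits, 1e-10)


class TestEmitGroupFasta:
    def test_group_of_three_writes_three_records(self, tmp_path):
        hits = [_hit(), _hit(subject="taxB|s1"), _hit(subject="taxC|s1")]
        (group,) = build_groups(hits, ["q1"])
        seqs = {h.subject_id: "MKV" * 20 for h in hits}
        out = tmp_path / "g.fasta"
        emit_group_fasta(group, seqs, out)
        assert len(read_fasta(out)) == 3

    def test_empty_group_writes_empty_fasta(self, tmp_path):
        (group,) = build_groups([], ["q1"])
        out = tmp_path / "g.fasta"
        emit_group_fasta(group, {}, out)
        assert read_fasta(out) == {}

    def test_missing_sequences_error_lists_ids(self, tmp_path):
        (group,) = build_groups([_hit()], ["q1"])
        with pytest.raises(KeyError, match="taxA\\|s1"):
            emit_group_fasta(group, {}, tmp_path / "g.fasta")

    def test_headers_round_trip_through_taxon_rule(self, tmp_path):
        hits = [_hit(), _hit(subject="taxB|s1")]
        (group,) = build_groups(hits, ["q1"])
        seqs = {h.subject_id: "ACDEF" * 10 for h in hits}
        out = tmp_path / "g.fasta"
        emit_group_fasta(group, seqs, out)
        # re-derive taxa from emitted headers with the pipe convention
        tab = tmp_path / "hits.tsv"
        rows = [
            f"q1\t{name}\t50\t100\t0\t0\t1\t100\t1\t100\t1e-20\t100"
            for name in read_fasta(out)
        ]
        tab.write_text("\n".join(rows) + "\n")
        taxa = {r.subject_taxon for r in parse_blast_tab(tab, taxon_rule="pipe")}
        assert taxa == set(group.taxa())
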