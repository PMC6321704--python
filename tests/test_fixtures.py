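"""Synthetic-bundle generation: determinism, ground truth, decoys."""

import os

import pytest

from placorep import architecture, fixtures, io, rules, vocab


def _bundle_bytes(root):
    out = {}
    for dirpath, _, files in os.walk(root):
        for f in files:
            p = os.path.join(dirpath, f)
            out[os.path.relpath(p, root)] = open(p, "rb").read()
    return out


def test_same_seed_regenerates_byte_identical_bundle(tmp_path, h2_bundle):
    again = fixtures.generate_fixture(
        fixtures.h2_repertoire_spec(seed=42), tmp_path / "again"
    )
    assert _bundle_bytes(h2_bundle.root) == _bundle_bytes(again.root)


def test_changing_seed_changes_ids_but_not_family_counts(tmp_path, h2_summary):
    bundle = fixtures.generate_fixture(
        fixtures.h2_repertoire_spec(seed=7), tmp_path / "seed7"
    )
    archs = architecture.build_proteome(
        io.parse_interproscan_tsv(bundle.domains_tsv),
        io.parse_topology_tsv(bundle.topology_tsv),
    )
    ruleset = rules.builtin_ruleset()
    cl = rules.classify_proteome(
        archs, ruleset, io.load_mapping_tables(bundle.mappings_dir)
    )
    summary = rules.summarize(cl, archs, ruleset)
    assert summary["families"] == h2_summary["families"]
    assert summary["subclasses"] == h2_summary["subclasses"]


def test_template_count_is_respected(tmp_path):
    spec = fixtures.FixtureSpec(
        seed=1,
        entries=(
            fixtures.ArchTemplate(
                name="three_tir",
                count=3,
                domains=(fixtures.DomainTemplate(vocab.TIR, 0.4, 0.7),),
                length_range=(200, 300),
            ),
        ),
    )
    bundle = fixtures.generate_fixture(spec, tmp_path / "b")
    hits = io.parse_interproscan_tsv(bundle.domains_tsv)
    assert len({h.protein_id for h in hits}) == 3
    assert all(h.interpro_acc == vocab.TIR for h in hits)


def test_unknown_accession_key_is_rejected():
    with pytest.raises(ValueError, match="not in the rule vocabulary"):
        fixtures.FixtureSpec(
            seed=1,
            entries=(
                fixtures.ArchTemplate(
                    name="bad",
                    count=1,
                    domains=(fixtures.DomainTemplate("IPR999999", 0.1, 0.5),),
                ),
            ),
        )


def test_spec_round_trips_through_yaml(tmp_path):
    spec = fixtures.h2_repertoire_spec(seed=42)
    p = tmp_path / "spec.yaml"
    fixtures.spec_to_yaml(spec, p)
    assert fixtures.spec_from_yaml(p) == spec


def test_manifest_matches_classifier_output_for_non_decoys(
    h2_truth, h2_classifications
):
    """Ground-truth labels equal classification output protein by protein."""
    by_id = {c.protein_id: c for c in h2_classifications}
    for row in h2_truth:
        if row["decoy_for"]:
            continue
        c = by_id[row["protein_id"]]
        subs = frozenset(f"{fam}:{sub}" for fam, sub in c.subclasses)
        assert c.labels == row["labels"], row["template"]
        assert subs == row["subclasses"], row["template"]
        assert c.flags == row["flags"], row["template"]


def test_every_decoy_fails_exactly_its_targeted_clause(
    h2_truth, h2_archs, h2_tables, ruleset
):
    rules_by_name = {r.name: r for r in ruleset}
    by_id = {a.protein_id: a for a in h2_archs}
    targeted = 0
    for row in h2_truth:
        decoy = row["decoy_for"]
        if not decoy or decoy == "ankyrin_background":
            continue
        targeted += 1
        target, clause = decoy.rsplit(":", 1)
        if "/" in target:
            parent, route = target.split("/")
            rule = next(s for s in rules_by_name[parent].any_of if s.name == route)
        else:
            rule = rules_by_name[target]
        res = rules.evaluate_rule(by_id[row["protein_id"]], rule, h2_tables)
        assert not res.passed
        assert res.first_failing == clause
    assert targeted == 4


def test_ankyrin_decoys_receive_no_family_label(h2_truth, h2_classifications):
    by_id = {c.protein_id: c for c in h2_classifications}
    ank = [r for r in h2_truth if r["decoy_for"] == "ankyrin_background"]
    assert len(ank) == 20
    for row in ank:
        assert by_id[row["protein_id"]].labels == frozenset()


def test_no_fixture_protein_carries_a_screened_accession(h2_archs):
    banned = {vocab.RIG_I_CTD, vocab.MAB21, vocab.STING_A, vocab.STING_B,
              vocab.C345C, vocab.ANAPHYLATOXIN}
    for arch in h2_archs:
        assert not (arch.keys & banned)


def test_bundle_is_internally_consistent(h2_bundle, h2_archs):
    seqs = io.read_fasta(h2_bundle.proteins_fasta)
    loci = {l.gene_id for l in io.parse_gff3_loci(h2_bundle.loci_gff3)}
    ids = {a.protein_id for a in h2_archs}
    assert set(seqs) == ids == loci
    lengths = {a.protein_id: a.length for a in h2_archs}
    for pid, seq in seqs.items():
        assert len(seq) == lengths[pid]
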