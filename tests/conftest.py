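import pytest

from placorep import architecture, fixtures, io, rules


@pytest.fixture(scope="session")
def h2_bundle(tmp_path_factory):
    """The packaged H2-repertoire fixture bundle, generated once per run."""
    out = tmp_path_factory.mktemp("h2") / "bundle"
    return fixtures.generate_fixture(fixtures.h2_repertoire_spec(seed=42), out)


@pytest.fixture(scope="session")
def h2_archs(h2_bundle):
    return architecture.build_proteome(
        io.parse_interproscan_tsv(h2_bundle.domains_tsv),
        io.parse_topology_tsv(h2_bundle.topology_tsv),
    )


@pytest.fixture(scope="session")
def h2_tables(h2_bundle):
    return io.load_mapping_tables(h2_bundle.mappings_dir)


@pytest.fixture(scope="session")
def ruleset():
    return rules.builtin_ruleset()


@pytest.fixture(scope="session")
def h2_classifications(h2_archs, h2_tables, ruleset):
    return rules.classify_proteome(h2_archs, ruleset, h2_tables)


@pytest.fixture(scope="session")
def h2_summary(h2_classifications, h2_archs, ruleset):
    return rules.summarize(h2_classifications, h2_archs, ruleset)


@pytest.fixture(scope="session")
def h2_truth(h2_bundle):
    return fixtures.read_truth_manifest(h2_bundle.truth_manifest)
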