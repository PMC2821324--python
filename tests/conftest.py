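import pytest

import blasttriage as bt


@pytest.fixture(scope="session")
def taxonomy_table():
    return bt.fixture_taxonomy()


@pytest.fixture(scope="session")
def mixed_truth():
    """A feature-rich simulated dataset: duplications, splits, partial coverage."""
    return bt.simulate_dataset(
        n_hits=30,
        query_len=150,
        tree_shape="random",
        sub_rate=0.1,
        indel_rate=0.02,
        dup_fraction=0.2,
        split_fraction=0.2,
        coverage_range=(0.5, 1.0),
        seed=7,
    )


@pytest.fixture(scope="session")
def mixed_xml(mixed_truth, tmp_path_factory):
    path = tmp_path_factory.mktemp("xml") / "mixed.xml"
    bt.emit_blast_xml(mixed_truth, path)
    return path


@pytest.fixture(scope="session")
def mixed_result(mixed_xml):
    return bt.parse_blast_xml(mixed_xml)


@pytest.fixture(scope="session")
def annotated_result(mixed_xml, taxonomy_table):
    result = bt.parse_blast_xml(mixed_xml)
    bt.annotate_hits(result, taxonomy_table)
    return result
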