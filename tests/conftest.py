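import pytest

from sdupnet.core import AlignmentRecord, build_duplicated_regions, build_network
from sdupnet.fixtures import FixtureParams, generate_fixture


def make_records(rows):
    """rows: (chrom_a, start_a, end_a, chrom_b, start_b, end_b, identity)."""
    return [AlignmentRecord(i, *row) for i, row in enumerate(rows)]


def net_from_rows(rows):
    records = make_records(rows)
    regions = build_duplicated_regions(records)
    return build_network(regions, records), regions, records


@pytest.fixture(scope="session")
def small_bundle():
    return generate_fixture(FixtureParams(n_duplication_events=80, seed=3))


@pytest.fixture(scope="session")
def no_overlap_bundle():
    return generate_fixture(FixtureParams(n_duplication_events=60, overlap_prob=0.0, seed=5))
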