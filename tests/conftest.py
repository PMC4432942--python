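import io

import pytest
from hypothesis import settings

from contigscope.fixtures import santa_barbara_toy

settings.register_profile("ci", derandomize=True, deadline=None)
settings.load_profile("ci")
from contigscope.ingest import (
    assign_roles,
    attach,
    read_annotations,
    read_metadata_table,
)


@pytest.fixture(scope="session")
def toy():
    """The canned synthetic community (seed 1) plus its ground truth."""
    return santa_barbara_toy(seed=1)


@pytest.fixture(scope="session")
def toy_dataset(toy):
    return toy[0]


@pytest.fixture(scope="session")
def toy_truth(toy):
    return toy[1]


@pytest.fixture(scope="session")
def toy_partition(toy_dataset):
    from contigscope.taxonomy import build_taxonomy_tree, collapse_to_groups

    return collapse_to_groups(build_taxonomy_tree(toy_dataset), k_max=30)


def make_dataset(csv_text, gff_text=None, sequences=None, roles=None):
    """Small-dataset builder for hand-written examples."""
    table = read_metadata_table(io.StringIO(csv_text), dialect="comma")
    roles = roles or {"id": "id"}
    ds = assign_roles(table, roles)
    annotations = (
        read_annotations(io.StringIO(gff_text)) if gff_text is not None else None
    )
    return attach(ds.table, sequences, annotations)
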