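import pytest

from kgrank import (
    build_all_gcs,
    build_index,
    canonical_motifs,
    worked_example_graph,
)


@pytest.fixture(scope="session")
def g0():
    return worked_example_graph()


@pytest.fixture(scope="session")
def g0_motifs():
    # the worked example uses the three canonical evidence motifs
    # (trait co-occurrence, ortholog->pathway, ortholog->process)
    return canonical_motifs()[:3]


@pytest.fixture(scope="session")
def g0_all_gcs(g0, g0_motifs):
    return build_all_gcs(g0, g0_motifs)


@pytest.fixture(scope="session")
def g0_index(g0, g0_all_gcs):
    return build_index(g0, g0_all_gcs)
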