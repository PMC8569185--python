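import types

import pytest
from hypothesis import HealthCheck, settings

from blennymine import homology, mining, synthetic_data

settings.register_profile(
    "default",
    deadline=None,
    derandomize=True,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("default")


@pytest.fixture(scope="session")
def default_fixture():
    """The default mining fixture: 50 planted precursors among 500 decoys.

    mutation_rate=0, so every planted core is the exact human dyn A 1-17;
    decoys are generated without the motif-in-frame property.
    """
    templates = synthetic_data.make_precursor_set(seed=1, n_species=50, mutation_rate=0.0)
    contigs, metadata, manifest = synthetic_data.embed_in_contigs(
        templates, seed=2, n_decoys=500
    )
    query = synthetic_data.make_query_precursor()
    return types.SimpleNamespace(
        templates=templates,
        contigs=contigs,
        metadata=metadata,
        manifest=manifest,
        query=query,
    )


@pytest.fixture(scope="session")
def default_search(default_fixture):
    """Candidate selection + homology search on the default fixture."""
    candidates = mining.select_candidates(default_fixture.contigs)
    hits = homology.search(default_fixture.query, candidates)
    return types.SimpleNamespace(candidates=candidates, hits=hits)
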