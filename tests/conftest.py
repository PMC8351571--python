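import pytest
from hypothesis import settings

from panfix.pipeline import run_full
from panfix.scoring import ScoringParams
from panfix.synth import FixtureConfig, generate

settings.register_profile("ci", derandomize=True, max_examples=50, deadline=None)
settings.load_profile("ci")

#: a small pangenome with one planted event of every kind
SMALL = dict(
    n_genomes=8, n_families=10, n_split_families=1, n_frameshift=1,
    n_element=1, n_end_split=1, n_paralog_decoys=1, seed=11,
)


@pytest.fixture(scope="session")
def params():
    return ScoringParams()


@pytest.fixture()
def small_state():
    """A fresh, un-corrected small pangenome plus its truth manifest."""
    return generate(FixtureConfig(**SMALL))


@pytest.fixture(scope="session")
def small_run():
    """The small pangenome after a full correction run (read-only)."""
    state, manifest = generate(FixtureConfig(**SMALL))
    result = run_full(state)
    return state, manifest, result
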