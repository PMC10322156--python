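"""Shared fixtures: small reservoir pairs for unit tests and the
desk-scale reference table used by the scenario/parameter recovery
experiments (built once per session)."""

import numpy as np
import pytest

from admixhist import synthdata as sd
from admixhist.abc_infer import ReferenceTable

#: desk-scale experiment configuration (scaled-down mirror of the
#: study's 60,000-SNP / 20,000-gamete / 10,000-simulation setup)
DESK_SEED = 123
DESK_SIMS = 500


@pytest.fixture(scope="session")
def tiny_spec():
    return sd.SourcePairSpec(L=1_000, divergence=0.15)


@pytest.fixture(scope="session")
def tiny_reservoirs(tiny_spec):
    rng = np.random.default_rng(7)
    fa, fe = sd.generate_source_frequencies(tiny_spec, rng)
    return sd.make_reservoirs(fa, fe, R=800, rng=rng)


@pytest.fixture(scope="session")
def mini_table():
    """A small 4-scenario reference table for ABC unit tests."""
    df = sd.build_reference_table(
        sims_per_scenario=40, seed=11,
        spec=sd.SourcePairSpec(L=1_000), reservoir_size=800,
    )
    return ReferenceTable(df)


@pytest.fixture(scope="session")
def desk_table():
    """The 4 x 500 desk-scale reference table (L=5000, n=30)."""
    df = sd.build_reference_table(sims_per_scenario=DESK_SIMS, seed=DESK_SEED)
    return ReferenceTable(df)


@pytest.fixture(scope="session")
def desk_reservoirs():
    """The reservoir pair the desk-scale table was built from."""
    root = np.random.default_rng(DESK_SEED)
    fa, fe = sd.generate_source_frequencies(sd.SourcePairSpec(), root)
    return sd.make_reservoirs(fa, fe, sd.DESK_SCALE["reservoir_size"], root)
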