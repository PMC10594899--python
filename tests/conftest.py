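import numpy as np
import pandas as pd
import pytest

from mirlocus.synthdata import SimulationConfig, simulate_all


@pytest.fixture(scope="session")
def default_bundle():
    """One full synthetic input bundle at the default (study-scale) config."""
    return simulate_all(SimulationConfig(seed=0))


@pytest.fixture()
def rng():
    return np.random.default_rng(1234)


def make_annotation(rows):
    """rows: (mirna_id, chrom, start, end, strand) tuples."""
    return pd.DataFrame(rows, columns=["mirna_id", "chrom", "start", "end", "strand"])


@pytest.fixture()
def annotation_builder():
    return make_annotation
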