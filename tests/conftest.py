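import numpy as np
import pytest

from isomirarm.pipeline import run_pipeline
from isomirarm.simulate import SimulationConfig, simulate


@pytest.fixture(scope="session")
def sim_dataset():
    """A moderate paired-library simulation used across test modules."""
    cfg = SimulationConfig(n_hairpins=5, library_depths=(20_000, 20_000), seed=11)
    return simulate(cfg)


@pytest.fixture(scope="session")
def sim_result(sim_dataset):
    ds = sim_dataset
    return run_pipeline(
        ds.hairpins,
        ds.annotations_public,
        ds.libraries[0],
        ds.libraries[1],
        labels=ds.config.library_names,
    )


@pytest.fixture()
def rng():
    return np.random.default_rng(1234)


def brute_force_map(sequence, hairpins, min_len=18):
    """Independent all-substring mapping oracle: scan every hairpin position
    at every trim length, longest first.  Returns (matched length, hits) with
    hits as (hairpin id, 1-based start, 1-based end)."""
    for length in range(len(sequence), min_len - 1, -1):
        prefix = sequence[:length]
        hits = []
        for hid, hp in hairpins.items():
            for i in range(hp.length - length + 1):
                if hp.sequence[i : i + length] == prefix:
                    hits.append((hid, i + 1, i + length))
        if hits:
            return length, hits
    return None, []
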