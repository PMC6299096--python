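import numpy as np
import pytest

from kinclock.emg import EMGParams
from kinclock.lineage import CellRecord, Fate, LineageForest
from kinclock.simulator import generate_fixture_suite


@pytest.fixture(scope="session")
def rng():
    return np.random.default_rng(20181218)


@pytest.fixture(scope="session")
def mild_model_params():
    """A mild two-clock parameter set used by the likelihood oracles."""
    return EMGParams(10.0, 2.0, 0.25), EMGParams(12.0, 3.0, 0.3)


@pytest.fixture()
def tiny_forest():
    """Hand-built 7-cell tree: founder -> 2 daughters -> 4 granddaughters."""
    rows = [
        CellRecord("f0", None, 0.0, 16.0, Fate.DIVIDED),
        CellRecord("f0a", "f0", 16.0, 30.0, Fate.DIVIDED),
        CellRecord("f0b", "f0", 16.0, 34.0, Fate.DIVIDED),
        CellRecord("f0aa", "f0a", 30.0, 46.0, Fate.DIVIDED),
        CellRecord("f0ab", "f0a", 30.0, 48.0, Fate.DIVIDED),
        CellRecord("f0ba", "f0b", 34.0, 50.0, Fate.CENSORED),
        CellRecord("f0bb", "f0b", 34.0, 50.0, Fate.CENSORED),
    ]
    return LineageForest(cells={c.cell_id: c for c in rows},
                         T_d=50.0, T_end=50.0).with_generations()


@pytest.fixture(scope="session")
def fixture_suite(tmp_path_factory):
    """The emulated-experiment fixture files, generated once per session."""
    out = tmp_path_factory.mktemp("fixtures")
    truth = generate_fixture_suite(out, seed=0)
    return out, truth
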