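import sys
import warnings
from pathlib import Path

import numpy as np
import pytest

sys.path.insert(0, str(Path(__file__).parent))  # for the oracle module

from imuposture.io import read_manifest  # noqa: E402
from imuposture.modeling import ModelSpec  # noqa: E402
from imuposture.pipeline import RunConfig, featurize_manifests  # noqa: E402
from imuposture.simulate import SimulationConfig, simulate_dataset  # noqa: E402


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)


@pytest.fixture(scope="session")
def tiny_dataset(tmp_path_factory):
    """6 infants x 1 session x 60 s, well-separated orientations."""
    out = tmp_path_factory.mktemp("tiny_dataset")
    cfg = SimulationConfig(
        n_infants=6, sessions_per_infant=1, session_s=60.0, seed=42
    )
    manifests = simulate_dataset(cfg, out)
    return {"dir": out, "manifests": manifests, "cfg": cfg}


@pytest.fixture(scope="session")
def tiny_sessions(tiny_dataset):
    return [read_manifest(m) for m in tiny_dataset["manifests"]]


@pytest.fixture(scope="session")
def tiny_run_config():
    return RunConfig(seed=5).replace(
        model=ModelSpec(hyperparameters={"n_estimators": 60}, seed=5)
    )


@pytest.fixture(scope="session")
def tiny_table(tiny_dataset, tiny_run_config):
    """Featurised tiny dataset (shared across modeling/importance tests)."""
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        table, windows_by, durations = featurize_manifests(
            tiny_dataset["manifests"], tiny_run_config
        )
    return {"table": table, "windows": windows_by, "durations": durations}
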