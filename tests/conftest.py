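import warnings

import numpy as np
import pytest

from regulome.pipeline import PipelineConfig, run_pipeline
from regulome.synthetic_data import SimulationConfig

warnings.filterwarnings("ignore", category=UserWarning)


@pytest.fixture(scope="session")
def noise_free_run(tmp_path_factory):
    """One noise-free synthetic pipeline run shared across the suite."""
    out = tmp_path_factory.mktemp("noise_free_run")
    cfg = PipelineConfig(seed=1, output_dir=str(out),
                         simulation=SimulationConfig.noise_free())
    return run_pipeline(cfg)


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)
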