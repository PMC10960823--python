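import numpy as np
import pytest

import wetmap as wm


@pytest.fixture(scope="session")
def sim_config():
    return wm.SimulationConfig(extent=(48, 48),
                               years=tuple(range(2000, 2006)),
                               dates_per_year=10, cloud_fraction=0.1, seed=11)


@pytest.fixture(scope="session")
def truth(sim_config):
    return wm.default_truth(sim_config.extent)


@pytest.fixture(scope="session")
def scene(sim_config, truth):
    return wm.simulate_year(sim_config, truth, year=2000)


@pytest.fixture(scope="session")
def dem(sim_config, truth):
    return wm.simulate_dem(sim_config, truth)


@pytest.fixture(scope="session")
def stack(scene, dem):
    return wm.build_feature_stack(scene, dem)


@pytest.fixture(scope="session")
def pipeline_result(tmp_path_factory):
    """One shared small end-to-end run (64x64, 5 years)."""
    out = tmp_path_factory.mktemp("pipeline")
    return wm.run_pipeline({"seed": 7, "out_dir": str(out), "extent": (64, 64),
                            "years": tuple(range(2000, 2005)),
                            "dates_per_year": 12, "cloud_fraction": 0.05,
                            "n_per_class": 40})
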