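import numpy as np
import pytest

from gastrosync import PipelineConfig, SimConfig, gen_cohort


@pytest.fixture(scope="session")
def rng():
    return np.random.default_rng(20230901)


@pytest.fixture(scope="session")
def small_cohort():
    """3 subjects x 2 short runs on a 6^3 grid with strong coupling."""
    cfg = SimConfig(n_subjects=3, runs_per_subject=2, run_duration_s=600,
                    grid_shape=(6, 6, 6), n_coupled_voxels=8,
                    coupling_plv_target=0.7, coupling_between_sd=0.05, seed=11)
    return gen_cohort(cfg)


@pytest.fixture(scope="session")
def pipeline_cfg():
    return PipelineConfig()
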