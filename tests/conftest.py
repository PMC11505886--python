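import numpy as np
import pytest

import msnetdyn as md


@pytest.fixture(scope="session")
def templates60():
    return md.make_templates(60, seed=0)


@pytest.fixture(scope="session")
def small_recording():
    """One default-condition recording with ground truth (20 s, 60 ch)."""
    cfg = md.SyntheticConfig(duration=20.0)
    return md.simulate_recording(cfg, seed=1)


@pytest.fixture(scope="session")
def tiny_cohort_results():
    """Fitted pipeline on a small two-group cohort (19 ch, 8 s, 4/group)."""
    cfg = md.PipelineConfig()
    cfg.synthetic = md.SyntheticConfig(
        n_channels=19, duration=8.0, n_subjects_per_group=4, seed=7
    )
    cfg.kmeans_restarts = 10
    cfg.n_surrogates = 5
    model = md.MicrostateNetworkModel.from_cohort(cfg)
    return model.fit()


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)
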