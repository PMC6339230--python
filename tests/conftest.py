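import numpy as np
import pytest

from pftcal import (
    SyntheticConfig,
    TrainingSet,
    make_ground_truth,
    simulate_session,
)


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


def random_instance(rng, M, m_max=3, n=2):
    """Random training set: features and targets with no planted structure."""
    features = rng.uniform(0, 500, size=(M, n))
    m = rng.integers(1, m_max + 1, size=M)
    targets = [rng.uniform(0, 100, size=(int(mi), 2)) for mi in m]
    return TrainingSet(features, targets)


def planted_session(seed, *, M_scenes=2, fix_per_scene=3, targets=3,
                    attention=1.0, jitter=0.0, sensor=0.0, mirrored=False):
    """Small noise-free (by default) session with planted ground truth."""
    gt = make_ground_truth(900 + seed, mirrored=mirrored)
    cfg = SyntheticConfig(
        n_scenes=M_scenes,
        fixations_per_scene=fix_per_scene,
        targets_per_scene=targets,
        attention_prob=attention,
        fixation_jitter_sigma=jitter,
        sensor_noise_sigma=sensor,
        seed=seed,
    )
    return simulate_session(gt, config=cfg)
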