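import numpy as np
import pytest

from breathomix import CohortConfig, generate_cohort


@pytest.fixture(scope="session")
def small_cohort():
    """14-patient two-class cohort with a clear class effect."""
    cfg = CohortConfig(
        class_sizes={"HNSCC": 8, "colon": 6},
        effect_amplitude=0.15,
        noise_cv=0.05,
        seed=11,
    )
    return generate_cohort(cfg)


@pytest.fixture(scope="session")
def rng():
    return np.random.default_rng(20260920)


def random_positive_tensor(rng, shape=(64, 36, 3)):
    return rng.random(shape) + 0.5


def low_rank_tensor(rng, shape=(64, 36, 3), ranks=(2, 2, 2)):
    """Random tensor with multilinear rank exactly `ranks`."""
    core = rng.standard_normal(ranks)
    u = np.linalg.qr(rng.standard_normal((shape[0], ranks[0])))[0]
    v = np.linalg.qr(rng.standard_normal((shape[1], ranks[1])))[0]
    w = np.linalg.qr(rng.standard_normal((shape[2], ranks[2])))[0]
    return np.einsum("abc,ia,jb,kc->ijk", core, u, v, w)
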