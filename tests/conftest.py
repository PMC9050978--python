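import sys
from pathlib import Path

import numpy as np
import pandas as pd
import pytest

sys.path.insert(0, str(Path(__file__).parent))

import lungrad as lr


@pytest.fixture(scope="session")
def disk_phantom():
    """Noise-free-ish disk lesion with its ground-truth mask."""
    return lr.make_lesion_phantom(lr.PhantomConfig(seed=7))


@pytest.fixture(scope="session")
def spiculated_phantom():
    return lr.make_lesion_phantom(lr.PhantomConfig(seed=7, spiculation_amp=0.3,
                                                   spiculation_freq=8))


def random_roi(rng, max_side=12, n_levels=4):
    """Small random discretized ROI (levels 2-D array + boolean mask)."""
    h = int(rng.integers(2, max_side + 1))
    w = int(rng.integers(2, max_side + 1))
    levels = rng.integers(1, n_levels + 1, size=(h, w))
    mask = rng.random((h, w)) < 0.8
    if not mask.any():
        mask[h // 2, w // 2] = True
    levels = np.where(mask, levels, 0)
    return levels.astype(np.int64), mask


def gaussian_feature_cohort(n, seed, log_hr=None, censor_rate=0.3):
    """Feature table + survival outcomes with Gaussian features and a known
    proportional-hazards structure."""
    rng = np.random.default_rng(seed)
    feats = pd.DataFrame(rng.standard_normal((n, 8)), columns=lr.FEATURE_NAMES)
    cfg = lr.CohortConfig(n_subjects=n, log_hr=log_hr or {},
                          censor_rate=censor_rate, seed=seed + 1)
    rec = lr.simulate_survival(feats, cfg)
    return feats, rec
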