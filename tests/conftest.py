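import sys
from pathlib import Path

import numpy as np
import pytest

sys.path.insert(0, str(Path(__file__).parent))  # for oracles.py

from fetradiomics.io import default_schedule
from fetradiomics.synthesis import ClassTacParams, CohortConfig


@pytest.fixture
def schedule():
    return default_schedule()


@pytest.fixture
def rng():
    return np.random.default_rng(42)


def random_discrete_volume(seed, max_side=6, max_levels=4):
    """Small random levels/mask pair for oracle-equivalence tests."""
    r = np.random.default_rng(seed)
    shape = tuple(r.integers(2, max_side + 1, size=3))
    G = int(r.integers(2, max_levels + 1))
    mask = r.random(shape) > 0.25
    if not mask.any():
        mask.flat[0] = True
    levels = np.zeros(shape, dtype=np.int64)
    levels[mask] = r.integers(1, G + 1, size=int(mask.sum()))
    return levels, mask, G


def deterministic_phantom_config(tbr, slope, ttp=30.0, heterogeneity=0.0, **overrides):
    """Noise-free, blur-free single-class phantom configuration."""
    cp = ClassTacParams(tbr, 0.0, ttp, 0.0, slope, 0.0, heterogeneity=heterogeneity)
    kwargs = dict(
        n_wt=1,
        n_mut=1,
        psf_fwhm_mm=0.0,
        noise_sd=0.0,
        bg_variation_sd=0.0,
        class_params={0: cp, 1: cp},
    )
    kwargs.update(overrides)
    return CohortConfig(**kwargs)
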