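import numpy as np
import pytest

from seafusion.design import class_vector, generate_design, subset
from seafusion.preprocess import fuse, pair_center
from seafusion.simulate import SyntheticSpec, generate_multiomics


@pytest.fixture
def paired_design():
    """Full default design: 24 fish, 12 day-pairs, 4 sites."""
    return generate_design(6)


@pytest.fixture
def muscle_3h_design():
    """One analysis set: 12 muscle samples at 3 h (6 day-pairs)."""
    return subset(generate_design(6, sites=("muscle",)), time="t3h",
                  site="muscle")


def make_fused(seed, block_sizes=None, effect_size=3.0, day_effect_sd=1.0,
               n_planted=20, design=None):
    """Synthetic pair-centered fused dataset + class vector + truth."""
    if design is None:
        design = subset(generate_design(6, sites=("muscle",)),
                        time="t3h", site="muscle")
    spec = SyntheticSpec(seed=seed,
                         block_sizes=block_sizes or {"metabolomics": 100},
                         effect_size=effect_size,
                         day_effect_sd=day_effect_sd, n_planted=n_planted)
    blocks, truth = generate_multiomics(design, spec)
    centered = {n: pair_center(b, design) for n, b in blocks.items()}
    fused = fuse(centered, design)
    y = class_vector(design)
    return fused, y, truth


@pytest.fixture
def rng():
    return np.random.default_rng(12345)
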