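import numpy as np
import pytest

from psma_sink import to_suv
from psma_sink.phantom import (EllipsoidSpec, PhantomConfig, generate_patient)


def build_single_organ(seed, organ="spleen", semi_axes=(18.0, 17.0, 16.0),
                       shape=(40, 40, 40), spacing=(2.0, 2.0, 2.0),
                       noise=0.05, lesions=(), allow_lesion=False,
                       organ_suv=None):
    """One-organ phantom centred on a small grid; returns (suv_vol, mask, phantom)."""
    center = tuple(s * sp / 2.0 for s, sp in zip(shape, spacing))
    cfg = PhantomConfig(
        shape=shape, spacing=spacing,
        organs={organ: [EllipsoidSpec(center, tuple(semi_axes))]},
        lesions=list(lesions), noise_sd_frac=noise, seed=seed,
        allow_lesion_in_organ=allow_lesion)
    if organ_suv is not None:
        cfg.organ_suv = {**cfg.organ_suv, organ: organ_suv}
    ph = generate_patient(cfg)
    return to_suv(ph.pet, ph.meta), ph.organ_masks[organ], ph


@pytest.fixture
def single_organ_phantom():
    return build_single_organ


@pytest.fixture
def rng():
    return np.random.default_rng(12345)
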