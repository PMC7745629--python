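import numpy as np
import pytest

from retmap import phantom as ph
from retmap import registration as reg
from retmap.regressor import Architecture, ModelEnsemble, build_model


@pytest.fixture(scope="session")
def default_cfg() -> ph.PhantomConfig:
    return ph.PhantomConfig()


@pytest.fixture(scope="session")
def noise_free_cfg() -> ph.PhantomConfig:
    return ph.PhantomConfig(speckle_shape=0.0, rit_noise_sd_minutes=0.0)


@pytest.fixture(scope="session")
def small_cohort(default_cfg) -> ph.Cohort:
    return ph.sample_cohort(default_cfg, 12, rng=np.random.default_rng(7))


@pytest.fixture(scope="session")
def tiny_arch() -> Architecture:
    """Smallest architecture accepting the standard 256x64 window."""
    return Architecture(conv_channels=(2, 4), dense_width=4)


def make_constant_image(value: int = 128, height: int = 256, width: int = 64,
                        **kwargs) -> reg.BScanImage:
    defaults = dict(fovea_col=width // 2, lateral_scale_mm_per_px=0.015,
                    axial_scale_mm_per_px=0.0039, patient_id="PX",
                    eye_id="OD", volume_id="VX")
    defaults.update(kwargs)
    pixels = np.full((height, width), value, dtype=np.uint8)
    return reg.BScanImage(pixels=pixels, **defaults)


def make_untrained_ensemble(arch: Architecture, n: int = 1,
                            seed: int = 0,
                            eccentricity_mm: float = 0.0) -> ModelEnsemble:
    models = [build_model(arch, seed + i) for i in range(n)]
    return ModelEnsemble(models=models, eccentricity_mm=eccentricity_mm,
                         architecture=arch, seeds=list(range(seed, seed + n)))
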