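import numpy as np
import pytest

from spineannot.imaging_io import ImageMeta
from spineannot.labelmap import LabelMap, RegionCode
from spineannot.phantom import PhantomConfig, generate


def toy_meta(dim: int) -> ImageMeta:
    return ImageMeta(pixel_spacing_mm=1.0, dimension_px=dim)


def make_label_map(codes: np.ndarray) -> LabelMap:
    codes = np.asarray(codes, dtype=np.int32)
    return LabelMap(codes, toy_meta(codes.shape[0]))


def toy_spine_map(dim: int = 60) -> LabelMap:
    """Minimal hand-built valid map: sacrum + 2 discs + 2 vertebrae."""
    codes = np.full((dim, dim), int(RegionCode.ANTERIOR), dtype=np.int32)
    c0, c1 = 22, 38
    codes[:, c1:50] = RegionCode.POSTERIOR_B
    codes[:, 50:] = RegionCode.POSTERIOR_A
    codes[50:, c0:c1] = RegionCode.SACRUM
    codes[44:50, c0:c1] = RegionCode.IVD
    codes[32:44, c0:c1] = RegionCode.VERTEBRAE
    codes[26:32, c0:c1] = RegionCode.IVD
    codes[14:26, c0:c1] = RegionCode.VERTEBRAE
    return make_label_map(codes)


@pytest.fixture(scope="session")
def phantom_default():
    return generate(PhantomConfig(seed=1))


@pytest.fixture(scope="session")
def phantom_clean():
    """Noise-free, gently tilted study with one disc of each severity band."""
    return generate(
        PhantomConfig(seed=3, grades=(1, 3, 5), noise_sd=0.0, curvature_amp_px=3.0)
    )
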