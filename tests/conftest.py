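import numpy as np
import pytest
from hypothesis import settings

settings.register_profile("suite", deadline=None, derandomize=True)
settings.load_profile("suite")

from tendonkit import histomorph as hm
from tendonkit import synthetic as syn


@pytest.fixture(scope="session")
def ctr_histology_preset():
    return syn.study_histology_preset()


@pytest.fixture(scope="session")
def study_activity_presets():
    return {g: syn.study_activity_preset(*g) for g in syn.GROUPS}


def make_stripes(angle_deg: float, shape=(400, 600), period_px: float = 12.0,
                 pixel_size: float = 0.5) -> hm.FieldImage:
    """Sinusoidal stripes running along ``angle_deg`` (x toward y-down)."""
    yy, xx = np.mgrid[0 : shape[0], 0 : shape[1]].astype(float)
    t = np.radians(angle_deg)
    perp = -np.sin(t) * xx + np.cos(t) * yy
    px = 100.0 + 50.0 * np.sin(2.0 * np.pi * perp / period_px)
    return hm.FieldImage(pixels=px, pixel_size=pixel_size)


@pytest.fixture
def stripe_image():
    return make_stripes
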