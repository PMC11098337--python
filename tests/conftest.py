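import numpy as np
import pytest

from thermotumor import simulate
from thermotumor.config import skin_tumor_preset


@pytest.fixture()
def preset():
    return skin_tumor_preset()


@pytest.fixture(scope="session")
def demo_field():
    """One shared full-model run of the reference scenario on a small grid."""
    cfg = skin_tumor_preset()
    R = cfg.geometry.tumor_radius
    radii = np.array(
        [0.0, 0.25 * R, 0.5 * R, 0.75 * R, R, np.nextafter(R, np.inf),
         1.1 * R, 1.25 * R, 1.5 * R, 2.0 * R, 5.0 * R, 10.0 * R]
    )
    times = np.arange(5.0, 81.0, 5.0)
    return simulate.run(cfg, radii, times)
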