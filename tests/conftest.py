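import numpy as np
import pytest

from flickerspec import Contour


@pytest.fixture
def theta360() -> np.ndarray:
    return np.arange(360) * 2 * np.pi / 360


@pytest.fixture
def circle(theta360) -> Contour:
    return Contour(theta=theta360, radius=np.full(360, 50.0))


def make_contour(theta, radius, center=(0.0, 0.0)) -> Contour:
    return Contour(theta=np.asarray(theta, float),
                   radius=np.asarray(radius, float), center=center)
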