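import numpy as np
import pytest

from fovxtend.geometry import SystemGeometry
from fovxtend.simulate import Phantom, Primitive


@pytest.fixture
def g_centered() -> SystemGeometry:
    """Reference scanner: M=2, 25.6 mm detector, COR on axis."""
    return SystemGeometry(zsm=0.3, zmo=0.2, zod=0.5, p=100e-6, n_col=256)


@pytest.fixture
def g_offset() -> SystemGeometry:
    """Same scanner with a 3.2 mm COR offset (extension factor 1.5)."""
    return SystemGeometry(
        zsm=0.3, zmo=0.2, zod=0.5, p=100e-6, n_col=256, delta_cor=3.2e-3
    )


@pytest.fixture
def disk_phantom() -> Phantom:
    """Homogeneous disk carrying all three contrast densities."""
    return Phantom(
        [Primitive.disk((0.0, 0.0), 5e-3, mu=5.0, delta=1e-7, scatter=3.0)]
    )


@pytest.fixture
def angles_360() -> np.ndarray:
    return np.arange(360) * (2.0 * np.pi / 360)
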