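import numpy as np
import pytest

from cardiobo.forward import GeometrySpec, CylindricalLVModel


@pytest.fixture(scope="session")
def default_geometry() -> GeometrySpec:
    return GeometrySpec()


@pytest.fixture(scope="session")
def default_model(default_geometry) -> CylindricalLVModel:
    return CylindricalLVModel(default_geometry)


@pytest.fixture()
def rng() -> np.random.Generator:
    return np.random.default_rng(20260923)


def random_unimodular(rng: np.random.Generator, scale: float = 0.2) -> np.ndarray:
    """A random deformation gradient with det F = 1."""
    A = np.eye(3) + scale * rng.standard_normal((3, 3))
    d = np.linalg.det(A)
    if d < 0:
        A[0] *= -1.0
        d = -d
    return A / d ** (1.0 / 3.0)
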