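import numpy as np
import pytest

from frcm3d.synthetic import ShapeSpec, make_shape


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture
def random_volume_16(rng):
    return rng.random((16, 16, 16))


@pytest.fixture
def random_volume_8(rng):
    return rng.random((8, 8, 8))


@pytest.fixture(scope="session")
def lobe_shape_48():
    """Asymmetric triaxial reference shape on a 48^3 grid."""
    return make_shape(ShapeSpec("two_lobe", dims=(48, 48, 48), seed=3))


def gauss_chebyshev_gram(n_max: int, alpha: float, quad_points: int = 256) -> np.ndarray:
    """Independent quadrature oracle for the basis Gram matrix.

    Substituting ``u = x**alpha`` turns the inner product of two
    fractional basis functions into the classical Chebyshev-weighted
    integral ``(1/(d_n d_m)) * int T̄_n(u) T̄_m(u) / sqrt(u - u^2) du``,
    which Gauss-Chebyshev quadrature evaluates exactly for polynomial
    integrands of degree < 2 * quad_points.  Never touches the production
    evaluation path for the integral itself.
    """
    from frcm3d.basis import norm_constant, shifted_chebyshev_table

    k = np.arange(1, quad_points + 1)
    u = 0.5 * (1.0 + np.cos((2 * k - 1) * np.pi / (2 * quad_points)))
    tab = shifted_chebyshev_table(n_max, u)
    d = np.sqrt([norm_constant(n) for n in range(n_max + 1)])
    scaled = tab / d[:, None]
    return (np.pi / quad_points) * scaled @ scaled.T
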