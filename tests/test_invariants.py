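from fractions import Fraction

import numpy as np
import pytest

from frcm3d.invariants import (
    Centroid,
    NormalizationAngles,
    canonical_rotation,
    central_moment,
    centroid,
    descriptor,
    frcmi,
    frcmi_tensor,
    frgm,
    frgmi,
    frgmi_tensor,
    mu_pqr,
    mu_sums,
    normalization_angles,
    principal_rotation,
    rotation_matrix,
    rpow,
    second_moment_tensor,
)
from frcm3d.invariants import _recombine
from frcm3d.moments import grid_coordinates
from frcm3d.synthetic import NoiseSpec, RigidTransform, ShapeSpec, add_noise, apply_transform, make_shape

PRESET1 = (1.4, 1.4, 1.4)


def dense_frgm_oracle(volume, p, q, r, alphas, subdiv=16384):
    """Midpoint-subdivision numeric integration, per axis (separable).

    The heavy subdivision controls the midpoint error of the mildly
    singular ``x**(alpha*e)`` integrand near 0 for ``alpha*e < 1``.
    """
    vol = np.asarray(volume, dtype=float)
    facs = []
    for d, a, e in zip(vol.shape, alphas, (p, q, r)):
        edges = np.arange(d + 1) / d
        fine = (
            edges[:-1, None]
            + (np.arange(subdiv)[None, :] + 0.5) * (1.0 / d / subdiv)
        )
        facs.append((fine ** (a * e)).sum(axis=1) / (d * subdiv))
    return float(np.einsum("ijk,i,j,k->", vol, *facs))


def dense_central_oracle(volume, p, q, r, alphas, center, subdiv=16384):
    vol = np.asarray(volume, dtype=float)
    facs = []
    for d, a, e, c in zip(vol.shape, alphas, (p, q, r), center.as_array()):
        edges = np.arange(d + 1) / d
        fine = (
            edges[:-1, None]
            + (np.arange(subdiv)[None, :] + 0.5) * (1.0 / d / subdiv)
        )
        ex = Fraction(a).limit_denominator(99) * e
        facs.append(rpow(fine - c, ex).sum(axis=1) / (d * subdiv))
    return float(np.einsum("ijk,i,j,k->", vol, *facs))


def _poly_mult(a: dict, b: dict) -> dict:
    out: dict = {}
    for ka, va in a.items():
        for kb, vb in b.items():
            k = (ka[0] + kb[0], ka[1] + kb[1], ka[2] + kb[2])
            out[k] = out.get(k, 0.0) + va * vb
    return out


def exact_rotated_oracle(volume, p, q, r, center, R):
    """Exact integral of the rotated integrand for integer exponents.

    Expands ``prod_a (R[a,:] . v)**e_a`` multinomially and integrates each
    monomial per cell in closed form -- an oracle fully independent of the
    Gauss-Legendre path.
    """
    vol = np.asarray(volume, dtype=float)
    poly = {(0, 0, 0): 1.0}
    for axis, e in enumerate((p, q, r)):
        lin = {(1, 0, 0): R[axis, 0], (0, 1, 0): R[axis, 1], (0, 0, 1): R[axis, 2]}
        for _ in range(e):
            poly = _poly_mult(poly, lin)
    total = 0.0
    ctr = center.as_array()
    for (kx, ky, kz), coeff in poly.items():
        facs = []
        for d, k, c in zip(vol.shape, (kx, ky, kz), ctr):
            edges = np.arange(d + 1) / d - c
            facs.append(np.diff(edges ** (k + 1)) / (k + 1))
        total += coeff * float(np.einsum("ijk,i,j,k->", vol, *facs))
    return total


class TestRpow:
    def test_integer_exponents_are_ordinary_powers(self):
        v = np.array([-2.0, -0.5, 0.0, 0.5, 2.0])
        np.testing.assert_allclose(rpow(v, 2), v**2)
        np.testing.assert_allclose(rpow(v, 3), v**3)

    def test_odd_root_sign_follows_numerator_parity(self):
        # (-8)^(1/3) = -2 (odd numerator); (-8)^(2/3) = 4 (even numerator)
        assert rpow(-8.0, Fraction(1, 3)) == pytest.approx(-2.0)
        assert rpow(-8.0, Fraction(2, 3)) == pytest.approx(4.0)

    def test_even_denominator_rejected(self):
        with pytest.raises(ValueError):
            rpow(-1.0, Fraction(1, 2))


class TestFrgm:
    def test_uniform_mass(self):
        u = np.ones((8, 8, 8))
        assert frgm(u, 0, 0, 0, (1, 1, 1)) == pytest.approx(1.0, rel=1e-12)

    def test_uniform_first_moment(self):
        u = np.ones((8, 8, 8))
        assert frgm(u, 1, 0, 0, (1, 1, 1)) == pytest.approx(0.5, rel=1e-12)

    def test_matches_dense_oracle_fractional(self, random_volume_8):
        alphas = (1.4, 1.0, 0.8)
        got = frgm(random_volume_8, 2, 1, 1, alphas)
        want = dense_frgm_oracle(random_volume_8, 2, 1, 1, alphas)
        assert got == pytest.approx(want, rel=1e-8)


class TestCentroid:
    def test_uniform_volume_centered(self):
        c = centroid(np.ones((8, 8, 8)))
        assert (c.x, c.y, c.z) == pytest.approx((0.5, 0.5, 0.5), rel=1e-12)

    def test_symmetric_shape_centered(self):
        c = centroid(make_shape(ShapeSpec("sphere", dims=(32, 32, 32))))
        assert (c.x, c.y, c.z) == pytest.approx((0.5, 0.5, 0.5), abs=1e-6)

    def test_degenerate_volume_rejected(self):
        with pytest.raises(ValueError, match="degenerate"):
            centroid(np.zeros((4, 4, 4)))


class TestCentralMoment:
    def test_order_zero_equals_frgm(self, random_volume_8):
        c = centroid(random_volume_8)
        got = central_moment(random_volume_8, 0, 0, 0, PRESET1, c)
        assert got == pytest.approx(frgm(random_volume_8, 0, 0, 0, PRESET1), rel=1e-12)

    def test_first_central_moment_vanishes(self, random_volume_8):
        c = centroid(random_volume_8)
        eta100 = central_moment(random_volume_8, 1, 0, 0, (1, 1, 1), c)
        assert abs(eta100) < 1e-10

    def test_matches_dense_oracle(self, random_volume_8):
        c = centroid(random_volume_8)
        got = central_moment(random_volume_8, 2, 1, 1, (1.4, 1.0, 0.8), c)
        want = dense_central_oracle(random_volume_8, 2, 1, 1, (1.4, 1.0, 0.8), c)
        assert got == pytest.approx(want, rel=1e-6)

    def test_integer_translation_invariance(self):
        base = make_shape(ShapeSpec("two_lobe", dims=(64, 64, 64), seed=1))
        shifted = apply_transform(base, RigidTransform(translation=(4.0, 0.0, 0.0)))
        e0 = central_moment(base, 2, 1, 1, PRESET1, centroid(base))
        e1 = central_moment(shifted, 2, 1, 1, PRESET1, centroid(shifted))
        assert abs(e1 - e0) / abs(e0) < 0.01


class TestAnglesAndRotation:
    def test_isotropic_volume_gives_zero_angles(self):
        ang = normalization_angles(make_shape(ShapeSpec("sphere", dims=(32, 32, 32))))
        assert (ang.theta, ang.phi, ang.psi) == pytest.approx((0, 0, 0), abs=1e-6)

    def test_axis_aligned_ellipsoid_gives_zero_angles(self):
        ang = normalization_angles(make_shape(ShapeSpec("ellipsoid", dims=(32, 32, 32))))
        assert (ang.theta, ang.phi, ang.psi) == pytest.approx((0, 0, 0), abs=1e-6)

    def test_small_rotation_recovers_half_arctangent_value(self):
        base = make_shape(ShapeSpec("ellipsoid", dims=(48, 48, 48)))
        rot = apply_transform(base, RigidTransform(angles=(0.1, 0.0, 0.0)))
        sig = second_moment_tensor(rot)
        ang = normalization_angles(sigma=sig)
        expect = 0.5 * np.arctan2(2 * sig[1, 2], sig[1, 1] + sig[2, 2])
        assert ang.theta == pytest.approx(expect, rel=1e-12)
        assert ang.theta != 0.0

    def test_identity_rotation(self):
        np.testing.assert_allclose(
            rotation_matrix(NormalizationAngles(0, 0, 0)), np.eye(3), atol=1e-15
        )

    def test_rotation_group_properties(self, rng):
        for _ in range(5):
            ang = NormalizationAngles(*rng.uniform(-np.pi, np.pi, 3))
            R = rotation_matrix(ang)
            np.testing.assert_allclose(R @ R.T, np.eye(3), atol=1e-12)
            assert np.linalg.det(R) == pytest.approx(1.0, abs=1e-12)

    def test_quarter_turn_symbolic_entries(self):
        # theta = pi/2, phi = psi = 0: sin(theta)=1, cos(theta)=0
        R = rotation_matrix(NormalizationAngles(np.pi / 2, 0.0, 0.0))
        expect = np.array([[1, 0, 0], [0, 0, 1], [0, -1, 0]], dtype=float)
        np.testing.assert_allclose(R, expect, atol=1e-15)

    def test_principal_rotation_diagonalizes(self):
        vol = make_shape(ShapeSpec("two_lobe", dims=(32, 32, 32), seed=2))
        sig = second_moment_tensor(vol)
        R = principal_rotation(sigma=sig)
        D = R @ sig @ R.T
        off = np.abs(D - np.diag(np.diag(D))).max()
        assert off < 1e-18
        assert D[0, 0] >= D[1, 1] >= D[2, 2]


class TestMuQuadrature:
    def test_identity_rotation_matches_closed_form(self, random_volume_8):
        """Even orders: positive integrand, relative comparison is meaningful."""
        c = centroid(random_volume_8)
        for pqr in [(2, 0, 0), (2, 2, 0), (2, 2, 2)]:
            closed = central_moment(random_volume_8, *pqr, PRESET1, c)
            quad = mu_pqr(random_volume_8, *pqr, PRESET1, c, np.eye(3), nodes=4)
            assert quad == pytest.approx(closed, rel=1e-6)

    def test_identity_rotation_odd_orders_scale_relative(self, random_volume_8):
        """Odd orders cancel across cells; compare on the tensor scale."""
        c = centroid(random_volume_8)
        M = mu_sums(random_volume_8, 2, PRESET1, c, np.eye(3), nodes=8)
        scale = np.abs(M).max()
        for pqr in [(1, 1, 0), (2, 1, 1)]:
            closed = central_moment(random_volume_8, *pqr, PRESET1, c)
            assert abs(M[pqr] - closed) < 1e-6 * scale

    def test_integer_alpha_random_rotation_matches_exact_oracle(self, rng):
        vol = rng.random((8, 8, 8))
        c = centroid(vol)
        R = rotation_matrix(NormalizationAngles(*rng.uniform(-1, 1, 3)))
        got = mu_pqr(vol, 2, 1, 1, (1, 1, 1), c, R, nodes=4)
        want = exact_rotated_oracle(vol, 2, 1, 1, c, R)
        assert got == pytest.approx(want, rel=1e-6)

    def test_node_count_self_convergence(self, rng):
        vol = rng.random((16, 16, 16))
        c = centroid(vol)
        R = rotation_matrix(NormalizationAngles(0.3, -0.2, 0.1))
        M8 = mu_sums(vol, 2, PRESET1, c, R, nodes=8)
        M16 = mu_sums(vol, 2, PRESET1, c, R, nodes=16)
        assert np.abs(M16 - M8).max() < 1e-8 * np.abs(M16).max()

    def test_invalid_node_count(self, random_volume_8):
        with pytest.raises(ValueError):
            mu_sums(random_volume_8, 1, PRESET1, centroid(random_volume_8), np.eye(3), nodes=0)


class TestFrgmi:
    def test_order_zero_is_one_exactly(self):
        for seed in (0, 1):
            vol = make_shape(ShapeSpec("two_lobe", dims=(24, 24, 24), seed=seed))
            assert frgmi(vol, 0, 0, 0, PRESET1) == pytest.approx(1.0, abs=1e-12)

    def test_sphere_axis_exchange_symmetry(self):
        vol = make_shape(ShapeSpec("sphere", dims=(48, 48, 48)))
        g = frgmi_tensor(vol, 2, PRESET1, nodes=2)
        assert g[2, 0, 0] == pytest.approx(g[0, 2, 0], abs=1e-3 * abs(g[2, 0, 0]) + 1e-9)

    def test_degenerate_volume_rejected(self):
        with pytest.raises(ValueError):
            frgmi(np.zeros((4, 4, 4)), 1, 0, 0, PRESET1)


class TestFrcmi:
    def test_order_zero_closed_form(self):
        """FrCMI_000 = FrGMI_000 / pi^3 since B[0,0] = 1 and d_0^2 = pi."""
        vol = make_shape(ShapeSpec("box", dims=(24, 24, 24)))
        assert frcmi(vol, 0, 0, 0, PRESET1) == pytest.approx(np.pi**-3, rel=1e-9)

    def test_linear_in_frgmi(self, rng):
        G = rng.standard_normal((4, 4, 4))
        np.testing.assert_allclose(_recombine(2.0 * G), 2.0 * _recombine(G), rtol=1e-12)

    def test_descriptor_lengths(self):
        vol = make_shape(ShapeSpec("sphere", dims=(8, 8, 8), smooth=0.5, size=0.9))
        assert len(descriptor(vol, 0, PRESET1, nodes=1)) == 1
        assert len(descriptor(vol, 3, PRESET1, nodes=1)) == 64

    def test_descriptor_max_order_dimensionality(self):
        """r_max = 19 gives the full 8000-dimensional input vector."""
        vol = make_shape(ShapeSpec("sphere", dims=(8, 8, 8), smooth=0.5, size=0.9))
        assert len(descriptor(vol, 19, PRESET1, nodes=1)) == 8000

    def test_raw_moment_descriptor_flag(self):
        vol = make_shape(ShapeSpec("sphere", dims=(16, 16, 16)))
        d = descriptor(vol, 2, (1.2, 1.0, 1.2), invariant=False)
        from frcm3d.basis import BasisSpec
        from frcm3d.moments import compute_frcm

        m = compute_frcm(vol, BasisSpec.make(2, (1.2, 1.0, 1.2))).values
        np.testing.assert_allclose(d.values, m.reshape(-1))


class TestRSTInvariance:
    def test_descriptor_stable_under_rigid_transforms(self, lobe_shape_48):
        """Rotation+scale+translation moves descriptor components < 10%."""
        rng = np.random.default_rng(7)
        descs = [frcmi_tensor(lobe_shape_48, 3, PRESET1, nodes=2).reshape(-1)]
        for _ in range(4):
            t = RigidTransform(
                angles=tuple(rng.uniform(-np.pi / 6, np.pi / 6, 3)),
                scale=float(rng.uniform(0.8, 1.2)),
                translation=tuple(rng.integers(-2, 3, 3).astype(float)),
            )
            moved = apply_transform(lobe_shape_48, t)
            descs.append(frcmi_tensor(moved, 3, PRESET1, nodes=2).reshape(-1))
        D = np.array(descs)
        rel_sd = D.std(axis=0) / np.abs(D.mean(axis=0))
        assert rel_sd.max() < 0.10

    def test_noise_grows_moment_distortion_monotonically(self, lobe_shape_48):
        """Central fractional moment distortion rises with noise density.

        Measured before scale normalization: the lambda**-gamma factor
        renormalizes noisy volumes nonmonotonically, but the underlying
        moment error grows essentially linearly with the noise density.
        """
        c = centroid(lobe_shape_48)
        R = canonical_rotation(lobe_shape_48)
        M0 = mu_sums(lobe_shape_48, 3, PRESET1, c, R, nodes=2)
        dist = []
        for level in (0.01, 0.02, 0.03, 0.04, 0.05):
            noisy = add_noise(lobe_shape_48, NoiseSpec(level, seed=42))
            M = mu_sums(noisy, 3, PRESET1, centroid(noisy), canonical_rotation(noisy), nodes=2)
            dist.append(np.linalg.norm(M - M0) / np.linalg.norm(M0))
        assert all(b > a for a, b in zip(dist, dist[1:]))


class TestCanonicalRotation:
    def test_proper_rotation(self, lobe_shape_48):
        R = canonical_rotation(lobe_shape_48)
        np.testing.assert_allclose(R @ R.T, np.eye(3), atol=1e-12)
        assert np.linalg.det(R) == pytest.approx(1.0, abs=1e-10)

    def test_consistent_across_rotation(self, lobe_shape_48):
        t = RigidTransform(angles=(0.4, -0.3, 0.25))
        moved = apply_transform(lobe_shape_48, t)
        R0 = canonical_rotation(lobe_shape_48)
        R1 = canonical_rotation(moved)
        # undoing the applied rotation must recover the same frame
        np.testing.assert_allclose(R1 @ t.matrix, R0, atol=0.05)
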