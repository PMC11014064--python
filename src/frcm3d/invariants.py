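"""Rotation/scale/translation invariants from fractional geometric moments.

Pipeline, for a voxel volume ``f`` on the unit cube:

1. fractional geometric moments ``FrGM_pqr`` with exact per-cell integrals
   of the separable integrand ``x**(ax*p) y**(ay*q) z**(az*r)``;
2. the intensity centroid (first-order classical moments), which removes
   translation;
3. second-order central moments -> a canonical principal-axes rotation
   (exact diagonalization of the second-moment tensor, axes ordered by
   descending principal moment, signs fixed by third-order skewness),
   which removes rotation; the one-shot half-arctangent angle formulas
   are exposed separately in :func:`normalization_angles`;
4. rotated central fractional moments ``mu_pqr`` by per-cell tensor-product
   Gauss-Legendre quadrature (the rotated integrand is non-separable);
5. scale normalization by ``lambda**(-gamma)`` with ``lambda = FrGM_000``
   and ``gamma = 1 + (ax*p + ay*q + az*r)/3``, giving ``FrGMI_pqr``;
6. fractional Chebyshev moment invariants ``FrCMI_nmp`` as the monomial
   recombination ``1/(d_n^2 d_m^2 d_p^2) * sum B[n,l]B[m,s]B[p,r] FrGMI_lsr``
   with per-axis fractional exponents ``alpha * l``.

Signed fractional powers use the exact real odd root: for ``alpha = a/b``
with ``b`` odd, ``v**alpha = sign(v)**a * |v|**alpha``.  This reduces to the
ordinary power at integer exponents (so the alpha=1 case is classical) and
makes the closed-form antiderivative ``rpow(v, e+1)/(e+1)`` exact.  It is
the reason the invariant route requires odd root denominators.
"""

from __future__ import annotations

from dataclasses import dataclass
from fractions import Fraction

import numpy as np

from .basis import BasisSpec, FractionalOrder, coefficient_table, norm_constant
from .moments import VoxelGrid, compute_frcm, grid_coordinates

__all__ = [
    "Centroid",
    "canonical_rotation",
    "NormalizationAngles",
    "InvariantDescriptor",
    "rpow",
    "frgm",
    "centroid",
    "central_moment",
    "second_moment_tensor",
    "normalization_angles",
    "rotation_matrix",
    "principal_rotation",
    "mu_pqr",
    "mu_sums",
    "frgmi",
    "frgmi_tensor",
    "frcmi",
    "frcmi_tensor",
    "descriptor",
]


@dataclass(frozen=True)
class Centroid:
    x: float
    y: float
    z: float

    def as_array(self) -> np.ndarray:
        return np.array([self.x, self.y, self.z])


@dataclass(frozen=True)
class NormalizationAngles:
    """Half-arctangent angles (radians), each in (-pi/2, pi/2]."""

    theta: float
    phi: float
    psi: float


@dataclass(frozen=True)
class InvariantDescriptor:
    """FrCMI values for all (n, m, p) <= r_max, lexicographic order."""

    values: np.ndarray
    spec: BasisSpec

    def __len__(self) -> int:
        return self.values.size


def _coerce_alphas(alphas) -> tuple[FractionalOrder, ...]:
    out = tuple(FractionalOrder.coerce(a) for a in alphas)
    if len(out) != 3:
        raise ValueError("three fractional orders required")
    return out


def rpow(v, e: Fraction | int):
    """Real signed power ``v**e`` for rational ``e`` with odd denominator."""
    e = Fraction(e)
    v = np.asarray(v, dtype=float)
    if e == 0:
        return np.ones_like(v)
    if e.denominator % 2 == 0:
        raise ValueError(f"exponent {e} has an even root denominator")
    r = np.abs(v) ** float(e)
    if e.numerator % 2 == 1:
        r = np.copysign(r, v)
    return r


# ---------------------------------------------------------------------------
# fractional geometric moments, closed-form per-cell integrals


def _cell_edges(n: int) -> np.ndarray:
    return np.arange(n + 1) / n


def frgm(volume, p: int, q: int, r: int, alphas) -> float:
    """``FrGM_pqr`` with exact (closed-form) per-cell monomial integrals."""
    vol = VoxelGrid.coerce(volume)
    ax, ay, az = _coerce_alphas(alphas)
    facs = []
    for d, a, e_ord in zip(vol.dims, (ax, ay, az), (p, q, r)):
        c = float(a.alpha) * e_ord + 1.0
        edges = _cell_edges(d) ** c
        facs.append(np.diff(edges) / c)
    return float(np.einsum("ijk,i,j,k->", vol.data, *facs))


def centroid(volume) -> Centroid:
    """Intensity centroid from classical first-order geometric moments."""
    vol = VoxelGrid.coerce(volume)
    ones = (1.0, 1.0, 1.0)
    m000 = frgm(vol, 0, 0, 0, ones)
    if m000 <= 0:
        raise ValueError("degenerate volume: nonpositive total mass")
    return Centroid(
        frgm(vol, 1, 0, 0, ones) / m000,
        frgm(vol, 0, 1, 0, ones) / m000,
        frgm(vol, 0, 0, 1, ones) / m000,
    )


def central_moment(volume, p: int, q: int, r: int, alphas, center: Centroid) -> float:
    """Translation-invariant central moment ``eta_pqr`` (closed form).

    Per axis, the antiderivative of the signed-power integrand gives
    ``(rpow(u_{i+1}-c, e+1) - rpow(u_i-c, e+1)) / (e+1)`` with ``e`` the
    rational exponent ``alpha * order``.
    """
    vol = VoxelGrid.coerce(volume)
    ax, ay, az = _coerce_alphas(alphas)
    ctr = center.as_array()
    facs = []
    for d, a, e_ord, c0 in zip(vol.dims, (ax, ay, az), (p, q, r), ctr):
        if e_ord > 0:
            a.require_odd_denominator()
        e1 = a.fraction * e_ord + 1
        anti = rpow(_cell_edges(d) - c0, e1)
        facs.append(np.diff(anti) / float(e1))
    return float(np.einsum("ijk,i,j,k->", vol.data, *facs))


def second_moment_tensor(volume, center: Centroid | None = None) -> np.ndarray:
    """Classical (alpha = 1) second-order central moment matrix."""
    vol = VoxelGrid.coerce(volume)
    ctr = center if center is not None else centroid(vol)
    coords = grid_coordinates(vol.dims)
    v = [c - o for c, o in zip(coords, ctr.as_array())]
    N, M, K = vol.dims
    dv = 1.0 / (N * M * K)
    f = vol.data
    sig = np.empty((3, 3))
    mats = []
    # first moments of f along each pair of axes via midpoint rule
    for axis_vals, axis in zip(v, range(3)):
        shape = [1, 1, 1]
        shape[axis] = -1
        mats.append(axis_vals.reshape(shape))
    for i in range(3):
        for j in range(i, 3):
            sig[i, j] = sig[j, i] = float(np.sum(f * mats[i] * mats[j])) * dv
    return sig


def normalization_angles(volume=None, sigma: np.ndarray | None = None) -> NormalizationAngles:
    """Half-arctangent angles from second-order central moments.

    ``theta = atan2(2*eta011, eta020 + eta002) / 2`` and cyclically for
    ``phi`` (eta101 over eta200 + eta002) and ``psi`` (eta110 over
    eta200 + eta020).  Both arguments below 1e-12 (isotropic degenerate
    case) give angle 0.
    """
    if sigma is None:
        sigma = second_moment_tensor(volume)
    e200, e020, e002 = sigma[0, 0], sigma[1, 1], sigma[2, 2]
    e110, e101, e011 = sigma[0, 1], sigma[0, 2], sigma[1, 2]

    def half_atan(num, den):
        if abs(num) < 1e-12 and abs(den) < 1e-12:
            return 0.0
        return 0.5 * np.arctan2(num, den)

    return NormalizationAngles(
        theta=half_atan(2.0 * e011, e020 + e002),
        phi=half_atan(2.0 * e101, e200 + e002),
        psi=half_atan(2.0 * e110, e200 + e020),
    )


def rotation_matrix(angles: NormalizationAngles) -> np.ndarray:
    """Tait-Bryan rotation ``R = Rx(theta) Ry(phi) Rz(psi)`` entry by entry."""
    ct, st = np.cos(angles.theta), np.sin(angles.theta)
    cp, sp = np.cos(angles.phi), np.sin(angles.phi)
    cs, ss = np.cos(angles.psi), np.sin(angles.psi)
    return np.array(
        [
            [cp * cs, cp * ss, -sp],
            [st * sp * cs - ct * ss, st * sp * ss + ct * cs, cp * st],
            [ct * sp * cs + st * ss, ct * sp * ss - st * cs, ct * cp],
        ]
    )


def principal_rotation(volume=None, sigma: np.ndarray | None = None) -> np.ndarray:
    """Principal-axes frame: exact diagonalization of the second-moment tensor.

    Rows are the principal directions ordered by descending principal
    second moment, so ``R @ sigma @ R.T`` is diagonal to machine
    precision.  The single half-arctangent step of
    :func:`normalization_angles` only approximates this frame (and
    applying it repeatedly does not converge, because its denominators
    couple the three planes); descriptor invariance needs the exact frame.
    Axis signs are left arbitrary here; :func:`canonical_rotation`
    resolves them.
    """
    if sigma is None:
        sigma = second_moment_tensor(volume)
    _, vecs = np.linalg.eigh(sigma)
    R = vecs[:, ::-1].T
    if np.linalg.det(R) < 0:
        R = R * np.array([1.0, 1.0, -1.0])[:, None]
    return R


def _axis_skewness(volume, center: Centroid, R: np.ndarray) -> np.ndarray:
    """Third-order moment of f along each rotated principal axis."""
    vol = VoxelGrid.coerce(volume)
    coords = grid_coordinates(vol.dims)
    ctr = center.as_array()
    v = [c - o for c, o in zip(coords, ctr)]
    shapes = [(-1, 1, 1), (1, -1, 1), (1, 1, -1)]
    out = np.empty(3)
    for a in range(3):
        proj = sum(R[a, ax] * v[ax].reshape(shapes[ax]) for ax in range(3))
        out[a] = float(np.sum(vol.data * proj**3))
    return out / vol.data.size


def canonical_rotation(volume, center: Centroid | None = None) -> np.ndarray:
    """Fully canonical principal-axes frame for invariant descriptors.

    :func:`principal_rotation` diagonalizes the second-moment tensor but
    leaves the axis ordering and axis signs arbitrary (they depend on the
    starting orientation), which would make descriptors of rotated copies
    incomparable.  This resolves both: axes are ordered by descending
    principal second moment, each axis sign is chosen so the third-order
    moment along it is nonnegative, and a proper rotation (det +1) is
    restored, if needed, by flipping the axis with the smallest absolute
    skewness.
    """
    vol = VoxelGrid.coerce(volume)
    ctr = center if center is not None else centroid(vol)
    sigma = second_moment_tensor(vol, ctr)
    R = principal_rotation(sigma=sigma)
    skew = _axis_skewness(vol, ctr, R)
    flips = np.where(skew < 0.0, -1.0, 1.0)
    if flips.prod() < 0:
        weakest = int(np.argmin(np.abs(skew)))
        flips[weakest] = -flips[weakest]
    return flips[:, None] * R


# ---------------------------------------------------------------------------
# rotated central fractional moments (Gauss-Legendre per cell)


def _gauss_offsets(dims, nodes: int):
    """Tensor-product GL offsets (Q, 3) within a cell and weights (Q,)."""
    if nodes < 1:
        raise ValueError("quadrature must use at least one node per axis")
    g, w = np.polynomial.legendre.leggauss(nodes)
    deltas = [1.0 / d for d in dims]
    axes_pts = [0.5 * dx * g for dx in deltas]
    axes_wts = [0.5 * dx * w for dx in deltas]
    px, py, pz = np.meshgrid(*axes_pts, indexing="ij")
    wx, wy, wz = np.meshgrid(*axes_wts, indexing="ij")
    offsets = np.stack([px.ravel(), py.ravel(), pz.ravel()], axis=1)
    weights = (wx * wy * wz).ravel()
    return offsets, weights


def _exponents(alpha: FractionalOrder, r_max: int) -> list[Fraction]:
    return [alpha.fraction * l for l in range(r_max + 1)]


def mu_sums(volume, r_max: int, alphas, center: Centroid,
            R: np.ndarray, nodes: int = 4, chunk: int = 250_000) -> np.ndarray:
    """All aggregates ``M[p,q,r] = sum_ijk f_ijk mu_pqr`` for orders <= r_max.

    Quadrature points are shared across orders; per-axis signed powers are
    computed once per exponent and combined by matrix products.  Cells with
    zero intensity are skipped.
    """
    vol = VoxelGrid.coerce(volume)
    ax, ay, az = (FractionalOrder.coerce(a).require_odd_denominator() for a in alphas)
    coords = grid_coordinates(vol.dims)
    mask = vol.data != 0.0
    idx = np.nonzero(mask)
    f = vol.data[mask]
    centers = np.stack(
        [coords[0][idx[0]], coords[1][idx[1]], coords[2][idx[2]]], axis=1
    )
    centers -= center.as_array()[None, :]
    offsets, wts = _gauss_offsets(vol.dims, nodes)
    Q = wts.size
    exps = [_exponents(a, r_max) for a in (ax, ay, az)]
    n1 = r_max + 1
    out = np.zeros((n1, n1, n1))
    step = max(1, chunk // Q)
    Rt = np.asarray(R, dtype=float).T
    for lo in range(0, f.size, step):
        hi = min(lo + step, f.size)
        pts = centers[lo:hi, None, :] + offsets[None, :, :]      # (c, Q, 3)
        rot = pts @ Rt                                           # rows R @ v
        nc = hi - lo
        flat = rot.reshape(-1, 3)
        P = [
            np.stack([rpow(flat[:, axis], e) for e in exps[axis]])
            for axis in range(3)
        ]  # each (n1, c*Q)
        base = (f[lo:hi, None] * wts[None, :]).reshape(-1)        # (c*Q,)
        PzT = P[2].T                                              # (c*Q, n1)
        for p in range(n1):
            Bp = base * P[0][p]
            for q in range(n1):
                out[p, q] += (Bp * P[1][q]) @ PzT
        del pts, rot, flat, P
    return out


def mu_pqr(volume, p: int, q: int, r: int, alphas, center: Centroid,
           R: np.ndarray, nodes: int = 4) -> float:
    """Aggregate rotated central fractional moment ``sum f * mu_pqr``."""
    r_max = max(p, q, r)
    return float(mu_sums(volume, r_max, alphas, center, R, nodes=nodes)[p, q, r])


# ---------------------------------------------------------------------------
# normalized invariants


def _lambda_gamma(vol: VoxelGrid, alphas, r_max: int):
    lam = frgm(vol, 0, 0, 0, (1.0, 1.0, 1.0))
    if lam <= 0:
        raise ValueError("degenerate volume: nonpositive total mass")
    ax, ay, az = (FractionalOrder.coerce(a).alpha for a in alphas)
    l = np.arange(r_max + 1)
    gamma = 1.0 + (
        ax * l[:, None, None] + ay * l[None, :, None] + az * l[None, None, :]
    ) / 3.0
    return lam, gamma


def frgmi_tensor(volume, r_max: int, alphas, nodes: int = 4,
                 center: Centroid | None = None,
                 R: np.ndarray | None = None) -> np.ndarray:
    """``FrGMI[p,q,r] = lambda**(-gamma_pqr) * M[p,q,r]`` for orders <= r_max."""
    vol = VoxelGrid.coerce(volume)
    ctr = center if center is not None else centroid(vol)
    rot = R if R is not None else canonical_rotation(vol, ctr)
    M = mu_sums(vol, r_max, alphas, ctr, rot, nodes=nodes)
    lam, gamma = _lambda_gamma(vol, alphas, r_max)
    return lam ** (-gamma) * M


def frgmi(volume, p: int, q: int, r: int, alphas, nodes: int = 4) -> float:
    return float(frgmi_tensor(volume, max(p, q, r), alphas, nodes=nodes)[p, q, r])


def frcmi_tensor(volume, r_max: int, alphas, nodes: int = 4) -> np.ndarray:
    """``FrCMI[n,m,p]`` for all orders <= r_max via monomial recombination."""
    G = frgmi_tensor(volume, r_max, alphas, nodes=nodes)
    return _recombine(G)


def _recombine(G: np.ndarray) -> np.ndarray:
    n1 = G.shape[0]
    B = np.array(
        [row + [0] * (n1 - len(row)) for row in coefficient_table(n1 - 1)],
        dtype=float,
    )
    # contract one axis at a time to avoid cancellation in B triple products
    vals = np.tensordot(B, G, axes=(1, 0))          # (n, s, r)
    vals = np.tensordot(vals, B, axes=([1], [1]))   # (n, r, m)
    vals = np.tensordot(vals, B, axes=([1], [1]))   # (n, m, p)
    d2 = np.array([norm_constant(n) for n in range(n1)])
    return vals / (d2[:, None, None] * d2[None, :, None] * d2[None, None, :])


def frcmi(volume, n: int, m: int, p: int, alphas, nodes: int = 4) -> float:
    return float(frcmi_tensor(volume, max(n, m, p), alphas, nodes=nodes)[n, m, p])


def descriptor(volume, r_max: int, alphas, nodes: int = 4,
               invariant: bool = True) -> InvariantDescriptor:
    """Length ``(r_max+1)**3`` feature vector, lexicographic in (n, m, p).

    ``invariant=True`` (default) gives the RST-invariant FrCMI vector used
    as classifier input; ``invariant=False`` gives raw FrCM moments.
    """
    if r_max < 0:
        raise ValueError("r_max must be nonnegative")
    spec = BasisSpec.make(r_max, alphas)
    if invariant:
        vals = frcmi_tensor(volume, r_max, alphas, nodes=nodes)
    else:
        vals = compute_frcm(volume, spec).values
    return InvariantDescriptor(vals.reshape(-1), spec)
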