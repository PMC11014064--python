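"""Synthetic labeled 3D voxel shapes, rigid transforms, and Gaussian noise.

Stand-in for mesh-derived voxel benchmarks: ten parametric shape families
(sphere, box, ellipsoid, cross, ring, two-lobe composite, L-bracket,
shell, rod bundle, star) rendered on the unit cube, each instance deformed
by a random rotation / scale / in-frame translation and optionally
corrupted by additive Gaussian noise.  Every generator is deterministic
given its seed.

Shapes are sized to sit strictly inside the grid with a >= 10% margin of
the extent, so that the default transform ranges can never push content
out of frame -- invariance measurements then reflect method error, not
framing error.

"Noise density" d follows the additive convention: zero-mean Gaussian with
standard deviation ``d x (intensity dynamic range)``, clipped to
nonnegative intensities.  A salt-style mode (fraction d of voxels replaced
by random extremes) is available behind a flag.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage

from .invariants import NormalizationAngles, rotation_matrix
from .moments import VoxelGrid

__all__ = ["ShapeSpec", "RigidTransform", "NoiseSpec", "Benchmark",
           "SHAPE_KINDS", "make_shape", "make_smooth_volume",
           "apply_transform", "add_noise", "make_benchmark"]

SHAPE_KINDS = (
    "sphere", "box", "ellipsoid", "cross", "ring",
    "two_lobe", "l_bracket", "shell", "rod_bundle", "star",
)

_MARGIN = 0.10
# intensity below this fraction of the peak counts as empty for framing checks
_SUPPORT_THRESH = 1e-3


@dataclass(frozen=True)
class ShapeSpec:
    kind: str
    dims: tuple[int, int, int] = (32, 32, 32)
    size: float = 1.0          # multiplies the family's canonical extents
    intensity: float = 1.0
    smooth: float = 0.8        # Gaussian pre-smoothing in voxels; 0 = binary
    seed: int = 0

    def __post_init__(self) -> None:
        if self.kind not in SHAPE_KINDS:
            raise ValueError(f"unknown shape kind {self.kind!r}; one of {SHAPE_KINDS}")
        if self.size <= 0 or self.intensity <= 0:
            raise ValueError("size and intensity must be positive")


@dataclass(frozen=True)
class RigidTransform:
    """Rotation angles (radians), isotropic scale, translation in voxels."""

    angles: tuple[float, float, float] = (0.0, 0.0, 0.0)
    scale: float = 1.0
    translation: tuple[float, float, float] = (0.0, 0.0, 0.0)

    def __post_init__(self) -> None:
        if self.scale <= 0:
            raise ValueError("scale must be positive")

    @property
    def matrix(self) -> np.ndarray:
        return rotation_matrix(NormalizationAngles(*self.angles))


@dataclass(frozen=True)
class NoiseSpec:
    density: float
    seed: int = 0
    mode: str = "gaussian"     # or "salt"

    def __post_init__(self) -> None:
        if not 0.0 <= self.density <= 0.10:
            raise ValueError("noise density must lie in [0, 0.10]")
        if self.mode not in ("gaussian", "salt"):
            raise ValueError("mode must be 'gaussian' or 'salt'")


def _coord_grids(dims):
    return np.meshgrid(
        *[(np.arange(d) + 0.5) / d for d in dims], indexing="ij", sparse=True
    )


def _mask_for(kind: str, x, y, z, s: float) -> np.ndarray:
    cx = cy = cz = 0.5
    dx, dy, dz = x - cx, y - cy, z - cz
    if kind == "sphere":
        return dx**2 + dy**2 + dz**2 <= (0.25 * s) ** 2
    if kind == "box":
        return (
            (np.abs(dx) <= 0.23 * s)
            & (np.abs(dy) <= 0.16 * s)
            & (np.abs(dz) <= 0.10 * s)
        )
    if kind == "ellipsoid":
        return (dx / (0.29 * s)) ** 2 + (dy / (0.19 * s)) ** 2 + (dz / (0.11 * s)) ** 2 <= 1.0
    if kind == "cross":
        hl, hw = 0.29 * s, 0.065 * s
        rod_x = (np.abs(dx) <= hl) & (np.abs(dy) <= hw) & (np.abs(dz) <= hw)
        rod_y = (np.abs(dy) <= hl) & (np.abs(dx) <= hw) & (np.abs(dz) <= hw)
        rod_z = (np.abs(dz) <= hl) & (np.abs(dx) <= hw) & (np.abs(dy) <= hw)
        return rod_x | rod_y | rod_z
    if kind == "ring":
        rho = np.sqrt(dx**2 + dy**2)
        return (rho - 0.22 * s) ** 2 + dz**2 <= (0.07 * s) ** 2
    if kind == "two_lobe":
        # two unequal ellipsoids: triaxial (well-separated principal
        # moments) and skewed along every principal axis, so its canonical
        # orientation is unambiguous -- the reference shape for invariance
        # measurements
        a = (
            ((dx - 0.12 * s) / (0.16 * s)) ** 2
            + ((dy - 0.03 * s) / (0.115 * s)) ** 2
            + ((dz - 0.01 * s) / (0.085 * s)) ** 2
            <= 1.0
        )
        b = (
            ((dx + 0.14 * s) / (0.105 * s)) ** 2
            + ((dy + 0.06 * s) / (0.085 * s)) ** 2
            + ((dz + 0.04 * s) / (0.065 * s)) ** 2
            <= 1.0
        )
        return a | b
    if kind == "l_bracket":
        arm1 = (np.abs(dx) <= 0.20 * s) & (np.abs(dy + 0.10 * s) <= 0.06 * s) & (np.abs(dz) <= 0.08 * s)
        arm2 = (np.abs(dx + 0.14 * s) <= 0.06 * s) & (np.abs(dy - 0.04 * s) <= 0.18 * s) & (np.abs(dz) <= 0.08 * s)
        return arm1 | arm2
    if kind == "shell":
        r2 = dx**2 + dy**2 + dz**2
        return ((0.18 * s) ** 2 <= r2) & (r2 <= (0.26 * s) ** 2)
    if kind == "rod_bundle":
        r = 0.05 * s
        in_z = np.abs(dz) <= 0.25 * s
        a = (dx - 0.11 * s) ** 2 + (dy - 0.09 * s) ** 2 <= r**2
        b = (dx + 0.12 * s) ** 2 + (dy - 0.02 * s) ** 2 <= r**2
        c = (dx - 0.02 * s) ** 2 + (dy + 0.12 * s) ** 2 <= r**2
        return in_z & (a | b | c)
    if kind == "star":
        return np.abs(dx) + np.abs(dy) + np.abs(dz) <= 0.28 * s
    raise ValueError(kind)


def make_shape(spec: ShapeSpec) -> VoxelGrid:
    """Render a shape; ~5% seeded size jitter gives per-instance variety."""
    rng = np.random.default_rng(spec.seed)
    s = spec.size * (1.0 + 0.05 * (2.0 * rng.random() - 1.0))
    x, y, z = _coord_grids(spec.dims)
    data = _mask_for(spec.kind, x, y, z, s).astype(float) * spec.intensity
    if not data.any():
        raise ValueError(f"shape {spec.kind!r} rendered empty on dims {spec.dims}")
    if spec.smooth > 0:
        data = ndimage.gaussian_filter(data, spec.smooth)
    _check_margin(data, spec.dims)
    return VoxelGrid(data)


def make_smooth_volume(dims=(32, 32, 32), seed: int = 0, smooth: float = 3.0,
                       peak: float = 255.0) -> VoxelGrid:
    """Band-limited random intensity field, rescaled to [0, peak].

    A Gaussian-filtered white-noise field: the reference "smooth volume"
    for reconstruction experiments (8-bit gray scale by default).
    """
    rng = np.random.default_rng(seed)
    f = ndimage.gaussian_filter(rng.random(tuple(int(d) for d in dims)), smooth)
    f = f - f.min()
    mx = f.max()
    if mx > 0:
        f = f / mx * peak
    return VoxelGrid(f)


def _check_margin(data: np.ndarray, dims, frac: float = _MARGIN) -> None:
    sup = np.nonzero(data > _SUPPORT_THRESH * data.max())
    for axis, d in enumerate(dims):
        lo, hi = int(sup[axis].min()), int(sup[axis].max())
        m = int(np.floor(frac * d))
        if lo < m or hi >= d - m:
            raise ValueError(
                f"shape support [{lo}, {hi}] violates the {frac:.0%} margin on axis "
                f"{axis} (dim {d})"
            )


def apply_transform(volume, t: RigidTransform, check_frame: bool = True) -> VoxelGrid:
    """Rotate/scale/translate about the grid center, trilinear resampling.

    Forward map in voxel index space: ``o = s * R (i - c) + c + shift``;
    the inverse map feeds ``scipy.ndimage.affine_transform`` with zero
    fill.  Raises if transformed content reaches the one-voxel border.
    """
    vol = VoxelGrid.coerce(volume)
    c = (np.array(vol.dims) - 1.0) / 2.0
    M = t.matrix.T / t.scale
    offset = c - M @ (c + np.asarray(t.translation, dtype=float))
    out = ndimage.affine_transform(
        vol.data, M, offset=offset, order=1, mode="constant", cval=0.0
    )
    out = np.clip(out, 0.0, None)
    if check_frame:
        peak = max(vol.data.max(), 1e-300)
        border = np.concatenate(
            [
                out[0].ravel(), out[-1].ravel(),
                out[:, 0].ravel(), out[:, -1].ravel(),
                out[:, :, 0].ravel(), out[:, :, -1].ravel(),
            ]
        )
        if border.max() > _SUPPORT_THRESH * peak:
            raise ValueError("transformed content leaves the grid frame")
    return VoxelGrid(out)


def add_noise(volume, noise: NoiseSpec) -> VoxelGrid:
    """Seeded noise injection; identity for density 0."""
    vol = VoxelGrid.coerce(volume)
    if noise.density == 0.0:
        return vol
    rng = np.random.default_rng(noise.seed)
    data = vol.data
    span = float(data.max() - data.min())
    if span == 0.0:
        span = abs(float(data.max())) or 1.0
    if noise.mode == "gaussian":
        out = data + rng.normal(0.0, noise.density * span, size=data.shape)
        out = np.clip(out, 0.0, None)
    else:  # salt: fraction d of voxels replaced by the intensity extremes
        out = data.copy()
        n_bad = int(round(noise.density * data.size))
        flat = rng.choice(data.size, size=n_bad, replace=False)
        out.ravel()[flat] = rng.choice([0.0, float(data.max())], size=n_bad)
    return VoxelGrid(out)


@dataclass
class Benchmark:
    """A stratified, seeded shape-classification dataset."""

    volumes: list[VoxelGrid]
    labels: np.ndarray
    transforms: list[RigidTransform]
    train_idx: np.ndarray
    test_idx: np.ndarray
    class_names: tuple[str, ...]
    noise: float = 0.0
    manifest: list[dict] = field(default_factory=list)


def make_benchmark(
    n_classes: int = 10,
    n_per_class: int = 60,
    dims: tuple[int, int, int] = (32, 32, 32),
    rotation_range: float = np.pi / 6,
    scale_range: tuple[float, float] = (0.8, 1.2),
    translation_frac: float = 0.03,
    noise_density: float = 0.0,
    split: tuple[float, float] = (0.4, 0.6),
    seed: int = 0,
) -> Benchmark:
    """Transformed shape instances with a stratified train/test split.

    Defaults mirror the multi-class voxel benchmark protocol: 10 classes x
    60 instances, rotations within +/-30 deg per axis, scales in
    [0.8, 1.2], in-frame translations, 40%/60% train/test.
    """
    if n_classes > len(SHAPE_KINDS):
        raise ValueError(f"at most {len(SHAPE_KINDS)} shape classes available")
    if abs(sum(split) - 1.0) > 1e-9:
        raise ValueError("split fractions must sum to 1")
    rng = np.random.default_rng(seed)
    volumes: list[VoxelGrid] = []
    labels = []
    transforms: list[RigidTransform] = []
    manifest = []
    for cls in range(n_classes):
        kind = SHAPE_KINDS[cls]
        for inst in range(n_per_class):
            shape_seed = int(rng.integers(0, 2**31 - 1))
            base = make_shape(ShapeSpec(kind, dims=dims, seed=shape_seed))
            # rejection-sample transforms: extreme scale+rotation corners can
            # push smoothing tails of elongated shapes past the border
            for _attempt in range(20):
                t = RigidTransform(
                    angles=tuple(rng.uniform(-rotation_range, rotation_range, size=3)),
                    scale=float(rng.uniform(*scale_range)),
                    translation=tuple(
                        rng.uniform(-translation_frac, translation_frac, size=3)
                        * np.array(dims)
                    ),
                )
                try:
                    v = apply_transform(base, t)
                    break
                except ValueError:
                    continue
            else:
                raise ValueError(
                    f"could not place {kind!r} in frame after 20 attempts"
                )
            if noise_density > 0:
                v = add_noise(v, NoiseSpec(noise_density, seed=int(rng.integers(0, 2**31 - 1))))
            volumes.append(v)
            labels.append(cls)
            transforms.append(t)
            manifest.append(
                {"class": kind, "label": cls, "instance": inst,
                 "scale": t.scale, "angles": list(t.angles),
                 "translation": list(t.translation), "noise": noise_density}
            )
    labels_arr = np.array(labels)
    train_idx, test_idx = [], []
    for cls in range(n_classes):
        members = np.nonzero(labels_arr == cls)[0]
        perm = rng.permutation(members)
        k = int(round(split[0] * members.size))
        train_idx.extend(perm[:k])
        test_idx.extend(perm[k:])
    for row, which in zip(
        manifest, ["train" if i in set(train_idx) else "test" for i in range(len(manifest))]
    ):
        row["split"] = which
    return Benchmark(
        volumes=volumes,
        labels=labels_arr,
        transforms=transforms,
        train_idx=np.array(sorted(train_idx)),
        test_idx=np.array(sorted(test_idx)),
        class_names=SHAPE_KINDS[:n_classes],
        noise=noise_density,
        manifest=manifest,
    )
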