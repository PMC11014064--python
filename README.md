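# frcm3d

Fractional-order Chebyshev moments for 3D voxel images: orthogonal moment
analysis and reconstruction, rotation/scale/translation (RST) invariant
shape descriptors, and a dense-network classifier over those descriptors —
with a synthetic voxel-shape benchmark generator so the whole pipeline is
testable end to end without external datasets.

## Who this is for

Researchers working with volumetric shape data (voxelized meshes, binary
occupancy grids, segmented medical volumes) who need compact, invertible,
transformation-invariant descriptors of 3D content — for retrieval,
recognition, or compression-style analysis — and a reproducible harness to
measure how such descriptors degrade under sensor noise.

## The mathematics in brief

**Basis.** Shifted Chebyshev polynomials of the first kind `T̄_n` on [0, 1]
(three-term recurrence `T̄_0 = 1`, `T̄_1 = 2t−1`,
`T̄_{n+1} = (4t−2)T̄_n − T̄_{n−1}`) are made *fractional* by the substitution
`t = x^α` (α > 0). Folding the transformed orthogonality weight

    w_α(x) = α x^{α−1} / √(x^α (1 − x^α))

into the function gives a family `FT_n^α(x) = √(w_α(x)/d_n²) · T̄_n(x^α)`
(`d_0² = π`, `d_n² = π/2`) that is orthonormal on (0, 1) under plain
integration. α tunes the spatial emphasis of every moment order.

**Moments and reconstruction.** A volume `f` on an `N×M×K` grid mapped to
the unit cube via cell centers `x_i = (i+0.5)/N` has moments

    FrCM_nmp = Σ_{ijk} f[i,j,k] · φ_n(x-cell i) · φ_m(y-cell j) · φ_p(z-cell k)

evaluated separably; `φ` integrates the polynomial factor exactly over each
cell and samples the (singular) weight at the cell center. The truncated
expansion `f ≈ Σ FrCM_nmp FT_n FT_m FT_p` reconstructs the volume, with
PSNR rising monotonically in the maximum order.

**Invariants.** Fractional geometric moments with exact per-cell integrals
give the intensity centroid (translation), the second-moment tensor and a
canonical principal-axes rotation (rotation), and a normalization
`λ^{−γ}` with `λ = FrGM_000`, `γ = 1 + (α_x p + α_y q + α_z r)/3` (scale).
Rotated central fractional moments are integrated by per-cell
Gauss–Legendre quadrature; for rational α = a/b with *odd* b, signed powers
use the exact real root `v^{a/b} = sign(v)^a |v|^{a/b}`. Recombining
through the integer Chebyshev coefficients `B[n,l]` yields the invariant
descriptors `FrCMI_nmp`; at maximum order 19 the descriptor has
20³ = 8000 components.

**Classifier.** A fully connected network (hidden widths 100/165/245/120,
batch norm, ELU then ReLU activations, dropout, softmax output) trained
with Adam on cross-entropy, implemented directly on numpy arrays and
bit-reproducible from a single seed.

## Worked example

```python
import numpy as np
from frcm3d import (BasisSpec, compute_frcm, reconstruct, psnr,
                    make_shape, apply_transform, ShapeSpec, RigidTransform)
from frcm3d.invariants import frcmi_tensor
from frcm3d.synthetic import make_smooth_volume

# --- reconstruction quality grows with moment order ---
vol = make_smooth_volume((32, 32, 32), seed=0)          # 8-bit scale field
for order in (4, 8, 16, 24):
    rec = reconstruct(compute_frcm(vol, BasisSpec.make(order, (1.2, 1.0, 1.2))),
                      vol.dims)
    print(order, round(psnr(vol, rec), 2))
# 4 21.27
# 8 25.86
# 16 32.41
# 24 34.24          <- dB; higher is better, rising with order

# --- descriptors are stable under rotation + scale + translation ---
shape = make_shape(ShapeSpec("two_lobe", dims=(64, 64, 64), seed=3))
d0 = frcmi_tensor(shape, 3, (1.4, 1.4, 1.4)).reshape(-1)
moved = apply_transform(shape, RigidTransform(angles=(0.5, -0.4, 0.3), scale=0.9))
d1 = frcmi_tensor(moved, 3, (1.4, 1.4, 1.4)).reshape(-1)
print(np.median(np.abs(d1 - d0) / np.abs(d0)))          # ~0.01 (1% shift)
```

The PSNR numbers say the order-24 expansion reconstructs the random smooth
volume to ~34 dB (a per-voxel error of about 5 gray levels out of 255);
the final line says a rotated, shrunk copy of an asymmetric shape keeps
the median component of its 64-value invariant descriptor within ~1%.

A command-line interface covers the same workflows
(`frcm simulate | moments | reconstruct | invariants | train | evaluate`);
`frcm evaluate` reproduces the accuracy-versus-noise table on the
synthetic benchmark.

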