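# Methods

This note documents the models, numerical choices and protocols behind
`frcm3d`, including the places where the design was genuinely open and
what the synthetic benchmark does and does not establish.

## Fractional Chebyshev basis

The basis is constructed by substituting `t = x^α` into shifted Chebyshev
polynomials of the first kind on [0, 1] and folding the pulled-back
orthogonality weight into the function:

    FT_n^α(x) = sqrt(w_α(x) / d_n²) · T̄_n(x^α),
    w_α(x)    = α x^{α−1} / sqrt(x^α (1 − x^α)),
    d_0² = π,  d_n² = π/2 (n ≥ 1).

Under `u = x^α` every inner product reduces to the classical
Chebyshev-weighted integral, so the family is orthonormal on (0, 1) for
any α > 0 and `d_n²` does not depend on α. Polynomials are always
evaluated by the three-term recurrence; the trigonometric closed form
`cos(n arccos(2t−1))` serves only as a test oracle. Monomial coefficients
`B[n, l]` (with `T̄_n(t) = Σ_l B[n,l] t^l`) are built by the same
recurrence acting on exact integer coefficient arrays — no factorials, no
overflow at any order used here.

α is carried with an exact rational form `a/b`. Invariant computations
require odd `b`: the real b-th root of a negative number then exists and
equals `sign(v)^a |v|^{a/b}`. This parity-aware signed power reduces to
the ordinary power at integer exponents (so α = 1 recovers classical
moments exactly) and makes the closed-form antiderivative
`rpow(v, e+1)/(e+1)` of the signed-power integrand exact. A blanket
`sign(v)|v|^e` convention would corrupt even integer exponents and was
rejected.

## Moment evaluation scheme

Voxel volumes live on the open unit cube via cell centers
`x_i = (i+0.5)/N`; the weight singularities at 0 and 1 are never sampled.
Two evaluation details matter:

* **Per-cell integration of the polynomial factor.** Sampling
  `T̄_n(x^α)` at cell centers aliases once the degree approaches the grid
  size (on 32³ grids the reconstruction PSNR *fell* between orders 16 and
  24). Each axis factor therefore integrates `T̄_n(x^α)` exactly over the
  cell (Gauss–Legendre in x, where the integrand is smooth; the first
  cell is power-substituted when α < 1) while the singular weight factor
  multiplies the image at the cell center — a weighted-image formulation.
  Synthesis (reconstruction) applies the same functionals, so the
  round-trip operator is symmetric and PSNR rises monotonically with
  order (measured 21 → 26 → 32 → 34 dB over orders 4/8/16/24 on smooth
  32³ fields).
* **Two routes, one algebra.** The geometric-moment route expands each
  `T̄` into monomials and uses closed-form per-cell integrals of
  `x^{αl}`. Recombining a fully contracted geometric-moment tensor
  through `B[n,l]B[m,s]B[p,r]` amplifies rounding by the monomial-basis
  condition number (~4^n per axis; 2×10⁻² relative at order 8), so the
  recombination is folded into each axis *before* the volume contraction
  — a pure reassociation of the same triple sum. The routes then agree to
  ~2×10⁻⁸ at order 8; beyond order ~20 the geometric route still loses
  about one digit per two degrees and the direct route should be used.

A stability cap (default order 60) guards the analysis on coarse grids.

Known accuracy limit: moments of volumes that themselves carry the basis'
edge singularity (e.g. a sampled basis-product field) converge only as
O(√h) at the boundary — about 8% per axis at N = 64. This is a property
of any cell-sampled discretization of the singular weight, not of this
implementation; moments of bounded images do not suffer from it.

## RST invariants

Pipeline per volume: (1) fractional geometric moments with exact per-cell
monomial integrals; (2) intensity centroid from the classical (α = 1)
first-order moments — the fractional first-moment ratio is not
translation-equivariant and would break the invariance it is meant to
provide; (3) classical second-order central moments → canonical
principal-axes rotation; (4) rotated central fractional moments by
per-cell tensor-product Gauss–Legendre quadrature (default 4³ nodes; the
rotated integrand is non-separable); (5) scale normalization
`λ^{−γ}`, `γ = 1 + (α_x p + α_y q + α_z r)/3`, which cancels the
`s^{3+Σαe}` scaling of the moments exactly; (6) recombination through
`B[n,l]` with the literal `1/(d_n² d_m² d_p²)` prefactor into `FrCMI`.

**Orientation normalization.** The one-shot half-arctangent angle
formulas (exposed as `normalization_angles`) do not diagonalize a general
second-moment tensor — their denominators couple the three planes — and
iterating them diverges. The canonical frame is therefore the exact
eigendecomposition of the second-moment tensor, rows ordered by
descending principal moment, each axis sign chosen so the third-order
moment (skewness) along it is nonnegative, and det +1 restored by
flipping the weakest-skew axis. Measured effect on an asymmetric 64³
shape under 12 random rotations (±30° per axis), scales in [0.8, 1.2] and
integer translations: per-component relative SD of the order-≤4
descriptor fell from ~50% (one-shot angles) to ~2% (canonical frame).

Limits of the normalization: shapes with (near-)degenerate principal
moments (spheres, crosses, near-axisymmetric bodies) have no recoverable
canonical orientation — their descriptors are only as rotation-stable as
their symmetry allows; and under arbitrary SO(3) rotations well beyond
±45° the eigenvalue-ordering convention can relabel axes. The benchmark
generator's default ±30° rotation range reflects that regime of validity.

**Quadrature.** 4³ Gauss–Legendre nodes per cell integrate the rotated
signed-power integrand to ~10⁻⁸ relative on positive-integrand (even)
orders at 8³, limited near the centroid by the |v|^e kink; odd orders
cancel across cells and should be judged on the tensor scale, not
component-relative. Doubling the nodes changes results at 16³ by < 10⁻⁸.

## Classifier

Four fully connected hidden blocks (widths 100/165/245/120, each
linear → batch norm → activation → dropout; ELU in the first block, ReLU
after; softmax output), categorical cross-entropy, Adam at 10⁻³, minibatch
32, dropout 0.3. Implemented directly in numpy (forward, backward,
batch-norm running statistics, optimizer); initialization, shuffling and
dropout all derive from one integer seed, so train + predict is
bit-reproducible. The hidden widths follow the published architecture
table; where its accompanying text says 240 for the third layer, the
table's 245 is used. Dropout rate, optimizer and loss were unspecified
upstream and are package choices.

## Synthetic benchmark

Ten parametric shape families (sphere, box, ellipsoid, cross, ring,
two-lobe composite, L-bracket, shell, rod bundle, star) rendered on the
unit cube with ±5% seeded size jitter, light Gaussian pre-smoothing
(σ = 0.8 voxels), and a ≥10% margin so transforms never clip content
(framing uses a 0.1%-of-peak support threshold; transforms are
rejection-sampled in the rare corner cases). Instances are deformed by
rotations within ±30° per axis, isotropic scales in [0.8, 1.2] and
in-frame translations, then optionally corrupted by additive zero-mean
Gaussian noise with σ = density × dynamic range, clipped to nonnegative
intensities (a salt-style "fraction of corrupted voxels" mode exists
behind a flag). The two-lobe composite is deliberately triaxial — eigen
gaps ~70% and ~580%, nonzero skewness on every axis — so its canonical
orientation is unambiguous; it is the reference shape for invariance
measurements.

What this emulates: multi-class voxelized shape recognition under rigid
transforms and sensor noise, with exactly stratified, seeded splits
(40%/60% by default; 50%/50% supported). What it does not: mesh
voxelization artifacts, partial volumes/occlusion, anisotropic voxels,
intra-class structural variation beyond size jitter, or realistic imaging
physics. Passing results bound method error under controlled conditions;
they do not predict absolute accuracy on real scan data.

## Benchmark classification protocol

Defaults in `frcm3d.pipeline` (all overridable):

* 10 classes × 60 instances on 32³ grids, 240/360 train/test;
* fractional orders (0.8, 0.8, 0.8) and descriptor order r_max = 3
  (64 invariants). Higher presets (e.g. α = 1.4 at order 4, exponents up
  to 5.6) weight the far field of the cube several hundred times more
  strongly than central shape content, so background noise overwhelms the
  descriptor at the first noise level and the accuracy ladder collapses
  to a flat floor; the lower preset keeps the ladder informative;
* descriptor features pass through `sign(x)·log(1+|x|)` and are z-scored
  with training statistics (invariant magnitudes span many decades);
* the training split is augmented with one lightly noisy copy per volume
  (density 0.5%). Without it the classifier falls to near-chance at 1%
  noise and the per-level accuracies tie at the floor; with augmentation
  over *all* densities the curve flattens and wiggles. One light level
  yields a high noiseless accuracy and a strictly decreasing ladder
  (measured at seed 1: 99.7 / 96.1 / 75.8 / 43.6 / 21.4 / 14.4% over
  densities 0–5%);
* 2³ quadrature nodes per cell in this pipeline (descriptor quality for
  classification is insensitive to the extra accuracy of the 4³ default,
  and the full 600-volume protocol then runs in minutes on one CPU);
* training: 300 epochs at the classifier defaults above.

Noise is injected into test volumes (not descriptors) with per-volume
seeds; descriptors are recomputed per level.

## Degenerate inputs and conventions

Zero-mass volumes are rejected wherever a centroid or normalization is
required; isotropic second-moment tensors give zero normalization angles;
precision/recall with empty denominators are defined as 0 with a warning;
PSNR of identical volumes is reported as infinity. Descriptor ordering is
lexicographic in (n, m, p); moment containers serialize with their α
rationals so round trips preserve the exact orders. Problem sizes used in
tests and the acceptance script (8³–64³ grids, orders ≤ 24, 600-instance
benchmark) are the package's reference configurations; every procedure
accepts larger settings unchanged.
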