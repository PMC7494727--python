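"""Synthetic micro-CT phantoms of embedded rice grains with ground truth.

A scan of milled rice pressed into a low-density clay support shows four
intensity classes, ordered by material density: air background, clay
support, chalky endosperm (air-pocketed, hence less dense) and normal
endosperm. The phantom rasterizes ellipsoidal grains with optional
interior chalky inclusions into such a class-level image, then applies
Gaussian blur (partial-volume effect of the finite focal spot) and
additive Gaussian noise. The pre-blur rasterization is kept as ground
truth, so every downstream estimate can be scored against exact voxel
counts.

Voxel membership is decided by voxel-center inclusion, which makes
brute-force enumeration an exact oracle for every rasterized shape.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Literal, Sequence

import numpy as np
from scipy import ndimage

from .volume_io import BinaryMask, LabelMap, VoxelVolume, _validate_spacing

__all__ = [
    "ChalkSpec",
    "GrainSpec",
    "PhantomSpec",
    "PhantomTruth",
    "rasterize_ellipsoid",
    "generate_blob_chalk",
    "generate_phantom",
    "multigrain_spec",
]


@dataclass(frozen=True)
class ChalkSpec:
    """Chalky inclusion inside one grain.

    ``kind="none"`` — sound grain; ``"centered_ball"`` — sphere of
    ``radius_mm`` at the grain center (idealized white-core);
    ``"blob"`` — amorphous connected region occupying
    ``target_fraction`` of the grain volume, shaped by thresholded
    smoothed noise (``smoothness_mm`` sets the correlation length).
    """

    kind: Literal["none", "centered_ball", "blob"] = "none"
    radius_mm: float = 0.0
    target_fraction: float = 0.0
    smoothness_mm: float = 0.05
    seed: int = 0


@dataclass(frozen=True)
class GrainSpec:
    """One ellipsoidal grain: center and semi-axes in mm, ZYX intrinsic
    rotation angles in degrees (applied about slice, row, column axes)."""

    center_mm: tuple[float, float, float]
    semi_axes_mm: tuple[float, float, float]
    rotation_deg: tuple[float, float, float] = (0.0, 0.0, 0.0)
    chalk: ChalkSpec = field(default_factory=ChalkSpec)


@dataclass(frozen=True)
class PhantomSpec:
    """Full phantom description.

    Intensity levels default to an 8-bit-like scale with the strict
    density ordering the segmentation exploits:
    ``mu_air < mu_clay < mu_chalk < mu_endosperm`` (0 < 40 < 110 < 200).
    ``clay_box_mm`` is an axis-aligned box ``((lo_z, lo_y, lo_x),
    (hi_z, hi_y, hi_x))`` filled with clay except where grains sit;
    ``None`` means no support material.
    """

    grid_shape: tuple[int, int, int]
    spacing_mm: tuple[float, float, float] = (0.005, 0.005, 0.005)
    grains: tuple[GrainSpec, ...] = ()
    mu_air: float = 0.0
    mu_clay: float = 40.0
    mu_chalk: float = 110.0
    mu_endosperm: float = 200.0
    clay_box_mm: tuple[tuple[float, float, float], tuple[float, float, float]] | None = None
    blur_sigma_mm: float = 0.0
    noise_sd: float = 0.0
    rng_seed: int = 0
    min_clearance_voxels: int = 2

    def __post_init__(self) -> None:
        _validate_spacing(self.spacing_mm)
        if not (self.mu_air < self.mu_clay < self.mu_chalk < self.mu_endosperm):
            raise ValueError(
                "intensity ordering mu_air < mu_clay < mu_chalk < mu_endosperm "
                f"violated: {self.mu_air}, {self.mu_clay}, {self.mu_chalk}, "
                f"{self.mu_endosperm}"
            )
        if self.blur_sigma_mm < 0 or self.noise_sd < 0:
            raise ValueError("blur_sigma_mm and noise_sd must be >= 0")


@dataclass
class PhantomTruth:
    """Pre-blur, pre-noise ground truth for a generated phantom."""

    grain_labels: LabelMap
    chalk_mask: BinaryMask
    clay_mask: BinaryMask
    grain_volumes_mm3: dict[int, float]
    chalk_volumes_mm3: dict[int, float]


def _rotation_matrix(rotation_deg: Sequence[float]) -> np.ndarray:
    """Composite rotation about the (slice, row, column) axes, applied
    in that order to grid offsets."""
    a, b, c = np.deg2rad(rotation_deg)
    rz = np.array(
        [[1, 0, 0], [0, np.cos(a), -np.sin(a)], [0, np.sin(a), np.cos(a)]]
    )
    ry = np.array(
        [[np.cos(b), 0, np.sin(b)], [0, 1, 0], [-np.sin(b), 0, np.cos(b)]]
    )
    rx = np.array(
        [[np.cos(c), -np.sin(c), 0], [np.sin(c), np.cos(c), 0], [0, 0, 1]]
    )
    return rx @ ry @ rz


def rasterize_ellipsoid(
    center_mm: Sequence[float],
    semi_axes_mm: Sequence[float],
    rotation_deg: Sequence[float],
    grid_shape: Sequence[int],
    spacing_mm: Sequence[float],
) -> BinaryMask:
    """Rasterize a rotated ellipsoid: a voxel is included iff its center
    satisfies the ellipsoid inequality in the body frame."""
    semi = np.asarray(semi_axes_mm, dtype=float)
    if np.any(semi <= 0):
        raise ValueError(f"semi-axes must be > 0, got {tuple(semi)}")
    spacing = np.asarray(_validate_spacing(spacing_mm))
    center = np.asarray(center_mm, dtype=float)
    rot = _rotation_matrix(rotation_deg)

    # Evaluate only within the bounding box of the rotated ellipsoid.
    half_extent = np.sqrt((rot * semi) ** 2 @ np.ones(3))
    lo = np.maximum(np.floor((center - half_extent) / spacing).astype(int) - 1, 0)
    hi = np.minimum(
        np.ceil((center + half_extent) / spacing).astype(int) + 2,
        np.asarray(grid_shape, dtype=int),
    )
    mask = np.zeros(tuple(grid_shape), dtype=bool)
    if np.any(lo >= hi):
        return BinaryMask(mask, tuple(spacing))

    axes = [ (np.arange(lo[i], hi[i]) + 0.5) * spacing[i] - center[i] for i in range(3) ]
    zz, yy, xx = np.meshgrid(*axes, indexing="ij", sparse=False)
    pts = np.stack([zz, yy, xx], axis=-1)
    body = pts @ rot  # rot^T applied to each offset (world -> body frame)
    inside = np.sum((body / semi) ** 2, axis=-1) <= 1.0
    mask[lo[0] : hi[0], lo[1] : hi[1], lo[2] : hi[2]] = inside
    return BinaryMask(mask, tuple(spacing))


def generate_blob_chalk(
    grain_mask: BinaryMask,
    target_fraction: float,
    smoothness_mm: float,
    seed: int,
) -> BinaryMask:
    """Carve an amorphous chalky inclusion out of a grain interior.

    Smoothed seeded Gaussian noise is thresholded at the quantile
    matching ``target_fraction`` of the grain voxel count, restricted to
    the grain eroded by one voxel, and the largest connected component
    kept. The quantile is re-tuned (bisected) up to 20 times until the
    component size is within ±10% of the target. Because the
    largest-component size jumps discontinuously when raising the
    threshold splits off a branch, the window can fall inside a jump;
    in that case the smallest overshooting component is trimmed to the
    target by peeling voxels in ascending field order (equivalently,
    growing from the component maximum in descending order), which is
    connected by construction. Raises only when even the full eroded
    interior cannot reach the target.
    """
    if not (0.0 < target_fraction < 1.0):
        raise ValueError(f"target_fraction must be in (0, 1), got {target_fraction}")
    grain = grain_mask.data
    n_grain = int(grain.sum())
    if n_grain == 0:
        raise ValueError("empty grain mask")
    interior = ndimage.binary_erosion(grain, ndimage.generate_binary_structure(3, 1))
    n_interior = int(interior.sum())
    if n_interior == 0:
        raise ValueError("grain has no interior after 1-voxel erosion")

    rng = np.random.default_rng(seed)
    sigma_vox = np.asarray(smoothness_mm) / np.asarray(grain_mask.spacing)
    noise = rng.standard_normal(grain.shape)
    smooth = ndimage.gaussian_filter(noise, sigma=sigma_vox)
    vals = smooth[interior]

    target_count = target_fraction * n_grain
    structure = ndimage.generate_binary_structure(3, 3)

    def _fill_enclosed(m: np.ndarray) -> np.ndarray:
        return ndimage.binary_fill_holes(m)

    def largest_component(q: float) -> tuple[np.ndarray | None, int]:
        cut = np.quantile(vals, q)
        cand = interior & (smooth >= cut)
        lab, n = ndimage.label(cand, structure=structure)
        if n == 0:
            return None, 0
        sizes = np.bincount(lab.ravel())[1:]
        best = int(np.argmax(sizes)) + 1
        blob = lab == best
        # solidify: enclosed cavities of the thresholded field are not
        # physical; keeping the blob cavity-free also keeps downstream
        # hole filling exactness-preserving
        blob = _fill_enclosed(blob)
        return blob, int(blob.sum())

    # The largest-component size is monotone non-increasing in the
    # quantile, so bisect; first guess is the quantile matching the
    # target count directly.
    q_lo, q_hi = 0.0, 1.0 - 1.0 / n_interior
    q = 1.0 - min(target_count / n_interior, 1.0)
    best_overshoot: np.ndarray | None = None
    best_size = np.inf
    for _ in range(20):
        blob, achieved = largest_component(q)
        if blob is not None and abs(achieved - target_count) <= 0.1 * target_count:
            return BinaryMask(blob, grain_mask.spacing)
        if achieved > target_count:
            if achieved < best_size:
                best_overshoot, best_size = blob, achieved
            q_lo = q
        else:
            q_hi = q
        q = 0.5 * (q_lo + q_hi)
    if best_overshoot is None:
        raise ValueError(
            f"target fraction unattainable: wanted {target_count:.0f} voxels, "
            f"eroded grain interior has only {n_interior}"
        )
    trimmed = _fill_enclosed(
        _grow_to_count(best_overshoot, smooth, int(round(target_count)))
    )
    return BinaryMask(trimmed, grain_mask.spacing)


def _grow_to_count(component: np.ndarray, field: np.ndarray, count: int) -> np.ndarray:
    """Connected subset of ``component`` with exactly ``count`` voxels:
    priority region growing from the field maximum, always absorbing the
    highest-field 26-neighbor next."""
    import heapq

    coords = np.argwhere(component)
    start = coords[np.argmax(field[tuple(coords.T)])]
    shape = component.shape
    out = np.zeros(shape, dtype=bool)
    in_heap = np.zeros(shape, dtype=bool)
    heap = [(-field[tuple(start)], tuple(start))]
    in_heap[tuple(start)] = True
    n_added = 0
    offsets = [(dz, dy, dx)
               for dz in (-1, 0, 1) for dy in (-1, 0, 1) for dx in (-1, 0, 1)
               if (dz, dy, dx) != (0, 0, 0)]
    while heap and n_added < count:
        _, (z, y, x) = heapq.heappop(heap)
        out[z, y, x] = True
        n_added += 1
        for dz, dy, dx in offsets:
            nz, ny, nx = z + dz, y + dy, x + dx
            if (0 <= nz < shape[0] and 0 <= ny < shape[1] and 0 <= nx < shape[2]
                    and component[nz, ny, nx] and not in_heap[nz, ny, nx]):
                in_heap[nz, ny, nx] = True
                heapq.heappush(heap, (-field[nz, ny, nx], (nz, ny, nx)))
    return out


def _chalk_for_grain(
    grain: GrainSpec, mask: BinaryMask, spacing: tuple[float, float, float],
    grid_shape: tuple[int, int, int],
) -> BinaryMask:
    spec = grain.chalk
    if spec.kind == "none":
        return BinaryMask(np.zeros(grid_shape, dtype=bool), spacing)
    if spec.kind == "centered_ball":
        if spec.radius_mm >= min(grain.semi_axes_mm):
            raise ValueError(
                f"chalk outside grain: ball radius {spec.radius_mm} mm >= "
                f"smallest semi-axis {min(grain.semi_axes_mm)} mm"
            )
        ball = rasterize_ellipsoid(
            grain.center_mm, (spec.radius_mm,) * 3, (0, 0, 0), grid_shape, spacing
        )
        if np.any(ball.data & ~mask.data):
            raise ValueError("chalk outside grain: rasterized ball leaves the grain")
        return ball
    if spec.kind == "blob":
        return generate_blob_chalk(
            mask, spec.target_fraction, spec.smoothness_mm, spec.seed
        )
    raise ValueError(f"unknown chalk kind {spec.kind!r}")


def generate_phantom(spec: PhantomSpec) -> tuple[VoxelVolume, PhantomTruth]:
    """Generate a synthetic CT volume and its ground truth.

    The class-level image (air / clay / chalk / endosperm) is blurred by
    ``blur_sigma_mm`` (converted to voxels per axis) and i.i.d. Gaussian
    noise of standard deviation ``noise_sd`` is added; the returned
    truth masks and per-grain volumes are computed from the *pre-blur*
    rasterization by exact voxel counting. Deterministic for a fixed
    ``rng_seed``.
    """
    shape = tuple(int(s) for s in spec.grid_shape)
    spacing = _validate_spacing(spec.spacing_mm)
    voxel_mm3 = float(np.prod(spacing))

    labels = np.zeros(shape, dtype=np.int32)
    chalk = np.zeros(shape, dtype=bool)
    grain_volumes: dict[int, float] = {}
    chalk_volumes: dict[int, float] = {}

    structure = ndimage.generate_binary_structure(3, 3)
    clearance = max(int(spec.min_clearance_voxels), 0)
    grid_extent_mm = np.asarray(shape) * np.asarray(spacing)
    for gid, grain in enumerate(spec.grains, start=1):
        rot = _rotation_matrix(grain.rotation_deg)
        half = np.sqrt((rot * np.asarray(grain.semi_axes_mm)) ** 2 @ np.ones(3))
        center = np.asarray(grain.center_mm)
        if np.any(center - half < 0) or np.any(center + half > grid_extent_mm):
            raise ValueError(
                f"grain {gid} extends outside the grid "
                f"(center {tuple(center)} mm, half-extent {tuple(half)} mm, "
                f"grid {tuple(grid_extent_mm)} mm)"
            )
        mask = rasterize_ellipsoid(
            grain.center_mm, grain.semi_axes_mm, grain.rotation_deg, shape, spacing
        )
        occupied = labels > 0
        if clearance and occupied.any():
            occupied = ndimage.binary_dilation(
                occupied, structure, iterations=clearance
            )
        if np.any(mask.data & occupied):
            raise ValueError(
                f"grain overlap: grain {gid} is within {clearance} voxels of "
                "a previously placed grain"
            )
        labels[mask.data] = gid
        grain_volumes[gid] = int(mask.data.sum()) * voxel_mm3
        cmask = _chalk_for_grain(grain, mask, spacing, shape)
        chalk |= cmask.data
        chalk_volumes[gid] = int(cmask.data.sum()) * voxel_mm3

    clay = np.zeros(shape, dtype=bool)
    if spec.clay_box_mm is not None:
        lo_mm, hi_mm = (np.asarray(v, dtype=float) for v in spec.clay_box_mm)
        centers = [(np.arange(shape[i]) + 0.5) * spacing[i] for i in range(3)]
        in_box = [
            (centers[i] >= lo_mm[i]) & (centers[i] <= hi_mm[i]) for i in range(3)
        ]
        clay = (
            in_box[0][:, None, None]
            & in_box[1][None, :, None]
            & in_box[2][None, None, :]
        )
        clay &= labels == 0

    image = np.full(shape, spec.mu_air, dtype=np.float64)
    image[clay] = spec.mu_clay
    image[labels > 0] = spec.mu_endosperm
    image[chalk] = spec.mu_chalk

    if spec.blur_sigma_mm > 0:
        sigma_vox = spec.blur_sigma_mm / np.asarray(spacing)
        image = ndimage.gaussian_filter(image, sigma=sigma_vox)
    if spec.noise_sd > 0:
        rng = np.random.default_rng(spec.rng_seed)
        image = image + rng.normal(0.0, spec.noise_sd, size=shape)

    volume = VoxelVolume(image, spacing)
    truth = PhantomTruth(
        grain_labels=LabelMap(labels, spacing),
        chalk_mask=BinaryMask(chalk, spacing),
        clay_mask=BinaryMask(clay, spacing),
        grain_volumes_mm3=grain_volumes,
        chalk_volumes_mm3=chalk_volumes,
    )
    return volume, truth


def multigrain_spec(
    n_grains: int = 10,
    n_chalky: int = 4,
    *,
    spacing_mm: float = 0.01,
    semi_axes_mm: tuple[float, float, float] = (0.5, 0.22, 0.20),
    chalk_fraction: float = 0.15,
    chalk_kind: Literal["centered_ball", "blob"] = "blob",
    blur_sigma_mm: float = 0.0,
    noise_sd: float = 0.0,
    clay: bool = True,
    rng_seed: int = 0,
) -> PhantomSpec:
    """Build a multi-grain embedded-in-clay phantom specification.

    Grains are laid out on a 2D raster inside a clay block, long axis
    in-plane, emulating a high-throughput scan of milled rice pressed
    into a support. The first ``n_chalky`` grains carry an interior
    chalky inclusion of ``chalk_fraction`` of the grain volume (for
    ``centered_ball`` the radius matching that volume fraction).

    The default grain is a miniature with the ~2.3 length/width aspect
    ratio of indica rice, keeping the minor diameter at 40 voxels for
    the default 10 µm spacing so that desk-scale runs stay fast; all
    geometry is overridable. The default chalk fraction (15% of the
    grain volume) keeps every planted inclusion above the 0.01 mm^3
    chalky-grain cutoff at this miniature grain size.
    """
    if not (0 <= n_chalky <= n_grains):
        raise ValueError("need 0 <= n_chalky <= n_grains")
    a, b, c = semi_axes_mm
    sp = float(spacing_mm)
    margin = 8 * sp  # clearance between grains and to the clay-box wall
    n_cols = max(1, int(np.ceil(np.sqrt(n_grains / 2))))
    n_rows = int(np.ceil(n_grains / n_cols))
    pitch_x = 2 * a + margin
    pitch_y = 2 * b + margin
    depth = 2 * c + 2 * margin

    grains = []
    rng = np.random.default_rng(rng_seed)
    for i in range(n_grains):
        r, q = divmod(i, n_cols)
        center = (
            depth / 2,
            margin + b + r * pitch_y + b,  # extra b of slack from the wall
            margin + a + q * pitch_x + a,
        )
        if i < n_chalky:
            if chalk_kind == "centered_ball":
                radius = (chalk_fraction * a * b * c) ** (1.0 / 3.0)
                chalk_spec = ChalkSpec(kind="centered_ball", radius_mm=radius)
            else:
                chalk_spec = ChalkSpec(
                    kind="blob",
                    target_fraction=chalk_fraction,
                    smoothness_mm=6 * sp,
                    seed=int(rng.integers(0, 2**31 - 1)),
                )
        else:
            chalk_spec = ChalkSpec()
        # long axis in-plane along columns, minor axis along the scan axis
        grains.append(
            GrainSpec(center_mm=center, semi_axes_mm=(c, b, a), chalk=chalk_spec)
        )

    extent_y = margin + n_rows * pitch_y + 2 * b + margin
    extent_x = margin + n_cols * pitch_x + 2 * a + margin
    grid = (
        int(np.ceil(depth / sp)),
        int(np.ceil(extent_y / sp)),
        int(np.ceil(extent_x / sp)),
    )
    clay_box = (
        ((sp, sp, sp), (depth - sp, extent_y - sp, extent_x - sp)) if clay else None
    )
    return PhantomSpec(
        grid_shape=grid,
        spacing_mm=(sp, sp, sp),
        grains=tuple(grains),
        clay_box_mm=clay_box,
        blur_sigma_mm=blur_sigma_mm,
        noise_sd=noise_sd,
        rng_seed=rng_seed,
    )
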