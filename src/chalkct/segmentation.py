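"""Mask pipeline for grain and chalk separation.

The workflow mirrors how a CT analyst separates milled rice from its
support and extracts the chalky endosperm, as a sequence of masks:

1. threshold the solid material (grain tissue) out of air and the
   low-density clay support;
2. region-grow / label connected components to isolate grain instances;
3. inside each grain, window the contrast and threshold the *dark*
   band — chalky endosperm is air-pocketed and therefore less dense
   than sound endosperm;
4. clean up morphologically (closing, 3D hole filling) and discard
   components below a minimum size, replacing manual mask editing.

All thresholds can be set explicitly or derived automatically by
multi-level Otsu on the intensity histogram.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Literal, Sequence

import numpy as np
from scipy import ndimage
from skimage.filters import threshold_multiotsu
from skimage.morphology import ball

from .volume_io import BinaryMask, LabelMap, VoxelVolume

__all__ = [
    "SegmentationParams",
    "threshold_band",
    "auto_threshold",
    "apply_contrast_window",
    "region_grow",
    "label_grains",
    "morph_clean",
    "fill_holes_3d",
    "segment_chalk",
    "segment_sample",
]

Band = "tuple[float, float] | Literal['auto']"


@dataclass
class SegmentationParams:
    """Tunable parameters of the mask pipeline.

    solid_threshold
        Closed intensity band ``[lo, hi]`` selecting grain tissue
        (chalky + sound endosperm), or ``"auto"`` for multi-Otsu cuts.
    chalk_band
        Band selecting chalky voxels within the grain, or ``"auto"``:
        a 2-class Otsu cut on grain voxels with the volume minimum as
        the lower end (chalk is everything darker than the cut).
    contrast_window
        Optional ``(center, width)`` linear remap applied before chalk
        thresholding; ``None`` disables it.
    connectivity
        Voxel neighborhood, 6 (faces) or 26 (faces+edges+corners).
        26 is the default: robust to thin diagonal bridges at coarse
        resolution.
    morph_radius_voxels
        Ball radius for morphological closing of the chalk mask;
        0 disables.
    fill_holes
        Convert enclosed background cavities to foreground (3D,
        border-connected definition).
    min_chalk_component_voxels / min_grain_voxels
        Size filters replacing manual mask editing.
    """

    solid_threshold: tuple[float, float] | str = "auto"
    chalk_band: tuple[float, float] | str = "auto"
    contrast_window: tuple[float, float] | None = None
    connectivity: int = 26
    morph_radius_voxels: int = 0
    min_chalk_component_voxels: int = 30
    min_grain_voxels: int = 500
    fill_holes: bool = True

    def __post_init__(self) -> None:
        if self.connectivity not in (6, 26):
            raise ValueError(f"connectivity must be 6 or 26, got {self.connectivity}")
        for band in (self.solid_threshold, self.chalk_band):
            if band != "auto":
                lo, hi = band
                if lo > hi:
                    raise ValueError(f"band lower bound {lo} > upper bound {hi}")
        if self.morph_radius_voxels < 0:
            raise ValueError("morph_radius_voxels must be >= 0")
        if self.min_chalk_component_voxels < 0 or self.min_grain_voxels < 0:
            raise ValueError("minimum component sizes must be >= 0")


def _structure(connectivity: int) -> np.ndarray:
    if connectivity == 6:
        return ndimage.generate_binary_structure(3, 1)
    if connectivity == 26:
        return ndimage.generate_binary_structure(3, 3)
    raise ValueError(f"connectivity must be 6 or 26, got {connectivity}")


def threshold_band(volume: VoxelVolume, lo: float, hi: float) -> BinaryMask:
    """Voxels with ``lo <= intensity <= hi`` (closed band)."""
    if lo > hi:
        raise ValueError(f"band lower bound {lo} > upper bound {hi}")
    return BinaryMask((volume.data >= lo) & (volume.data <= hi), volume.spacing)


def auto_threshold(volume: VoxelVolume | np.ndarray, n_classes: int) -> list[float]:
    """Multi-level Otsu cuts on the intensity histogram.

    Uses 256 bins over the observed intensity range and returns the
    ``n_classes - 1`` cut intensities in ascending order. Each cut is
    placed midway between the nearest observed intensities on either
    side of it, so that for well-separated classes the cut falls
    strictly between adjacent class values rather than on a histogram
    bin center.
    """
    if n_classes not in (2, 3, 4):
        raise ValueError(f"n_classes must be 2, 3 or 4, got {n_classes}")
    data = volume.data if isinstance(volume, VoxelVolume) else np.asarray(volume)
    if data.size == 0 or np.ptp(data) == 0:
        raise ValueError("degenerate histogram: volume has a single intensity value")
    flat = data.ravel().astype(np.float64, copy=False)
    cuts = threshold_multiotsu(flat, classes=n_classes, nbins=256)
    # skimage returns the center of the last bin of each lower class;
    # everything in that bin (up to half a bin above the center) is below
    # the cut
    half_bin = np.ptp(flat) / 256 / 2.0
    snapped = []
    for cut in cuts:
        below = flat[flat <= cut + half_bin]
        above = flat[flat > cut + half_bin]
        if below.size and above.size:
            cut = (below.max() + above.min()) / 2.0
        snapped.append(float(cut))
    return sorted(snapped)


def apply_contrast_window(
    volume: VoxelVolume, center: float, width: float
) -> VoxelVolume:
    """Linear contrast window mapping onto the display range [0, 255].

    Intensities at or below ``center - width/2`` map to 0, at or above
    ``center + width/2`` to 255, linearly in between (so an intensity
    equal to ``center`` maps to 127.5). Output is floating point; no
    quantization is applied.
    """
    if width <= 0:
        raise ValueError(f"window width must be > 0, got {width}")
    lo = center - width / 2.0
    out = np.clip((volume.data.astype(np.float64) - lo) / width, 0.0, 1.0) * 255.0
    return VoxelVolume(out, volume.spacing)


def region_grow(
    mask: BinaryMask, seeds: Sequence[Sequence[int]], connectivity: int = 26
) -> BinaryMask:
    """Grow seed points through a mask: the union of the mask's
    connected components that contain at least one seed."""
    data = mask.data
    for seed in seeds:
        seed = tuple(int(i) for i in seed)
        if len(seed) != 3 or any(
            not (0 <= seed[i] < data.shape[i]) for i in range(3)
        ):
            raise ValueError(f"seed not in mask: {seed} outside grid {data.shape}")
        if not data[seed]:
            raise ValueError(f"seed not in mask: {seed}")
    lab, _ = ndimage.label(data, structure=_structure(connectivity))
    keep = np.unique([lab[tuple(s)] for s in seeds]) if len(seeds) else np.array([], int)
    return BinaryMask(np.isin(lab, keep[keep > 0]), mask.spacing)


def label_grains(
    mask: BinaryMask, connectivity: int = 26, min_grain_voxels: int = 0
) -> LabelMap:
    """Label grain instances as connected components of the mask.

    Components smaller than ``min_grain_voxels`` are discarded;
    survivors are renumbered 1..N by descending voxel count, ties
    broken by the smaller first-voxel flat index in scan order.
    """
    lab, n = ndimage.label(mask.data, structure=_structure(connectivity))
    if n == 0:
        return LabelMap(np.zeros(mask.shape, dtype=np.int32), mask.spacing)
    counts = np.bincount(lab.ravel(), minlength=n + 1)
    first_index = np.full(n + 1, lab.size, dtype=np.int64)
    flat = lab.ravel()
    nz = np.flatnonzero(flat)
    # first occurrence per label in scan order
    first_index[flat[nz[::-1]]] = nz[::-1]
    order = sorted(
        (l for l in range(1, n + 1) if counts[l] >= max(min_grain_voxels, 1)),
        key=lambda l: (-counts[l], first_index[l]),
    )
    remap = np.zeros(n + 1, dtype=np.int32)
    for new, old in enumerate(order, start=1):
        remap[old] = new
    return LabelMap(remap[lab], mask.spacing)


def fill_holes_3d(mask: BinaryMask, background_connectivity: int = 6) -> BinaryMask:
    """Fill enclosed cavities: background components with no voxel on
    the grid border become foreground.

    Background connectivity defaults to 6, the complement of the
    26-connected foreground convention.
    """
    bg = ~mask.data
    lab, n = ndimage.label(bg, structure=_structure(background_connectivity))
    if n == 0:
        return BinaryMask(mask.data.copy(), mask.spacing)
    border_labels = np.unique(
        np.concatenate(
            [
                lab[0].ravel(), lab[-1].ravel(),
                lab[:, 0].ravel(), lab[:, -1].ravel(),
                lab[:, :, 0].ravel(), lab[:, :, -1].ravel(),
            ]
        )
    )
    enclosed = bg & ~np.isin(lab, border_labels)
    return BinaryMask(mask.data | enclosed, mask.spacing)


def morph_clean(
    mask: BinaryMask, radius: int, fill_holes_flag: bool = True
) -> BinaryMask:
    """Morphological closing with a ball element, then 3D hole filling.

    Closing (dilation then erosion) fuses the dotted appearance of a
    thresholded porous region into a solid one; hole filling converts
    fully enclosed background cavities to foreground. ``radius=0`` with
    the flag off is the identity.
    """
    if radius < 0:
        raise ValueError(f"radius must be >= 0, got {radius}")
    out = mask.data
    if radius > 0:
        out = ndimage.binary_closing(
            out, structure=ball(radius), iterations=1, border_value=0
        )
    result = BinaryMask(out, mask.spacing)
    if fill_holes_flag:
        result = fill_holes_3d(result)
    return result


def _auto_chalk_cut(values: np.ndarray) -> float:
    """Otsu cut between the chalk and sound-endosperm classes among
    grain-voxel intensities."""
    if values.size == 0 or np.ptp(values) == 0:
        raise ValueError("degenerate histogram: grain voxels have a single value")
    cuts = threshold_multiotsu(values, classes=2, nbins=256)
    return float(cuts[0])


def segment_chalk(
    volume: VoxelVolume, grain_mask: BinaryMask, params: SegmentationParams
) -> BinaryMask:
    """Extract the chalky region within a grain mask.

    Pipeline: optional contrast window -> chalk-band threshold
    ("auto": everything darker than the Otsu cut between chalk and
    endosperm inside the grain) -> intersect with the grain -> drop
    components below the minimum size -> morphological cleanup. The
    result is a subset of ``grain_mask`` by construction.
    """
    if not grain_mask.data.any():
        raise ValueError("no grain region: grain_mask is empty")
    work = volume
    if params.contrast_window is not None:
        work = apply_contrast_window(work, *params.contrast_window)

    if params.chalk_band == "auto":
        grain_values = work.data[grain_mask.data]
        if np.ptp(grain_values) == 0:
            # uniform grain tissue: nothing darker to separate
            return BinaryMask(np.zeros(volume.shape, dtype=bool), volume.spacing)
        cut = _auto_chalk_cut(grain_values)
        lo, hi = float(work.data.min()), cut
    else:
        lo, hi = params.chalk_band
    chalk = threshold_band(work, lo, hi).data & grain_mask.data

    if params.min_chalk_component_voxels > 0:
        lab, n = ndimage.label(chalk, structure=_structure(params.connectivity))
        if n:
            counts = np.bincount(lab.ravel(), minlength=n + 1)
            keep = counts >= params.min_chalk_component_voxels
            keep[0] = False
            chalk = keep[lab]

    cleaned = morph_clean(
        BinaryMask(chalk, volume.spacing),
        params.morph_radius_voxels,
        params.fill_holes,
    )
    out = cleaned.data & grain_mask.data
    assert not np.any(out & ~grain_mask.data)
    return BinaryMask(out, volume.spacing)


def _auto_solid_band(volume: VoxelVolume) -> tuple[float, float]:
    """Automatic solid-tissue band: a single binary Otsu cut.

    In an embedded-grain scan the background classes (air, clay
    support) vastly outnumber the grain voxels, and the chalky class is
    a tiny fraction of the total, so a single multi-level Otsu pass
    tends to spend cuts subdividing the dominant background instead of
    isolating chalk. A binary cut is robust: it lands above the support
    material, somewhere between clay and sound endosperm. When it lands
    above the chalk level the chalky voxels drop out of the solid mask,
    but chalk is interior to the grain, so the subsequent 3D hole
    filling restores them to the grain region; the chalk band is then
    derived separately from grain voxels only, where chalk is no longer
    a negligible class.
    """
    cuts = auto_threshold(volume, 2)
    return cuts[0], float(volume.data.max())


def segment_sample(
    volume: VoxelVolume, params: SegmentationParams | None = None
) -> tuple[LabelMap, BinaryMask]:
    """Run the full pipeline on a volume: grain labels + chalk mask.

    Thresholds the solid band, labels grain instances (size-filtered),
    then extracts chalk within the union of grains. The chalk mask is
    always a subset of the labeled grain region.
    """
    params = params or SegmentationParams()
    if params.solid_threshold == "auto":
        try:
            lo, hi = _auto_solid_band(volume)
        except ValueError as exc:
            raise ValueError(f"no grains detected: {exc}") from exc
    else:
        lo, hi = params.solid_threshold
    solid = threshold_band(volume, lo, hi)
    # the grain stage always fills holes: interior chalk below the solid
    # cut must still belong to its grain
    solid = morph_clean(solid, params.morph_radius_voxels, fill_holes_flag=True)
    labels = label_grains(solid, params.connectivity, params.min_grain_voxels)
    if labels.n_labels == 0:
        raise ValueError("no grains detected")
    grain_mask = BinaryMask(labels.data > 0, volume.spacing)
    chalk = segment_chalk(volume, grain_mask, params)
    return labels, chalk
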