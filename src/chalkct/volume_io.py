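"""Reading and writing CT volumes, masks and tabular reports.

A reconstructed micro-CT scan is a stack of grayscale cross-section
images. This module turns such stacks (a DICOM series or an ordered list
of TIFF/BMP/PNG/JPEG slices) into a spacing-aware :class:`VoxelVolume`,
writes segmentation results back out as image stacks, and exports
per-grain metric tables as CSV or Excel reports.

Conventions
-----------
* Arrays are indexed ``(slice, row, column)``, 0-based; slice 0 is the
  first file in sorted order.
* ``spacing`` is the physical voxel edge length along each axis in mm.
* Intensity increases with material density (air < clay < chalky
  endosperm < normal endosperm). Scanner exports with the opposite
  polarity can be flipped with ``invert=True`` on the readers.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import imageio.v3 as iio
import numpy as np
import pandas as pd
import tifffile

logger = logging.getLogger(__name__)

#: Report columns, in the exact order written by :func:`write_report`.
REPORT_COLUMNS = [
    "grain_id",
    "VG_mm3",
    "VC_mm3",
    "CD3D_percent",
    "CD2D_percent",
    "length_mm",
    "width_mm",
    "length_width_ratio",
    "is_chalky",
]


def _validate_spacing(spacing: Sequence[float]) -> tuple[float, float, float]:
    spacing = tuple(float(s) for s in spacing)
    if len(spacing) != 3:
        raise ValueError(f"spacing must have 3 components, got {len(spacing)}")
    if any(not np.isfinite(s) or s <= 0 for s in spacing):
        raise ValueError(f"all spacing components must be positive, got {spacing}")
    return spacing


@dataclass
class VoxelVolume:
    """A 3D scalar intensity grid with physical voxel spacing.

    Parameters
    ----------
    data
        3D array of intensities, axes ``(slice, row, column)``. Higher
        values mean denser material.
    spacing
        Voxel edge length (mm) along ``(slice, row, column)``.
    """

    data: np.ndarray
    spacing: tuple[float, float, float]

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data)
        if self.data.ndim != 3 or min(self.data.shape) < 1:
            raise ValueError(
                f"volume data must be 3D with every axis >= 1, got shape {self.data.shape}"
            )
        if not np.all(np.isfinite(self.data)):
            raise ValueError("volume intensities must be finite")
        self.spacing = _validate_spacing(self.spacing)

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.data.shape

    @property
    def voxel_volume_mm3(self) -> float:
        """Physical volume of one voxel in mm^3."""
        return float(np.prod(self.spacing))


@dataclass
class BinaryMask:
    """Boolean voxel occupancy for one tissue class (grain, chalk, clay)."""

    data: np.ndarray
    spacing: tuple[float, float, float]

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data, dtype=bool)
        if self.data.ndim != 3:
            raise ValueError(f"mask data must be 3D, got shape {self.data.shape}")
        self.spacing = _validate_spacing(self.spacing)

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.data.shape

    @property
    def voxel_volume_mm3(self) -> float:
        return float(np.prod(self.spacing))

    def count(self) -> int:
        return int(self.data.sum())


@dataclass
class LabelMap:
    """Integer per-grain instance labels: 0 = background, 1..N = grains.

    Labels are contiguous ``{0} ∪ {1..N}`` with no gaps.
    """

    data: np.ndarray
    spacing: tuple[float, float, float]

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data)
        if self.data.ndim != 3:
            raise ValueError(f"label data must be 3D, got shape {self.data.shape}")
        if not np.issubdtype(self.data.dtype, np.integer):
            raise ValueError("label data must be integer-typed")
        if self.data.size and self.data.min() < 0:
            raise ValueError("labels must be non-negative")
        present = np.unique(self.data)
        positive = present[present > 0]
        if positive.size and not np.array_equal(
            positive, np.arange(1, positive.size + 1)
        ):
            raise ValueError(f"labels must be contiguous 1..N, got {positive}")
        self.spacing = _validate_spacing(self.spacing)

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.data.shape

    @property
    def n_labels(self) -> int:
        return int(self.data.max()) if self.data.size else 0

    @property
    def voxel_volume_mm3(self) -> float:
        return float(np.prod(self.spacing))


# ---------------------------------------------------------------------------
# Readers
# ---------------------------------------------------------------------------


def _dicom_sort_key(ds, path: Path):
    inst = getattr(ds, "InstanceNumber", None)
    if inst is not None:
        return (0, int(inst))
    loc = getattr(ds, "SliceLocation", None)
    if loc is not None:
        return (1, float(loc))
    return (2, str(path.name))


def read_dicom_series(
    directory_path: str | Path,
    *,
    default_spacing: Sequence[float] | None = None,
    invert: bool = False,
) -> VoxelVolume:
    """Read a single-frame grayscale DICOM series into a volume.

    Slices are ordered by InstanceNumber, falling back to SliceLocation
    and then filename. In-plane spacing comes from PixelSpacing and the
    slice step from SpacingBetweenSlices (or SliceThickness); when those
    attributes are absent ``default_spacing`` is used with a warning.

    Parameters
    ----------
    directory_path
        Directory holding one DICOM series.
    default_spacing
        ``(slice, row, column)`` spacing in mm used for any attribute
        missing from the files.
    invert
        Flip intensity polarity (for exports where denser is darker).
    """
    import pydicom

    directory_path = Path(directory_path)
    paths = sorted(p for p in directory_path.iterdir() if p.is_file())
    datasets = []
    for p in paths:
        try:
            ds = pydicom.dcmread(p)
            _ = ds.pixel_array  # force decode; skips non-image files
        except Exception:
            continue
        datasets.append((ds, p))
    if not datasets:
        raise ValueError(f"no readable slices in {directory_path}")

    datasets.sort(key=lambda t: _dicom_sort_key(*t))
    arrays = [ds.pixel_array for ds, _ in datasets]
    shapes = {a.shape for a in arrays}
    if len(shapes) > 1:
        raise ValueError(f"inconsistent series: in-plane dimensions {sorted(shapes)}")

    first = datasets[0][0]
    pixel_spacing = getattr(first, "PixelSpacing", None)
    slice_step = getattr(first, "SpacingBetweenSlices", None) or getattr(
        first, "SliceThickness", None
    )
    if pixel_spacing is None or slice_step is None:
        if default_spacing is None:
            raise ValueError(
                "DICOM spacing attributes missing and no default_spacing given"
            )
        default_spacing = _validate_spacing(default_spacing)
        if pixel_spacing is None:
            logger.warning(
                "PixelSpacing missing; using default in-plane spacing %s mm",
                default_spacing[1:],
            )
            row_sp, col_sp = default_spacing[1], default_spacing[2]
        else:
            row_sp, col_sp = float(pixel_spacing[0]), float(pixel_spacing[1])
        if slice_step is None:
            logger.warning(
                "SpacingBetweenSlices/SliceThickness missing; "
                "using default slice spacing %s mm",
                default_spacing[0],
            )
            slice_sp = default_spacing[0]
        else:
            slice_sp = float(slice_step)
    else:
        row_sp, col_sp = float(pixel_spacing[0]), float(pixel_spacing[1])
        slice_sp = float(slice_step)

    data = np.stack(arrays, axis=0)
    if invert:
        data = _invert_intensity(data)
    return VoxelVolume(data=data, spacing=(slice_sp, row_sp, col_sp))


def _invert_intensity(data: np.ndarray) -> np.ndarray:
    if np.issubdtype(data.dtype, np.integer):
        info = np.iinfo(data.dtype)
        return (info.max - data.astype(np.int64) + info.min).astype(data.dtype)
    return data.max() + data.min() - data


def _to_grayscale(img: np.ndarray) -> np.ndarray:
    if img.ndim == 2:
        return img
    if img.ndim == 3 and img.shape[2] in (3, 4):
        # ITU-R 601 luminance; alpha ignored
        rgb = img[..., :3].astype(np.float64)
        gray = rgb @ np.array([0.299, 0.587, 0.114])
        return np.round(gray).astype(img.dtype)
    raise ValueError(f"unsupported image shape {img.shape}")


def read_image_stack(
    file_paths_ordered: Sequence[str | Path],
    spacing: Sequence[float],
    *,
    invert: bool = False,
) -> VoxelVolume:
    """Read an ordered list of 2D slice images into a volume.

    Accepts 8/16-bit grayscale TIFF, BMP or PNG (RGB converted by
    luminance); JPEG is accepted with a lossy-compression warning. The
    slice axis follows the list order and ``spacing`` must be supplied
    by the caller because these formats carry no physical calibration.
    """
    paths = [Path(p) for p in file_paths_ordered]
    if not paths:
        raise ValueError("empty slice list")
    slices = []
    for p in paths:
        if p.suffix.lower() in (".jpg", ".jpeg"):
            warnings.warn(
                f"{p.name}: JPEG is lossy; intensities may differ from the scan export",
                stacklevel=2,
            )
        slices.append(_to_grayscale(np.asarray(iio.imread(p))))
    shapes = {s.shape for s in slices}
    if len(shapes) > 1:
        raise ValueError(f"mixed dimensions across slices: {sorted(shapes)}")
    data = np.stack(slices, axis=0)
    if invert:
        data = _invert_intensity(data)
    return VoxelVolume(data=data, spacing=_validate_spacing(spacing))


# ---------------------------------------------------------------------------
# Writers
# ---------------------------------------------------------------------------


def write_volume_stack(
    volume: VoxelVolume, directory_path: str | Path, fmt: str = "tiff"
) -> list[Path]:
    """Write a volume as one grayscale image per slice (8/16-bit)."""
    data = volume.data
    if np.issubdtype(data.dtype, np.floating):
        data = np.clip(np.round(data), 0, 65535)
        data = data.astype(np.uint8 if data.max() <= 255 else np.uint16)
    return _write_stack(data, directory_path, fmt, prefix="slice")


def write_mask_stack(
    mask_or_labels: BinaryMask | LabelMap,
    directory_path: str | Path,
    fmt: str = "tiff",
) -> list[Path]:
    """Write a mask or label map as an image stack.

    Binary masks are written as 0/255 8-bit images; label maps as
    16-bit (labels must not exceed 65535). Reading the stack back with
    :func:`read_image_stack` reproduces the grid exactly.
    """
    if isinstance(mask_or_labels, BinaryMask):
        data = np.where(mask_or_labels.data, 255, 0).astype(np.uint8)
        prefix = "mask"
    elif isinstance(mask_or_labels, LabelMap):
        if mask_or_labels.data.max(initial=0) > 65535:
            raise ValueError(
                f"label overflow: max label {int(mask_or_labels.data.max())} > 65535"
            )
        data = mask_or_labels.data.astype(np.uint16)
        prefix = "labels"
    else:
        raise TypeError(f"expected BinaryMask or LabelMap, got {type(mask_or_labels)}")
    return _write_stack(data, directory_path, fmt, prefix=prefix)


def _write_stack(
    data: np.ndarray, directory_path: str | Path, fmt: str, prefix: str
) -> list[Path]:
    fmt = fmt.lower().lstrip(".")
    if fmt in ("tif", "tiff"):
        ext, writer = ".tif", tifffile.imwrite
    elif fmt == "png":
        ext, writer = ".png", iio.imwrite
    else:
        raise ValueError(f"unsupported stack format {fmt!r} (use TIFF or PNG)")
    directory_path = Path(directory_path)
    directory_path.mkdir(parents=True, exist_ok=True)
    width = max(4, len(str(data.shape[0] - 1)))
    out = []
    for i in range(data.shape[0]):
        path = directory_path / f"{prefix}_{i:0{width}d}{ext}"
        writer(path, data[i])
        out.append(path)
    return out


def write_report(
    per_grain_metrics: Iterable,
    sample_summary: dict,
    path: str | Path,
    fmt: str = "csv",
) -> Path:
    """Write the per-grain metrics table plus a sample summary block.

    One row per grain with the columns in :data:`REPORT_COLUMNS`
    (numeric metrics rounded to one decimal in mm / percent, volumes to
    four decimals), followed by a summary block with ``grain_count``,
    ``chalky_rice_rate_percent`` and ``mean_CD3D_percent``. An empty
    metrics list produces a report with the summary only.
    """
    fmt = fmt.lower()
    if fmt not in ("csv", "xlsx"):
        raise ValueError(f"unsupported report format {fmt!r} (use CSV or XLSX)")
    path = Path(path)

    rows = []
    for m in per_grain_metrics:
        rows.append(
            {
                "grain_id": int(m.grain_id),
                "VG_mm3": round(float(m.VG), 4),
                "VC_mm3": round(float(m.VC), 4),
                "CD3D_percent": round(float(m.CD3D), 1),
                "CD2D_percent": round(float(m.CD2D), 1),
                "length_mm": round(float(m.length), 4),
                "width_mm": round(float(m.width), 4),
                "length_width_ratio": round(float(m.lw_ratio), 2),
                "is_chalky": bool(m.is_chalky),
            }
        )
    table = pd.DataFrame(rows, columns=REPORT_COLUMNS)

    summary = pd.DataFrame(
        {
            "statistic": [
                "grain_count",
                "chalky_rice_rate_percent",
                "mean_CD3D_percent",
            ],
            "value": [
                int(sample_summary.get("grain_count", len(rows))),
                round(float(sample_summary.get("chalky_rice_rate_percent", 0.0)), 1),
                round(float(sample_summary.get("mean_CD3D_percent", 0.0)), 1),
            ],
        }
    )

    if fmt == "csv":
        with open(path, "w", newline="") as fh:
            table.to_csv(fh, index=False)
            fh.write("\n")
            summary.to_csv(fh, index=False)
    else:
        with pd.ExcelWriter(path, engine="openpyxl") as xl:
            table.to_excel(xl, sheet_name="grains", index=False)
            summary.to_excel(xl, sheet_name="summary", index=False)
    return path


def read_report_csv(path: str | Path) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Read back a CSV report written by :func:`write_report`."""
    text = Path(path).read_text().split("\n\n")
    import io

    table = pd.read_csv(io.StringIO(text[0]))
    summary = pd.read_csv(io.StringIO(text[1]))
    return table, summary
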