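"""Radiograph and spine-mask loading, validation and normalization.

Coordinate convention
---------------------
Row index ``t`` increases downward (superior → inferior on a PA/AP
radiograph); column index ``x`` increases rightward.  All downstream
geometry — centerline slopes, vertebral directions, Cobb angles — is
computed in this raster frame, so anisotropic pixel spacing must be
removed (``resample_isotropic``) before angles are meaningful.

Supported inputs are single-frame grayscale DICOM and 8/16-bit grayscale
PNG.  Pixel intensities are never rescaled: the loader's job is plumbing,
not windowing.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pydicom
from PIL import Image
from skimage import measure

from .errors import (
    AmbiguousMaskError,
    EmptyMaskError,
    InputError,
    PreconditionError,
    UnsupportedFormatError,
)

log = logging.getLogger(__name__)

#: PIL modes accepted as grayscale payloads (8-bit, 16-bit, 32-bit int, float)
_GRAY_MODES = {"L", "I", "I;16", "I;16B", "I;16L", "F"}


@dataclass(frozen=True)
class RadiographImage:
    """A 2-D grayscale radiograph with optional physical pixel spacing.

    Parameters
    ----------
    pixels
        2-D intensity array; dtype is whatever the source file carried.
    spacing_row, spacing_col
        Physical size of one pixel in mm, if known (DICOM ``PixelSpacing``).
    source_id
        Opaque identifier (typically the file stem) echoed into reports.
    """

    pixels: np.ndarray
    spacing_row: float | None = None
    spacing_col: float | None = None
    source_id: str = ""

    def __post_init__(self) -> None:
        px = np.asarray(self.pixels)
        if px.ndim != 2 or px.shape[0] < 2 or px.shape[1] < 2:
            raise PreconditionError(
                f"radiograph must be 2-D with at least 2 rows and 2 columns, got shape {px.shape}"
            )
        for name, s in (("spacing_row", self.spacing_row), ("spacing_col", self.spacing_col)):
            if s is not None and not s > 0:
                raise PreconditionError(f"{name} must be > 0, got {s!r}")
        object.__setattr__(self, "pixels", px)

    @property
    def shape(self) -> tuple[int, int]:
        return self.pixels.shape


@dataclass(frozen=True)
class SpineMask:
    """A binary spine segmentation aligned to a radiograph.

    ``values`` holds exactly {0, 1} (uint8) and contains at least one
    foreground pixel; both are enforced at construction.
    """

    values: np.ndarray
    spacing_row: float | None = None
    spacing_col: float | None = None
    source_id: str = ""

    def __post_init__(self) -> None:
        v = np.asarray(self.values)
        if v.ndim != 2:
            raise PreconditionError(f"mask must be 2-D, got shape {v.shape}")
        uniq = np.unique(v)
        if not np.isin(uniq, (0, 1)).all():
            raise PreconditionError(f"mask values must be exactly {{0, 1}}, got {uniq[:5]}")
        if not v.any():
            raise EmptyMaskError("mask has no foreground pixels")
        for name, s in (("spacing_row", self.spacing_row), ("spacing_col", self.spacing_col)):
            if s is not None and not s > 0:
                raise PreconditionError(f"{name} must be > 0, got {s!r}")
        object.__setattr__(self, "values", v.astype(np.uint8))

    @property
    def shape(self) -> tuple[int, int]:
        return self.values.shape

    @property
    def foreground_count(self) -> int:
        return int(self.values.sum())


@dataclass(frozen=True)
class MaskReport:
    """Structural report from :func:`validate_mask` (report-only, no errors)."""

    n_components: int
    row_coverage: float
    foreground_count: int
    flags: tuple[str, ...] = field(default=())

    @property
    def ok(self) -> bool:
        return not self.flags


def _is_dicom(path: Path) -> bool:
    try:
        return pydicom.misc.is_dicom(path)
    except Exception:
        return path.suffix.lower() in {".dcm", ".dicom"}


def _load_dicom(path: Path) -> RadiographImage:
    try:
        ds = pydicom.dcmread(path)
    except Exception as exc:  # pragma: no cover - corrupt-file path
        raise InputError(f"cannot read DICOM {path}: {exc}") from exc
    if int(getattr(ds, "NumberOfFrames", 1) or 1) > 1:
        raise UnsupportedFormatError(f"{path}: multi-frame DICOM is not supported")
    if int(getattr(ds, "SamplesPerPixel", 1) or 1) != 1:
        raise UnsupportedFormatError(f"{path}: color (multi-sample) DICOM payload is not supported")
    try:
        px = ds.pixel_array
    except Exception as exc:
        raise InputError(f"{path}: DICOM has no decodable pixel data: {exc}") from exc
    if px.ndim != 2:
        raise UnsupportedFormatError(f"{path}: expected 2-D pixel data, got shape {px.shape}")
    spacing = getattr(ds, "PixelSpacing", None) or getattr(ds, "ImagerPixelSpacing", None)
    sr = sc = None
    if spacing is not None:
        sr, sc = float(spacing[0]), float(spacing[1])
    return RadiographImage(px, spacing_row=sr, spacing_col=sc, source_id=path.stem)


def load_image(path) -> RadiographImage:
    """Load a radiograph from DICOM or grayscale PNG.

    Spacing is populated from DICOM ``PixelSpacing`` (or
    ``ImagerPixelSpacing``) when present and left unset otherwise; pixel
    values are passed through unmodified.
    """
    p = Path(path)
    if not p.exists():
        raise InputError(f"no such file: {p}")
    if _is_dicom(p):
        return _load_dicom(p)
    try:
        im = Image.open(p)
    except Exception as exc:
        raise InputError(f"cannot read raster {p}: {exc}") from exc
    if im.mode not in _GRAY_MODES:
        raise UnsupportedFormatError(
            f"{p}: mode {im.mode!r} (color/palette) is not supported; expected 8/16-bit grayscale"
        )
    arr = np.asarray(im)
    if arr.ndim != 2:
        raise UnsupportedFormatError(f"{p}: expected a single-channel raster, got shape {arr.shape}")
    return RadiographImage(arr, source_id=p.stem)


def load_mask(path) -> SpineMask:
    """Load a binary mask raster; nonzero pixels map to 1.

    A raster with more than two distinct pixel values is rejected as
    ambiguous (probabilistic masks must be binarized explicitly upstream),
    and an all-zero raster is rejected as empty.
    """
    p = Path(path)
    if not p.exists():
        raise InputError(f"no such file: {p}")
    try:
        arr = np.asarray(Image.open(p))
    except Exception as exc:
        raise InputError(f"cannot read mask raster {p}: {exc}") from exc
    if arr.ndim != 2:
        raise UnsupportedFormatError(f"{p}: mask must be single-channel, got shape {arr.shape}")
    uniq = np.unique(arr)
    if uniq.size > 2:
        raise AmbiguousMaskError(
            f"{p}: {uniq.size} distinct pixel values; a binary mask may have at most 2"
        )
    if not arr.any():
        raise EmptyMaskError(f"{p}: mask has no foreground pixels")
    return SpineMask((arr != 0).astype(np.uint8), source_id=p.stem)


def save_mask(mask: SpineMask, path) -> None:
    """Write a mask as an 8-bit PNG with foreground = 255."""
    Image.fromarray(mask.values * np.uint8(255), mode="L").save(path)


def resample_isotropic(mask: SpineMask) -> SpineMask:
    """Resample a mask to isotropic spacing (the smaller of the two).

    Nearest-neighbour so the output stays strictly binary.  Slopes, and
    hence every angle downstream, are only meaningful once row and column
    spacing agree.  No-op when spacing is already isotropic.
    """
    if mask.spacing_row is None or mask.spacing_col is None:
        raise PreconditionError("resample_isotropic requires both spacings to be present")
    if mask.spacing_row == mask.spacing_col:
        return mask
    target = min(mask.spacing_row, mask.spacing_col)
    rows, cols = mask.shape
    n_rows = int(round(rows * mask.spacing_row / target))
    n_cols = int(round(cols * mask.spacing_col / target))
    # centre-aligned nearest-neighbour index maps
    ri = np.minimum(np.floor((np.arange(n_rows) + 0.5) * rows / n_rows).astype(int), rows - 1)
    ci = np.minimum(np.floor((np.arange(n_cols) + 0.5) * cols / n_cols).astype(int), cols - 1)
    out = mask.values[np.ix_(ri, ci)]
    return SpineMask(out, spacing_row=target, spacing_col=target, source_id=mask.source_id)


def validate_mask(mask: SpineMask) -> MaskReport:
    """Structural sanity report: connectivity, row coverage, pixel count.

    Flags "fragmented" when the foreground has more than one 8-connected
    component and "gappy" when fewer than 95% of the rows inside the
    foreground's row span contain foreground.  Never mutates its input.
    """
    labeled, n_comp = measure.label(mask.values, connectivity=2, return_num=True)
    rows_with_fg = mask.values.any(axis=1)
    idx = np.flatnonzero(rows_with_fg)
    span = idx[-1] - idx[0] + 1
    coverage = float(idx.size / span)
    flags: list[str] = []
    if n_comp > 1:
        flags.append("fragmented")
    if coverage < 0.95:
        flags.append("gappy")
    return MaskReport(
        n_components=int(n_comp),
        row_coverage=coverage,
        foreground_count=mask.foreground_count,
        flags=tuple(flags),
    )
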