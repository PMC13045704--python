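"""Pluggable spine-instance segmentation contract.

The measurement pipeline starts at a binary spine mask.  Where that mask
comes from — a trained instance-segmentation network, a hand annotation,
a phantom generator — is behind the backend contract here: a callable
``backend(image) -> list[InstanceDetection]``.  When a backend proposes
several instances, the highest-confidence one wins (no confidence
threshold is applied; top-1 selection deliberately replaces thresholding).

Also hosts the Dice coefficient used for mask-quality scoring.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from pathlib import Path
from typing import Callable, Sequence

import numpy as np

from .errors import BackendFailureError, NoDetectionError, PreconditionError
from .imaging_io import RadiographImage, SpineMask, load_mask

Backend = Callable[[RadiographImage], "Sequence[InstanceDetection]"]


@dataclass(frozen=True)
class InstanceDetection:
    """One candidate spine instance from a segmentation backend.

    ``box`` is ``(row_min, col_min, row_max, col_max)`` in pixels,
    half-open (``row_max``/``col_max`` exclusive).  ``mask`` is a binary
    array, either full-frame (``full_frame=True``) or cropped to exactly
    the box, in which case ``frame_shape`` gives the full raster size.
    """

    box: tuple[int, int, int, int]
    confidence: float
    mask: np.ndarray
    full_frame: bool = True
    frame_shape: tuple[int, int] | None = None

    def __post_init__(self) -> None:
        r0, c0, r1, c1 = self.box
        if not (r0 < r1 and c0 < c1):
            raise PreconditionError(f"degenerate box {self.box}")
        if not 0.0 <= self.confidence <= 1.0:
            raise PreconditionError(f"confidence must lie in [0,1], got {self.confidence}")
        m = np.asarray(self.mask)
        if m.ndim != 2:
            raise PreconditionError("detection mask must be 2-D")
        if not self.full_frame:
            if self.frame_shape is None:
                raise PreconditionError("cropped detection requires frame_shape")
            if m.shape != (r1 - r0, c1 - c0):
                raise PreconditionError(
                    f"cropped mask shape {m.shape} does not match box extent {(r1 - r0, c1 - c0)}"
                )
        object.__setattr__(self, "mask", (m != 0).astype(np.uint8))

    def full_frame_mask(self) -> np.ndarray:
        """Binary mask in the full raster frame (box-paste for cropped input)."""
        if self.full_frame:
            return self.mask
        out = np.zeros(self.frame_shape, dtype=np.uint8)
        r0, c0, r1, c1 = self.box
        out[r0:r1, c0:c1] = self.mask
        return out

    @property
    def area(self) -> int:
        return int(np.asarray(self.mask).sum())


def select_best_instance(detections: Sequence[InstanceDetection]) -> SpineMask:
    """Pick the detection with maximal confidence and return its full-frame mask.

    Ties go to the larger foreground area, then to the earliest detection
    in the list, so the result is invariant to input order up to that rule.
    """
    if not detections:
        raise NoDetectionError("backend returned no spine instances")
    best = detections[0]
    for det in detections[1:]:
        if det.confidence > best.confidence or (
            det.confidence == best.confidence and det.area > best.area
        ):
            best = det
    return SpineMask(best.full_frame_mask(), source_id="instance")


def segment(image: RadiographImage, backend: Backend) -> list[InstanceDetection]:
    """Run a segmentation backend and normalize its detections to full frame.

    The backend's output is passed through unmodified apart from pasting
    cropped masks into the image frame; an exception inside the backend is
    wrapped so callers can distinguish backend bugs from pipeline errors.
    """
    try:
        raw = list(backend(image))
    except Exception as exc:
        raise BackendFailureError(f"segmentation backend raised: {exc}") from exc
    out = []
    for det in raw:
        if det.full_frame:
            out.append(det)
        else:
            out.append(
                InstanceDetection(
                    box=det.box,
                    confidence=det.confidence,
                    mask=det.full_frame_mask(),
                    full_frame=True,
                )
            )
    return out


def oracle_backend(mask: SpineMask) -> Backend:
    """Backend that returns a known ground-truth mask at confidence 1.0.

    Stands in for a trained network in tests and worked examples: the
    bespoke computation of this package starts at the mask, so any source
    honoring the contract is interchangeable.
    """

    def _backend(image: RadiographImage) -> list[InstanceDetection]:
        rows = np.flatnonzero(mask.values.any(axis=1))
        cols = np.flatnonzero(mask.values.any(axis=0))
        box = (int(rows[0]), int(cols[0]), int(rows[-1]) + 1, int(cols[-1]) + 1)
        return [InstanceDetection(box=box, confidence=1.0, mask=mask.values, full_frame=True)]

    return _backend


def dice(a: SpineMask, b: SpineMask) -> float:
    """Dice coefficient 2|A∩B| / (|A|+|B|) between two same-shape masks."""
    if a.shape != b.shape:
        raise PreconditionError(f"mask shapes differ: {a.shape} vs {b.shape}")
    inter = int(np.logical_and(a.values, b.values).sum())
    return 2.0 * inter / (a.foreground_count + b.foreground_count)


def detections_to_json(detections: Sequence[InstanceDetection], path, mask_dir) -> None:
    """Serialize detections to JSON, with masks written as PNG beside it."""
    from .imaging_io import save_mask

    mask_dir = Path(mask_dir)
    mask_dir.mkdir(parents=True, exist_ok=True)
    records = []
    for i, det in enumerate(detections):
        mask_path = mask_dir / f"detection_{i:03d}.png"
        save_mask(SpineMask(det.full_frame_mask()), mask_path)
        records.append(
            {"box": list(det.box), "confidence": det.confidence, "mask_path": str(mask_path)}
        )
    Path(path).write_text(json.dumps(records, indent=2))


def detections_from_json(path) -> list[InstanceDetection]:
    records = json.loads(Path(path).read_text())
    out = []
    for rec in records:
        mask = load_mask(rec["mask_path"])
        out.append(
            InstanceDetection(
                box=tuple(rec["box"]), confidence=float(rec["confidence"]), mask=mask.values
            )
        )
    return out
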