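"""Overlay rendering: measurements drawn back onto the radiograph.

The overlay reproduces the measurement's visual audit trail: the fitted
centerline, a direction segment through each tilted point at its
vertebral angle theta, and every Cobb value as text at the apex of its
pair — the main angle in orange with a star marker, secondary angles in
green.  Rendering is pure PIL drawing: deterministic, pixel-exact, and
the output raster has exactly the input image's size.  It never alters
the report's numeric content.
"""

from __future__ import annotations

import numpy as np
from PIL import Image, ImageDraw, ImageFont

from .angles import MeasurementReport
from .errors import PreconditionError
from .imaging_io import RadiographImage

MAIN_COLOR = (255, 140, 0)       # orange: the main Cobb angle
SECONDARY_COLOR = (0, 200, 80)   # green: additional Cobb angles
CENTERLINE_COLOR = (80, 160, 255)


def _to_display(pixels: np.ndarray) -> np.ndarray:
    """8-bit view of arbitrary grayscale data (display only, min-max)."""
    if pixels.dtype == np.uint8:
        return pixels
    lo, hi = float(pixels.min()), float(pixels.max())
    if hi == lo:
        return np.zeros(pixels.shape, dtype=np.uint8)
    return ((pixels.astype(float) - lo) / (hi - lo) * 255).astype(np.uint8)


def plan_annotations(report: MeasurementReport) -> dict:
    """Geometry of every overlay element, in pixel coordinates.

    Exposed separately from the raster so callers (and tests) can inspect
    exactly what will be drawn: the centerline polyline, one direction
    segment per tilted point, and one label per Cobb angle.
    """
    cl = report.centerline
    s, off = cl.scale, cl.offset

    def to_pixel(t: float, x: float) -> tuple[float, float]:
        return (t / s + off, x / s)  # (row, col)

    ts = np.linspace(report.curve.domain[0], report.curve.domain[1], 400)
    xs = report.curve(ts)
    polyline = [to_pixel(t, x) for t, x in zip(ts, xs)]

    height = report.mask_shape[0]
    seg_len = max(height / 16.0, 12.0)
    segments = []
    for tp in report.tilted_points:
        row, col = to_pixel(tp.t_peak, float(report.curve(tp.t_peak)))
        slope = tp.slope_mean
        d = np.array([1.0, slope]) / np.hypot(1.0, slope)  # (drow, dcol), unit
        a = (row - d[0] * seg_len, col - d[1] * seg_len)
        b = (row + d[0] * seg_len, col + d[1] * seg_len)
        segments.append({"from": a, "to": b, "theta_deg": tp.theta})

    labels = []
    for angle in report.angles:
        ru, cu = to_pixel(angle.upper.t_peak, float(report.curve(angle.upper.t_peak)))
        rl, cl_ = to_pixel(angle.lower.t_peak, float(report.curve(angle.lower.t_peak)))
        apex = (0.5 * (ru + rl), 0.5 * (cu + cl_))
        labels.append(
            {
                "apex": apex,
                "text": f"{angle.value:.1f}\N{DEGREE SIGN}",
                "is_main": angle.is_main,
            }
        )
    return {"centerline": polyline, "segments": segments, "labels": labels}


def _star(draw: ImageDraw.ImageDraw, center: tuple[float, float], r: float, color) -> None:
    """5-point star marker (font-independent, hence deterministic)."""
    cy, cx = center
    pts = []
    for k in range(10):
        rad = r if k % 2 == 0 else 0.45 * r
        ang = -np.pi / 2 + k * np.pi / 5
        pts.append((cx + rad * np.cos(ang), cy + rad * np.sin(ang)))
    draw.polygon(pts, fill=color)


def render_overlay(image: RadiographImage, report: MeasurementReport) -> np.ndarray:
    """Draw a measurement report onto its radiograph; returns H×W×3 uint8.

    The report must have been produced from a mask aligned to this image
    (same raster size); anything else is a precondition error.
    """
    if tuple(image.shape) != tuple(report.mask_shape):
        raise PreconditionError(
            f"image shape {image.shape} does not match report mask shape {report.mask_shape}"
        )
    plan = plan_annotations(report)
    base = Image.fromarray(_to_display(image.pixels), mode="L").convert("RGB")
    draw = ImageDraw.Draw(base)
    font = ImageFont.load_default()

    draw.line([(c, r) for r, c in plan["centerline"]], fill=CENTERLINE_COLOR, width=2)

    # direction segments of the main pair inherit the main color
    main = next(lbl for lbl in plan["labels"] if lbl["is_main"])
    main_angle = report.main_angle
    main_peaks = {main_angle.upper.t_peak, main_angle.lower.t_peak}
    for tp, seg in zip(report.tilted_points, plan["segments"]):
        color = MAIN_COLOR if tp.t_peak in main_peaks else SECONDARY_COLOR
        (r0, c0), (r1, c1) = seg["from"], seg["to"]
        draw.line([(c0, r0), (c1, r1)], fill=color, width=2)

    for lbl in plan["labels"]:
        row, col = lbl["apex"]
        color = MAIN_COLOR if lbl["is_main"] else SECONDARY_COLOR
        draw.text((col + 8, row - 6), lbl["text"], fill=color, font=font)
        if lbl["is_main"]:
            _star(draw, (row, col + 2), 6.0, MAIN_COLOR)

    return np.asarray(base)


def save_overlay(image: RadiographImage, report: MeasurementReport, path) -> None:
    Image.fromarray(render_overlay(image, report), mode="RGB").save(path)
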