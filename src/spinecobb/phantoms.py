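"""Synthetic spine phantoms with closed-form ground truth.

A phantom is a band of foreground pixels around a known smooth centerline
x(t) (t = row).  Because the centerline family is analytic, the most
tilted points, vertebral directions and Cobb angles have closed-form /
dense-numeric ground truth (:func:`analytic_cobb`) that never touches the
measurement pipeline's code paths — it is the independent oracle every
pipeline stage is tested against.

Families
--------
constant(x0)                      vertical band, zero curvature
linear(x0, slope)                 uniformly tilted band
single_arch(x0, amplitude)        half-sine arch, one C-shaped curve
s_curve(x0, amplitude, period, phase)  sinusoid, the classic S deformity
spline(control_points)            cubic spline through (t, x) knots

For an s-curve of amplitude A and period T the peak slope is 2πA/T, so
the Cobb angle between adjacent opposite crests is 2·arctan(2πA/T); the
suite builder inverts this to place phantoms in chosen severity bins.

Noise model: boundary jitter perturbs the band half-width (never the
centerline, so the analytic truth stays exact in expectation) and
interior holes knock out non-boundary pixels at a given rate.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Callable, Sequence

import numpy as np
from scipy.interpolate import CubicSpline
from scipy.ndimage import binary_erosion, gaussian_filter
from scipy.optimize import brentq
from skimage import measure

from .agreement import ReaderTable
from .errors import ParameterError, PhantomSpecError, PreconditionError
from .imaging_io import RadiographImage, SpineMask, save_mask

SEVERITY_EDGES = (10.0, 25.0, 45.0, 60.0)

_FAMILIES = {"constant", "linear", "single_arch", "s_curve", "spline"}


@dataclass(frozen=True)
class SpinePhantomSpec:
    """Parametric description of one synthetic spine band.

    Same spec + same seed → bit-identical mask.  ``halfwidth`` may taper
    linearly down the image via ``taper`` (fraction lost at the bottom row)
    but must stay ≥ 2 px everywhere.
    """

    image_height: int = 640
    image_width: int = 320
    family: str = "s_curve"
    params: dict = field(default_factory=dict)
    halfwidth: float = 18.0
    taper: float = 0.0
    spacing: float | None = None
    boundary_jitter_sd: float = 0.0
    hole_rate: float = 0.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.family not in _FAMILIES:
            raise ParameterError(f"unknown centerline family {self.family!r}")
        if self.image_height < 16 or self.image_width < 8:
            raise ParameterError("frame too small for a spine band")
        if not 0.0 <= self.taper < 1.0:
            raise ParameterError(f"taper must lie in [0, 1), got {self.taper}")
        hmin = self.halfwidth * (1.0 - self.taper)
        if hmin < 2.0:
            raise PhantomSpecError(f"half-width must stay ≥ 2 px, reaches {hmin:.2f}")
        if self.hole_rate < 0 or self.hole_rate >= 1:
            raise ParameterError(f"hole_rate must lie in [0, 1), got {self.hole_rate}")

    # -- analytic centerline ------------------------------------------------

    def centerline_fns(self) -> tuple[Callable, Callable, Callable]:
        """(x, dx/dt, d2x/dt2) as vectorized callables of the row index t."""
        H = self.image_height
        p = self.params
        x0 = float(p.get("x0", self.image_width / 2.0))
        if self.family == "constant":
            return (
                lambda t: x0 + 0.0 * np.asarray(t, float),
                lambda t: 0.0 * np.asarray(t, float),
                lambda t: 0.0 * np.asarray(t, float),
            )
        if self.family == "linear":
            a = float(p.get("slope", 0.0))
            return (
                lambda t: x0 + a * np.asarray(t, float),
                lambda t: a + 0.0 * np.asarray(t, float),
                lambda t: 0.0 * np.asarray(t, float),
            )
        if self.family == "single_arch":
            A = float(p["amplitude"])
            w = np.pi / (H - 1)
            return (
                lambda t: x0 + A * np.sin(w * np.asarray(t, float)),
                lambda t: A * w * np.cos(w * np.asarray(t, float)),
                lambda t: -A * w * w * np.sin(w * np.asarray(t, float)),
            )
        if self.family == "s_curve":
            A = float(p["amplitude"])
            T = float(p["period"])
            phase = float(p.get("phase", 0.0))
            w = 2.0 * np.pi / T
            return (
                lambda t: x0 + A * np.sin(w * (np.asarray(t, float) + phase)),
                lambda t: A * w * np.cos(w * (np.asarray(t, float) + phase)),
                lambda t: -A * w * w * np.sin(w * (np.asarray(t, float) + phase)),
            )
        # spline
        pts = np.asarray(p["control_points"], dtype=float)
        cs = CubicSpline(pts[:, 0], pts[:, 1])
        return cs, cs.derivative(1), cs.derivative(2)

    def halfwidth_at(self, t: np.ndarray) -> np.ndarray:
        t = np.asarray(t, dtype=float)
        return self.halfwidth * (1.0 - self.taper * t / (self.image_height - 1))


def rasterize(spec: SpinePhantomSpec) -> tuple[RadiographImage, SpineMask]:
    """Render a phantom to (intensity image, binary mask), seeded.

    Jitter perturbs the half-width per row; interior holes are punched at
    ``hole_rate`` and refilled wholesale if they fragment the band (the
    mask must stay 8-connected).  Errors out if the band leaves the frame.
    """
    H, W = spec.image_height, spec.image_width
    rng = np.random.default_rng(spec.seed)
    t = np.arange(H, dtype=float)
    x_fn, _, _ = spec.centerline_fns()
    xc = np.asarray(x_fn(t), dtype=float)
    hw = spec.halfwidth_at(t)
    if spec.boundary_jitter_sd > 0:
        hw = np.maximum(hw + rng.normal(0.0, spec.boundary_jitter_sd, H), 2.0)
    if (xc - hw).min() < 0 or (xc + hw).max() > W - 1:
        raise PhantomSpecError(
            f"band leaves the {H}x{W} frame "
            f"(columns {float((xc - hw).min()):.1f}..{float((xc + hw).max()):.1f})"
        )
    cols = np.arange(W, dtype=float)
    mask = (np.abs(cols[None, :] - xc[:, None]) <= hw[:, None]).astype(np.uint8)
    if spec.hole_rate > 0:
        interior = binary_erosion(mask.astype(bool), structure=np.ones((3, 3), bool))
        holes = interior & (rng.random(mask.shape) < spec.hole_rate)
        punched = mask.copy()
        punched[holes] = 0
        if measure.label(punched, connectivity=2, return_num=True)[1] == 1:
            mask = punched
        # else: refill — holes must never disconnect the band
    intensity = gaussian_filter(mask * 170.0 + 40.0, sigma=2.0)
    intensity = intensity + rng.normal(0.0, 4.0, mask.shape)
    image = RadiographImage(
        np.clip(intensity, 0, 255).astype(np.uint8),
        spacing_row=spec.spacing,
        spacing_col=spec.spacing,
        source_id=f"phantom_{spec.family}_{spec.seed}",
    )
    return image, SpineMask(
        mask,
        spacing_row=spec.spacing,
        spacing_col=spec.spacing,
        source_id=image.source_id,
    )


@dataclass(frozen=True)
class AnalyticReport:
    """Ground truth for one phantom: tilted locations, directions, angles."""

    t_peaks: tuple[float, ...]
    thetas: tuple[float, ...]
    cobb_values: tuple[float, ...]
    main: float
    severity_level: int


def analytic_cobb(
    spec: SpinePhantomSpec,
    max_interval_frac: float = 0.5,
    n_grid: int = 25_000,
) -> AnalyticReport:
    """Closed-form / dense-numeric ground-truth Cobb angles for a phantom.

    Mirrors the measurement semantics — inflections of the centerline,
    midpoint splits of overlong inflection-free intervals, per-interval
    argmax of |x'|, theta = arctan(x') at the peak (the zero-width-window
    limit), adjacent-pair angles — but entirely on the analytic
    centerline, independent of every pipeline code path.
    """
    H = spec.image_height
    _, dx_fn, d2x_fn = spec.centerline_fns()
    lo, hi = 0.0, float(H - 1)
    grid = np.linspace(lo, hi, n_grid)
    step = grid[1] - grid[0]
    d2 = np.asarray(d2x_fn(grid), dtype=float)
    sign = np.sign(d2)

    inflections: list[float] = []
    for i in range(n_grid - 1):
        if sign[i] == 0:
            if 0 < i and sign[i - 1] * sign[i + 1] < 0:
                inflections.append(float(grid[i]))
        elif sign[i] * sign[i + 1] < 0:
            inflections.append(float(brentq(lambda u: float(d2x_fn(u)), grid[i], grid[i + 1], xtol=step / 100)))

    guard = (hi - lo) / 571.0  # keep inflections off the boundaries, as raster rounding would
    points = [lo]
    for r in sorted(inflections):
        if r - points[-1] > guard and hi - r > guard:
            points.append(r)
    points.append(hi)

    max_len = max_interval_frac * (hi - lo)
    segments: list[float] = []

    def split(a: float, b: float) -> list[float]:
        if b - a > max_len + 1e-12:
            mid = 0.5 * (a + b)
            return split(a, mid)[:-1] + split(mid, b)
        return [a, b]

    for a, b in zip(points[:-1], points[1:]):
        segments.extend(split(a, b)[:-1])
    segments.append(hi)

    t_peaks: list[float] = []
    for a, b in zip(segments[:-1], segments[1:]):
        sub = np.linspace(a, b, max(int(np.ceil((b - a) / step)), 1) + 1)
        slopes = np.abs(np.asarray(dx_fn(sub), dtype=float))
        t_peaks.append(float(sub[int(np.argmax(slopes))]))

    thetas = [float(np.degrees(np.arctan(float(dx_fn(t))))) for t in t_peaks]
    cobbs = [abs(a - b) for a, b in zip(thetas[:-1], thetas[1:])]
    main = max(cobbs) if cobbs else 0.0
    level = int(np.sum(main >= np.asarray(SEVERITY_EDGES)))
    return AnalyticReport(
        t_peaks=tuple(t_peaks),
        thetas=tuple(thetas),
        cobb_values=tuple(cobbs),
        main=main,
        severity_level=level,
    )


# -- severity-targeted suite ------------------------------------------------

#: Target main-angle ranges per severity level, kept off the bin edges so
#: pixel-level noise cannot flip the grade.
_LEVEL_RANGES = {0: (2.0, 8.0), 1: (12.0, 23.0), 2: (27.0, 43.0), 3: (47.0, 58.0), 4: (62.0, 80.0)}


def spec_for_angle(
    target_deg: float,
    family: str = "s_curve",
    height: int = 640,
    width: int = 320,
    seed: int = 0,
    **noise,
) -> SpinePhantomSpec:
    """Invert a family's closed form to hit a target main Cobb angle.

    s_curve: Cobb = 2·arctan(2πA/T)  →  A = T·tan(Cobb/2) / 2π
    single_arch: Cobb = 2·arctan(πA/(H−1))  →  A = (H−1)·tan(Cobb/2) / π
    """
    half = np.radians(target_deg / 2.0)
    if family == "s_curve":
        T = float(noise.pop("period", 400.0))
        A = T * np.tan(half) / (2.0 * np.pi)
        params = {"x0": width / 2.0, "amplitude": A, "period": T, "phase": 0.0}
    elif family == "single_arch":
        A = (height - 1) * np.tan(half) / np.pi
        params = {"x0": width / 2.0, "amplitude": A}
    elif family == "constant":
        if target_deg != 0:
            raise ParameterError("constant family only produces a 0° angle")
        params = {"x0": width / 2.0}
    else:
        raise ParameterError(f"no closed-form inversion for family {family!r}")
    return SpinePhantomSpec(
        image_height=height, image_width=width, family=family, params=params, seed=seed, **noise
    )


def severity_suite(
    n_per_level: int = 2,
    seed: int = 7,
    jitter_sd: float = 0.0,
    hole_rate: float = 0.0,
    height: int = 640,
    width: int = 320,
) -> list[tuple[SpinePhantomSpec, float]]:
    """Phantoms spanning severity levels 0-4, ≥ ``n_per_level`` each.

    Targets are spread inside each level's safe range; the single-arch
    family is alternated in at low-to-moderate severities (its amplitude
    at high severity would leave the frame), s-curves carry the rest.
    """
    if n_per_level < 1:
        raise ParameterError("n_per_level must be ≥ 1")
    out: list[tuple[SpinePhantomSpec, float]] = []
    k = 0
    for level in sorted(_LEVEL_RANGES):
        lo, hi = _LEVEL_RANGES[level]
        targets = np.linspace(lo, hi, n_per_level) if n_per_level > 1 else [0.5 * (lo + hi)]
        for j, target in enumerate(targets):
            family = "single_arch" if (level <= 2 and j % 2 == 1) else "s_curve"
            spec = spec_for_angle(
                float(target),
                family=family,
                height=height,
                width=width,
                seed=seed + k,
                boundary_jitter_sd=jitter_sd,
                hole_rate=hole_rate,
            )
            out.append((spec, float(target)))
            k += 1
    return out


def make_reader_panel(
    truths: Sequence[float],
    m: int = 7,
    bias_sd: float = 1.0,
    noise_sd: float = 3.0,
    seed: int = 0,
) -> ReaderTable:
    """Simulate an m-reader panel: truth + per-rater bias + i.i.d. noise.

    Rater j on case k reads truth_k + b_j + e_jk with b_j ~ N(0, bias_sd²)
    and e_jk ~ N(0, noise_sd²), clipped at 0°.  Same seed → same table.
    """
    if m < 2:
        raise PreconditionError("a panel needs at least 2 raters")
    if bias_sd < 0 or noise_sd < 0:
        raise PreconditionError("standard deviations must be ≥ 0")
    truths = np.asarray(truths, dtype=float)
    rng = np.random.default_rng(seed)
    bias = rng.normal(0.0, bias_sd, m) if bias_sd > 0 else np.zeros(m)
    noise = rng.normal(0.0, noise_sd, (truths.size, m)) if noise_sd > 0 else np.zeros((truths.size, m))
    values = np.clip(truths[:, None] + bias[None, :] + noise, 0.0, None)
    return ReaderTable(
        values=values,
        case_ids=tuple(f"case_{i:03d}" for i in range(truths.size)),
        rater_ids=tuple(f"reader_{j + 1}" for j in range(m)),
    )


def fixture_suite(
    out_dir,
    n_per_level: int = 2,
    seed: int = 7,
    noise: str = "none",
) -> dict:
    """Write a versioned phantom fixture set: masks, images, truth, readers.

    Layout: ``masks/*.png``, ``images/*.png``, ``truth.json`` and
    ``readers.csv``; regeneration with the same seed is byte-identical.
    """
    if noise not in {"none", "jitter"}:
        raise ParameterError(f"noise must be 'none' or 'jitter', got {noise!r}")
    out = Path(out_dir)
    (out / "masks").mkdir(parents=True, exist_ok=True)
    (out / "images").mkdir(parents=True, exist_ok=True)
    jitter = 1.0 if noise == "jitter" else 0.0
    suite = severity_suite(n_per_level=n_per_level, seed=seed, jitter_sd=jitter)
    truth_records = []
    truths = []
    for i, (spec, target) in enumerate(suite):
        case_id = f"case_{i:03d}"
        image, mask = rasterize(spec)
        save_mask(mask, out / "masks" / f"{case_id}.png")
        from PIL import Image as _PILImage

        _PILImage.fromarray(image.pixels, mode="L").save(out / "images" / f"{case_id}.png")
        truth = analytic_cobb(spec)
        truths.append(truth.main)
        truth_records.append(
            {
                "case_id": case_id,
                "family": spec.family,
                "target_deg": round(target, 6),
                "thetas": [round(v, 6) for v in truth.thetas],
                "cobb_values": [round(v, 6) for v in truth.cobb_values],
                "main": round(truth.main, 6),
                "severity": truth.severity_level,
            }
        )
    (out / "truth.json").write_text(json.dumps(truth_records, indent=2) + "\n")
    panel = make_reader_panel(truths, seed=seed + 1000)
    panel.to_csv(out / "readers.csv")
    return {"n_cases": len(suite), "dir": str(out)}
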