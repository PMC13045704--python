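"""Spine centerline extraction, length normalization and polynomial smoothing.

The centerline is the per-row centroid of the segmented spine: for every
mask row containing foreground, the arithmetic mean of the foreground
column indices.  The sample sequence x(t) (t = row index) is then mapped
affinely onto a fixed 572-sample grid so that one smoothing configuration
serves exams of any resolution; crucially, the lateral coordinate is
scaled by the *same* affine factor, which preserves slopes dx/dt exactly
and hence leaves every angle downstream invariant to the normalization.

Smoothing is a single least-squares polynomial fit of fixed degree
(default 10, the maximum).  Internally the fit is conditioned on [-1, 1]
(a degree-10 Vandermonde on [0, 571] is numerically singular); the stored
curve evaluates values and first/second derivatives analytically.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .errors import DomainError, FitFailureError, PreconditionError, TooShortSpineError
from .imaging_io import SpineMask

#: Fixed length (in samples) every centerline is normalized to before fitting.
NORMALIZED_LENGTH = 572

#: Minimum foreground rows needed to support a degree-10 fit with slack.
MIN_FOREGROUND_ROWS = 12


@dataclass(frozen=True)
class Centerline:
    """Ordered (t, x) centroid samples of a spine mask.

    ``scale``/``offset`` record the affine map from the source row frame
    into this centerline's t frame (t = (row - offset) * scale), so
    overlay rendering can project normalized geometry back onto pixels.
    """

    t: np.ndarray
    x: np.ndarray
    n_rows_source: int
    scale: float = 1.0
    offset: float = 0.0

    def __post_init__(self) -> None:
        t = np.asarray(self.t, dtype=float)
        x = np.asarray(self.x, dtype=float)
        if t.shape != x.shape or t.ndim != 1:
            raise PreconditionError("t and x must be 1-D arrays of equal length")
        if t.size >= 2 and not (np.diff(t) > 0).all():
            raise PreconditionError("t must be strictly increasing")
        object.__setattr__(self, "t", t)
        object.__setattr__(self, "x", x)

    def __len__(self) -> int:
        return self.t.size

    @property
    def is_normalized(self) -> bool:
        return len(self) == NORMALIZED_LENGTH and self.t[0] == 0 and self.t[-1] == NORMALIZED_LENGTH - 1


@dataclass(frozen=True)
class FittedCurve:
    """A least-squares polynomial x = f(t) over a closed domain.

    Wraps a :class:`numpy.polynomial.Polynomial` conditioned on [-1, 1];
    evaluation outside the domain raises, since the fit has no meaning
    beyond the spine it smoothed.
    """

    poly: np.polynomial.Polynomial
    domain: tuple[float, float]
    degree: int
    residual_rms: float = float("nan")

    def _check(self, t) -> np.ndarray:
        t = np.asarray(t, dtype=float)
        lo, hi = self.domain
        eps = 1e-9 * max(1.0, hi - lo)
        if np.any(t < lo - eps) or np.any(t > hi + eps):
            raise DomainError(f"t outside curve domain [{lo}, {hi}]")
        return t

    def __call__(self, t):
        return self.poly(self._check(t))

    def d1(self, t):
        """First derivative dx/dt (slope) at t."""
        return self.poly.deriv(1)(self._check(t))

    def d2(self, t):
        """Second derivative at t — the curvature proxy used for breakpoints."""
        return self.poly.deriv(2)(self._check(t))

    def to_dict(self) -> dict:
        return {
            "coefficients": [float(c) for c in self.poly.coef],
            "window": [float(w) for w in self.poly.window],
            "domain": [float(self.domain[0]), float(self.domain[1])],
            "degree": self.degree,
            "residual_rms": float(self.residual_rms),
        }


def extract_centerline(mask: SpineMask) -> Centerline:
    """Per-row foreground centroids of a spine mask, ordered by row.

    The centroid is the mean of *all* foreground column indices in the
    row — robust to interior holes.  Rows without foreground inside the
    spine's span are skipped; the later polynomial fit bridges them.
    """
    v = mask.values
    rows = np.flatnonzero(v.any(axis=1))
    if rows.size < MIN_FOREGROUND_ROWS:
        raise TooShortSpineError(
            f"only {rows.size} foreground rows; at least {MIN_FOREGROUND_ROWS} required "
            "to support a degree-10 fit"
        )
    cols = np.arange(v.shape[1], dtype=float)
    counts = v[rows].sum(axis=1)
    centroids = (v[rows] * cols).sum(axis=1) / counts
    return Centerline(t=rows.astype(float), x=centroids, n_rows_source=int(rows.size))


def normalize_length(cl: Centerline, length: int = NORMALIZED_LENGTH) -> Centerline:
    """Resample a centerline onto ``length`` uniform samples t = 0..length-1.

    The source row span [t0, tN] is mapped affinely onto [0, length-1] and
    x is multiplied by the same factor, so dx/dt — and therefore every
    angle computed later — is exactly preserved.  Idempotent: normalizing
    an already-normalized centerline is the identity.
    """
    if len(cl) < 2:
        raise PreconditionError("normalization needs at least 2 samples")
    span = cl.t[-1] - cl.t[0]
    s = (length - 1) / span
    t_scaled = (cl.t - cl.t[0]) * s
    x_scaled = cl.x * s
    t_new = np.arange(length, dtype=float)
    x_new = np.interp(t_new, t_scaled, x_scaled)
    return Centerline(
        t=t_new,
        x=x_new,
        n_rows_source=cl.n_rows_source,
        scale=cl.scale * s,
        offset=cl.offset + cl.t[0] / cl.scale,
    )


def fit_curve(cl: Centerline, degree: int = 10) -> FittedCurve:
    """Least-squares polynomial fit of a centerline at fixed degree.

    No model selection: the degree (max 10) is a configuration choice,
    and the fit is deterministic.  Residual RMS is reported alongside.
    """
    if not 1 <= degree <= 10:
        raise PreconditionError(f"degree must be in 1..10, got {degree}")
    if len(cl) <= degree:
        raise PreconditionError(f"need more samples ({len(cl)}) than degree ({degree})")
    poly, diag = np.polynomial.Polynomial.fit(cl.t, cl.x, deg=degree, full=True)
    rank = diag[1]
    if rank < degree + 1:
        raise FitFailureError(f"rank-deficient fit: rank {rank} < {degree + 1} coefficients")
    resid = cl.x - poly(cl.t)
    rms = float(np.sqrt(np.mean(resid**2)))
    return FittedCurve(
        poly=poly,
        domain=(float(cl.t[0]), float(cl.t[-1])),
        degree=degree,
        residual_rms=rms,
    )
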