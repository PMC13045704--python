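"""Pipeline configuration: the handful of knobs that matter, validated.

Defaults mirror the measurement procedure's published operating point:
tolerance 0.15 of each interval, polynomial degree 10, 572-sample
normalized centerline, severity thresholds at 10/25/45/60 degrees.
"""

from __future__ import annotations

from dataclasses import asdict, dataclass, fields
from pathlib import Path

from .errors import ParameterError

SEVERITY_THRESHOLDS = (10.0, 25.0, 45.0, 60.0)


@dataclass(frozen=True)
class PipelineConfig:
    """Resolved configuration echoed into every report.

    Parameters
    ----------
    tolerance
        Fraction Lt of each interval's length over which the derivative is
        averaged to obtain a vertebral direction; in (0, 1].
    degree
        Polynomial degree of the centerline fit, 1..10.
    max_interval_frac
        Intervals longer than this fraction of the curve domain are split
        at their midpoint, recursively; in (0, 1].
    grid_step
        Step (in normalized samples) of the dense grids used for
        inflection scanning and tilt argmax; deterministic, no randomness.
    normalized_length
        Number of samples every centerline is resampled to (572).
    severity_thresholds
        Ascending degree thresholds separating severity levels 0-4.
    icc_variant / kappa_weighting
        Agreement-suite selections (``"2,1"``/``"2,k"``/``"3,1"``;
        ``"unweighted"``/``"linear"``/``"quadratic"``).
    seed
        Seed echoed into provenance; the measurement engine itself is
        deterministic and never consumes it.
    """

    tolerance: float = 0.15
    degree: int = 10
    max_interval_frac: float = 0.5
    grid_step: float = 0.25
    normalized_length: int = 572
    severity_thresholds: tuple[float, ...] = SEVERITY_THRESHOLDS
    icc_variant: str = "2,1"
    kappa_weighting: str = "unweighted"
    seed: int = 0

    def __post_init__(self) -> None:
        if not 0.0 < self.tolerance <= 1.0:
            raise ParameterError(f"tolerance must lie in (0, 1], got {self.tolerance}")
        if not 1 <= int(self.degree) <= 10:
            raise ParameterError(f"degree must lie in 1..10, got {self.degree}")
        if not 0.0 < self.max_interval_frac <= 1.0:
            raise ParameterError(
                f"max_interval_frac must lie in (0, 1], got {self.max_interval_frac}"
            )
        if not self.grid_step > 0:
            raise ParameterError(f"grid_step must be > 0, got {self.grid_step}")
        if int(self.normalized_length) < 16:
            raise ParameterError(f"normalized_length too small: {self.normalized_length}")
        th = tuple(float(t) for t in self.severity_thresholds)
        if list(th) != sorted(th) or len(th) != 4 or th[0] <= 0:
            raise ParameterError(f"severity_thresholds must be 4 ascending positives, got {th}")
        if self.icc_variant not in {"2,1", "2,k", "3,1"}:
            raise ParameterError(f"unknown icc_variant {self.icc_variant!r}")
        if self.kappa_weighting not in {"unweighted", "linear", "quadratic"}:
            raise ParameterError(f"unknown kappa_weighting {self.kappa_weighting!r}")
        object.__setattr__(self, "severity_thresholds", th)

    def as_dict(self) -> dict:
        d = asdict(self)
        d["severity_thresholds"] = list(self.severity_thresholds)
        return d

    @classmethod
    def from_dict(cls, mapping: dict) -> "PipelineConfig":
        known = {f.name for f in fields(cls)}
        unknown = set(mapping) - known
        if unknown:
            raise ParameterError(f"unknown config keys: {sorted(unknown)}")
        return cls(**mapping)

    @classmethod
    def from_file(cls, path) -> "PipelineConfig":
        """Read a flat ``key = value`` text file ('#' starts a comment)."""
        numeric = {
            "tolerance": float,
            "degree": int,
            "max_interval_frac": float,
            "grid_step": float,
            "normalized_length": int,
            "seed": int,
        }
        out: dict = {}
        for lineno, line in enumerate(Path(path).read_text().splitlines(), 1):
            line = line.split("#", 1)[0].strip()
            if not line:
                continue
            if "=" not in line:
                raise ParameterError(f"{path}:{lineno}: expected 'key = value', got {line!r}")
            key, _, value = (s.strip() for s in line.partition("="))
            if key == "severity_thresholds":
                out[key] = tuple(float(v) for v in value.split(","))
            elif key in numeric:
                out[key] = numeric[key](value)
            else:
                out[key] = value
        return cls.from_dict(out)

    def replace(self, **changes) -> "PipelineConfig":
        d = self.as_dict()
        d.update(changes)
        return self.from_dict(d)
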