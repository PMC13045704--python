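"""Multi-reader agreement statistics and tolerance calibration.

A reader study yields an n_cases × m_raters table of main Cobb angles.
This module computes the full comparison battery between that panel and
an automated measurement column:

* deviation from the per-case reader mean and median
  (D̄_mean = (1/n) Σ |R̄_k − D_k|, D̄_median analogously);
* the average pairwise difference among readers,
  D̄_readers = (1/n) Σ_k Σ_{i≠j} |R_i,k − R_j,k| / (m(m−1)) (ordered pairs),
  and D̄_readers−DL, the mean absolute difference between the automated
  column and each reader;
* the pairwise mean-absolute-difference (MAD) matrix across all columns;
* Pearson correlation, intraclass correlation (two-way random-effects
  mean-squares decomposition; ICC(2,1) absolute-agreement single-rater by
  default, ICC(2,k) and ICC(3,1) selectable);
* Cohen's kappa on 5-level severity labels and the severity
  classification metrics (accuracy, balanced accuracy, macro-F1, and the
  scoliosis-detection F1 with levels 2-4 pooled as positive).

The tolerance Lt is calibrated by minimizing Σ_k |D_k(Lt) − R̄_k| over a
candidate grid, D_k being each case's recomputed main angle.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Callable, Sequence

import numpy as np
import pandas as pd
from scipy import stats as sps
from sklearn import metrics as skm

from .angles import apply_tolerance, cobb_angles, locate_tilted_points
from .centerline import FittedCurve
from .errors import ParameterError, PreconditionError, UndefinedMetricError

SEVERITY_LABELS = (0, 1, 2, 3, 4)


@dataclass(frozen=True)
class ReaderTable:
    """n_cases × m_raters matrix of main Cobb angles in degrees."""

    values: np.ndarray
    case_ids: tuple[str, ...]
    rater_ids: tuple[str, ...]

    def __post_init__(self) -> None:
        v = np.asarray(self.values, dtype=float)
        if v.ndim != 2:
            raise PreconditionError("reader table must be 2-D (cases × raters)")
        n, m = v.shape
        if n < 1 or m < 2:
            raise PreconditionError(f"need ≥1 case and ≥2 raters, got {n}×{m}")
        if not np.isfinite(v).all():
            raise PreconditionError("reader table contains non-finite entries")
        if (v < 0).any():
            raise PreconditionError("Cobb angles must be non-negative")
        if len(self.case_ids) != n or len(self.rater_ids) != m:
            raise PreconditionError("label lengths do not match the value matrix")
        object.__setattr__(self, "values", v)
        object.__setattr__(self, "case_ids", tuple(str(c) for c in self.case_ids))
        object.__setattr__(self, "rater_ids", tuple(str(r) for r in self.rater_ids))

    @property
    def n_cases(self) -> int:
        return self.values.shape[0]

    @property
    def n_raters(self) -> int:
        return self.values.shape[1]

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.values, index=list(self.case_ids), columns=list(self.rater_ids))

    @classmethod
    def from_csv(cls, path) -> "ReaderTable":
        """CSV with a header row of rater ids and a first column of case ids.

        Missing cells are rejected: every reader measured every case.
        """
        df = pd.read_csv(path, index_col=0)
        if df.isna().any().any():
            raise PreconditionError(f"{path}: missing cells in reader table")
        return cls(
            values=df.to_numpy(dtype=float),
            case_ids=tuple(str(i) for i in df.index),
            rater_ids=tuple(str(c) for c in df.columns),
        )

    def to_csv(self, path) -> None:
        self.to_frame().to_csv(path, index_label="case_id")


def _check_dl(table: ReaderTable, dl: Sequence[float]) -> np.ndarray:
    dl = np.asarray(dl, dtype=float)
    if dl.shape != (table.n_cases,):
        raise PreconditionError(
            f"dl length {dl.shape} does not match {table.n_cases} cases"
        )
    return dl


def deviation_stats(table: ReaderTable, dl: Sequence[float]) -> tuple[float, float]:
    """(D̄_mean, D̄_median): mean over cases of |reader mean − D| and |reader median − D|."""
    dl = _check_dl(table, dl)
    r_mean = table.values.mean(axis=1)
    r_median = np.median(table.values, axis=1)
    return float(np.mean(np.abs(r_mean - dl))), float(np.mean(np.abs(r_median - dl)))


def pairwise_reader_diff(table: ReaderTable) -> float:
    """Average pairwise absolute difference among readers (ordered pairs, /m(m−1))."""
    v = table.values
    m = table.n_raters
    diffs = np.abs(v[:, :, None] - v[:, None, :])  # n × m × m, diagonal zero
    per_case = diffs.sum(axis=(1, 2)) / (m * (m - 1))
    return float(per_case.mean())


def readers_vs_dl(table: ReaderTable, dl: Sequence[float]) -> float:
    """Mean over cases of the mean absolute difference between dl and each reader."""
    dl = _check_dl(table, dl)
    return float(np.mean(np.abs(table.values - dl[:, None]).mean(axis=1)))


def mad_matrix(table: ReaderTable, dl: Sequence[float] | None = None) -> pd.DataFrame:
    """Pairwise mean-absolute-difference matrix across raters (and a DL column).

    Entry (i, j) is the mean over cases of |col_i − col_j|; symmetric with
    zero diagonal.  A ``mean_vs_others`` column summarizes each rater's
    average MAD to all other columns.
    """
    df = table.to_frame()
    if dl is not None:
        df = df.assign(DL=_check_dl(table, dl))
    cols = list(df.columns)
    v = df.to_numpy(dtype=float)
    mad = np.abs(v[:, :, None] - v[:, None, :]).mean(axis=0)
    out = pd.DataFrame(mad, index=cols, columns=cols)
    k = len(cols)
    out["mean_vs_others"] = (out[cols].to_numpy().sum(axis=1)) / (k - 1)
    return out


def pearson(a: Sequence[float], b: Sequence[float]) -> float:
    """Sample Pearson correlation; undefined on zero variance."""
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if a.shape != b.shape or a.size < 3:
        raise PreconditionError("pearson needs two equal-length vectors of length ≥ 3")
    if np.ptp(a) == 0 or np.ptp(b) == 0:
        raise UndefinedMetricError("pearson undefined: zero variance input")
    return float(sps.pearsonr(a, b).statistic)


def icc(table: ReaderTable, variant: str = "2,1") -> float:
    """Intraclass correlation from the two-way mean-squares decomposition.

    ``variant``:

    * ``"2,1"`` — two-way random effects, absolute agreement, single rater
      (default: raters are a random sample and systematic offsets count
      against agreement);
    * ``"2,k"`` — same model, reliability of the k-rater mean;
    * ``"3,1"`` — two-way mixed, consistency (rater offsets forgiven).
    """
    v = table.values
    n, m = v.shape
    if n < 2:
        raise PreconditionError("icc needs at least 2 cases")
    grand = v.mean()
    if np.allclose(v, grand):
        raise UndefinedMetricError("icc undefined: zero total variance")
    row_means = v.mean(axis=1)
    col_means = v.mean(axis=0)
    msr = m * np.sum((row_means - grand) ** 2) / (n - 1)          # between cases
    msc = n * np.sum((col_means - grand) ** 2) / (m - 1)          # between raters
    resid = v - row_means[:, None] - col_means[None, :] + grand
    mse = np.sum(resid**2) / ((n - 1) * (m - 1))
    if variant == "2,1":
        denom = msr + (m - 1) * mse + m * (msc - mse) / n
    elif variant == "2,k":
        denom = msr + (msc - mse) / n
    elif variant == "3,1":
        denom = msr + (m - 1) * mse
    else:
        raise ParameterError(f"unknown ICC variant {variant!r}")
    if denom == 0:
        raise UndefinedMetricError("icc undefined: zero denominator")
    if variant == "2,k":
        return float((msr - mse) / denom)
    return float((msr - mse) / denom)


def cohen_kappa(
    a: Sequence[int], b: Sequence[int], weighting: str = "unweighted"
) -> float:
    """Cohen's kappa between two severity-label vectors on the 5-level scale.

    Unweighted by default; ``"linear"``/``"quadratic"`` weights are
    available for the ordinal scale.  Undefined when chance agreement is
    one (both raters constant and equal).
    """
    a = np.asarray(a, dtype=int)
    b = np.asarray(b, dtype=int)
    if a.shape != b.shape or a.ndim != 1 or a.size == 0:
        raise PreconditionError("cohen_kappa needs two equal-length label vectors")
    for v in (a, b):
        if not np.isin(v, SEVERITY_LABELS).all():
            raise PreconditionError(f"labels must come from {SEVERITY_LABELS}")
    # chance agreement from the marginals; p_e == 1 iff both constant and equal
    pa = np.bincount(a, minlength=5) / a.size
    pb = np.bincount(b, minlength=5) / b.size
    if np.isclose(float(pa @ pb), 1.0):
        raise UndefinedMetricError("kappa undefined: chance agreement is 1")
    weights = None if weighting == "unweighted" else weighting
    if weighting not in {"unweighted", "linear", "quadratic"}:
        raise ParameterError(f"unknown kappa weighting {weighting!r}")
    return float(
        skm.cohen_kappa_score(a, b, labels=list(SEVERITY_LABELS), weights=weights)
    )


def classification_metrics(truth: Sequence[int], pred: Sequence[int]) -> dict[str, float]:
    """Severity-grading metrics: accuracy, balanced accuracy, macro-F1,
    and scoliosis-detection F1 (levels 2-4 pooled as positive)."""
    truth = np.asarray(truth, dtype=int)
    pred = np.asarray(pred, dtype=int)
    if truth.shape != pred.shape or truth.size == 0:
        raise PreconditionError("truth and pred must be equal-length, non-empty")
    detect_truth = (truth >= 2).astype(int)
    detect_pred = (pred >= 2).astype(int)
    return {
        "accuracy": float(skm.accuracy_score(truth, pred)),
        "balanced_accuracy": float(skm.balanced_accuracy_score(truth, pred)),
        "f1_multi": float(skm.f1_score(truth, pred, average="macro", zero_division=0)),
        "f1_scoliosis_detect": float(
            skm.f1_score(detect_truth, detect_pred, zero_division=0)
        ),
    }


def abs_dev_quantile(dl: Sequence[float], reference: Sequence[float], q: float = 0.95) -> float:
    """Empirical quantile of |D_k − reference_k| (inclusive linear interpolation)."""
    d = np.abs(np.asarray(dl, float) - np.asarray(reference, float))
    return float(np.quantile(d, q, method="linear"))


def bootstrap_ci(
    stat: Callable[[np.ndarray], float],
    per_case: Sequence[float],
    n_boot: int = 10_000,
    seed: int = 0,
    alpha: float = 0.05,
) -> tuple[float, float]:
    """Nonparametric percentile bootstrap CI over cases for a per-case statistic."""
    x = np.asarray(per_case, dtype=float)
    rng = np.random.default_rng(seed)
    idx = rng.integers(0, x.size, size=(n_boot, x.size))
    reps = np.array([stat(x[row]) for row in idx])
    return float(np.quantile(reps, alpha / 2)), float(np.quantile(reps, 1 - alpha / 2))


@dataclass(frozen=True)
class CalibrationResult:
    best_tolerance: float
    objective: float
    trace: dict[float, float]


def main_angle_at_tolerance(
    curve: FittedCurve, breakpoints, tolerance: float, grid_step: float = 0.25
) -> float:
    """Recompute one case's main Cobb angle at a given tolerance Lt."""
    tps = locate_tilted_points(curve, breakpoints, grid_step)
    tps = [apply_tolerance(curve, tp, tolerance) for tp in tps]
    return max(a.value for a in cobb_angles(tps))


def calibrate_tolerance(
    cases: Sequence[tuple[FittedCurve, Sequence]],
    reader_avgs: Sequence[float],
    grid: Sequence[float],
    grid_step: float = 0.25,
) -> CalibrationResult:
    """Choose Lt minimizing Σ_k |D_k(Lt) − R̄_k| over a candidate grid.

    ``cases`` pairs each fitted curve with its breakpoints; ``reader_avgs``
    is the per-case mean of the reader panel.  Ties go to the smallest Lt;
    the full objective trace is returned for audit.
    """
    grid = list(grid)
    if not grid:
        raise ParameterError("empty tolerance grid")
    if any(not 0.0 < lt <= 1.0 for lt in grid):
        raise ParameterError("tolerance candidates must lie in (0, 1]")
    reader_avgs = np.asarray(reader_avgs, dtype=float)
    if reader_avgs.shape != (len(cases),):
        raise PreconditionError("one reader average required per case")
    trace: dict[float, float] = {}
    for lt in sorted(grid):
        dk = np.array(
            [main_angle_at_tolerance(curve, bps, lt, grid_step) for curve, bps in cases]
        )
        trace[float(lt)] = float(np.abs(dk - reader_avgs).sum())
    # ascending scan with strict improvement: objectives within numerical
    # noise of each other tie, and the tie goes to the smallest Lt
    best = None
    for lt in sorted(trace):
        if best is None or trace[lt] < trace[best] - 1e-9:
            best = lt
    return CalibrationResult(best_tolerance=best, objective=trace[best], trace=trace)
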