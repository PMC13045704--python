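"""Reader-agreement battery: deviations, MAD, Pearson, ICC, kappa, grading."""

import numpy as np
import pytest

from spinecobb import (
    ReaderTable,
    abs_dev_quantile,
    bootstrap_ci,
    calibrate_tolerance,
    classification_metrics,
    cohen_kappa,
    deviation_stats,
    icc,
    mad_matrix,
    make_reader_panel,
    pairwise_reader_diff,
    pearson,
    readers_vs_dl,
)
from spinecobb.errors import ParameterError, PreconditionError, UndefinedMetricError


def table(rows, rater_prefix="r"):
    rows = np.atleast_2d(np.asarray(rows, dtype=float))
    return ReaderTable(
        values=rows,
        case_ids=tuple(f"c{i}" for i in range(rows.shape[0])),
        rater_ids=tuple(f"{rater_prefix}{j}" for j in range(rows.shape[1])),
    )


class TestDeviationStats:
    def test_dl_at_reader_center_scores_zero(self):
        d_mean, d_median = deviation_stats(table([[10, 12, 14]]), [12.0])
        assert d_mean == 0.0 and d_median == 0.0

    def test_skewed_panel_separates_mean_and_median(self):
        # readers [10, 20, 60]: mean 30, median 20; dl 20 -> (10, 0)
        d_mean, d_median = deviation_stats(table([[10, 20, 60]]), [20.0])
        assert d_mean == pytest.approx(10.0)
        assert d_median == pytest.approx(0.0)

    def test_dl_tracking_the_median_reader(self):
        t = table([[8, 10, 30], [14, 20, 90], [5, 6, 7]])
        dl = np.median(t.values, axis=1)
        assert deviation_stats(t, dl)[1] == 0.0

    def test_length_mismatch_rejected(self):
        with pytest.raises(PreconditionError):
            deviation_stats(table([[1, 2]]), [1.0, 2.0])


class TestPairwiseReaderDiff:
    def test_two_readers_single_case(self):
        assert pairwise_reader_diff(table([[10, 14]])) == pytest.approx(4.0)

    def test_identical_readers_score_zero(self):
        assert pairwise_reader_diff(table([[7, 7, 7], [9, 9, 9]])) == 0.0

    def test_three_reader_hand_example(self):
        # ordered |differences| sum to 48 over 6 ordered pairs -> 8
        assert pairwise_reader_diff(table([[0, 6, 12]])) == pytest.approx(8.0)


class TestReadersVsDl:
    def test_dl_equal_to_every_reader(self):
        assert readers_vs_dl(table([[12, 12], [30, 30]]), [12.0, 30.0]) == 0.0

    def test_single_case_two_readers(self):
        assert readers_vs_dl(table([[10, 20]]), [10.0]) == pytest.approx(5.0)

    def test_single_case_three_readers(self):
        # |10-8| + |10-12| + |10-16| = 10 over three readers
        assert readers_vs_dl(table([[8, 12, 16]]), [10.0]) == pytest.approx(10 / 3)


class TestMadMatrix:
    def test_identical_columns_all_zero(self):
        out = mad_matrix(table([[5, 5], [9, 9]]))
        assert (out[["r0", "r1"]].to_numpy() == 0).all()

    def test_constant_offset_appears_off_diagonal(self):
        out = mad_matrix(table([[10, 13], [20, 23]]))
        assert out.loc["r0", "r1"] == pytest.approx(3.0)
        assert out.loc["r1", "r0"] == pytest.approx(3.0)
        assert out.loc["r0", "r0"] == 0.0

    def test_three_rater_hand_example(self):
        out = mad_matrix(table([[1, 2, 4], [1, 2, 4]]))
        assert out.loc["r0", "r2"] == pytest.approx(3.0)

    def test_dl_column_and_summary(self):
        out = mad_matrix(table([[10, 12], [20, 22]]), dl=[11.0, 21.0])
        assert "DL" in out.index
        assert out.loc["DL", "r0"] == pytest.approx(1.0)
        assert out.loc["r0", "mean_vs_others"] == pytest.approx((2.0 + 1.0) / 2)


class TestPearson:
    def test_identity_and_inverse(self):
        a = [10.0, 20.0, 30.0, 40.0]
        assert pearson(a, a) == pytest.approx(1.0)
        assert pearson(a, [-v + 100 for v in a]) == pytest.approx(-1.0)

    def test_four_point_hand_example(self):
        assert pearson([1, 2, 3, 4], [1, 3, 2, 4]) == pytest.approx(0.8)

    def test_zero_variance_undefined(self):
        with pytest.raises(UndefinedMetricError):
            pearson([1, 1, 1], [1, 2, 3])


class TestIcc:
    def test_perfect_agreement(self):
        t = table([[10, 10], [30, 30], [50, 50]])
        assert icc(t) == pytest.approx(1.0)

    def test_constant_offset_penalized_under_absolute_agreement(self):
        base = np.array([10.0, 25.0, 40.0, 55.0, 60.0])
        t = table(np.column_stack([base, base + 10.0]))
        # independent mean-squares oracle
        v = t.values
        n, m = v.shape
        grand = v.mean()
        msr = m * ((v.mean(axis=1) - grand) ** 2).sum() / (n - 1)
        msc = n * ((v.mean(axis=0) - grand) ** 2).sum() / (m - 1)
        resid = v - v.mean(axis=1, keepdims=True) - v.mean(axis=0, keepdims=True) + grand
        mse = (resid**2).sum() / ((n - 1) * (m - 1))
        expected = (msr - mse) / (msr + (m - 1) * mse + m * (msc - mse) / n)
        assert icc(t, "2,1") == pytest.approx(expected)
        assert icc(t, "2,1") < 1.0
        # consistency variant forgives the offset entirely
        assert icc(t, "3,1") == pytest.approx(1.0)

    def test_variance_ratio_recovery(self):
        rng = np.random.default_rng(1)
        case = rng.normal(100.0, 10.0, 400)
        noise = rng.normal(0.0, 5.0, (400, 5))
        t = table(case[:, None] + noise)
        expected = 100.0 / (100.0 + 25.0)  # sigma2_case / (sigma2_case + sigma2_noise)
        assert icc(t, "2,1") == pytest.approx(expected, abs=0.05)

    def test_matches_pingouin(self):
        import pandas as pd
        import pingouin as pg

        rng = np.random.default_rng(7)
        v = rng.normal(60, 8, (12, 4)) + rng.normal(0, 2, (1, 4))
        t = table(v)
        long = pd.DataFrame(
            {
                "case": np.repeat(np.arange(12), 4),
                "rater": np.tile(np.arange(4), 12),
                "y": v.ravel(),
            }
        )
        ref = pg.intraclass_corr(long, targets="case", raters="rater", ratings="y")
        ref = ref.set_index("Type")["ICC"]
        assert icc(t, "2,1") == pytest.approx(ref["ICC(A,1)"], abs=1e-9)
        assert icc(t, "2,k") == pytest.approx(ref["ICC(A,k)"], abs=1e-9)
        assert icc(t, "3,1") == pytest.approx(ref["ICC(C,1)"], abs=1e-9)

    def test_common_shift_invariance_directions(self):
        rng = np.random.default_rng(3)
        case_effect = rng.normal(40.0, 10.0, 20)
        v = case_effect[:, None] + rng.normal(0, 3, (20, 4))
        t = table(v)
        shifted = table(v + 5.0)  # same constant added to every entry
        assert icc(shifted, "2,1") == pytest.approx(icc(t, "2,1"), abs=1e-9)
        # but a per-rater offset lowers the absolute-agreement form only
        offset = table(v + np.array([0.0, 4.0, -4.0, 8.0]))
        assert icc(offset, "2,1") < icc(t, "2,1")
        assert icc(offset, "3,1") == pytest.approx(icc(t, "3,1"), abs=1e-6)

    def test_degenerate_table_undefined(self):
        with pytest.raises(UndefinedMetricError):
            icc(table([[5, 5], [5, 5]]))


class TestCohenKappa:
    def test_perfect_agreement(self):
        assert cohen_kappa([0, 1, 2, 3, 4, 0], [0, 1, 2, 3, 4, 0]) == pytest.approx(1.0)

    def test_crossing_pattern_scores_zero(self):
        # observed agreement 0.5 equals chance agreement 0.5
        assert cohen_kappa([0, 0, 1, 1], [0, 1, 0, 1]) == pytest.approx(0.0)

    def test_independent_labels_near_zero(self):
        rng = np.random.default_rng(11)
        a = rng.integers(0, 5, 10_000)
        b = rng.integers(0, 5, 10_000)
        assert abs(cohen_kappa(a, b)) < 0.05

    def test_constant_equal_raters_undefined(self):
        with pytest.raises(UndefinedMetricError):
            cohen_kappa([2, 2, 2], [2, 2, 2])

    def test_quadratic_weighting_forgives_near_misses_more(self):
        a = [0, 1, 2, 3, 4, 0, 1, 2]
        b = [1, 2, 3, 4, 3, 1, 0, 1]  # all misses are near misses
        assert cohen_kappa(a, b, "quadratic") > cohen_kappa(a, b, "unweighted")

    def test_labels_outside_scale_rejected(self):
        with pytest.raises(PreconditionError):
            cohen_kappa([0, 5], [0, 1])


class TestClassificationMetrics:
    def test_identity_prediction(self):
        out = classification_metrics([0, 1, 2, 3, 4], [0, 1, 2, 3, 4])
        assert all(v == 1.0 for v in out.values())

    def test_hand_example_accuracy_and_detection_f1(self):
        out = classification_metrics([0, 0, 2, 2], [0, 2, 2, 2])
        assert out["accuracy"] == pytest.approx(0.75)
        assert out["f1_scoliosis_detect"] == pytest.approx(4 / 5)

    def test_constant_prediction_balanced_accuracy(self):
        out = classification_metrics([0, 0, 1, 2, 2, 3], [2, 2, 2, 2, 2, 2])
        assert out["balanced_accuracy"] == pytest.approx(1 / 4)

    def test_detection_mapping_consistent_with_severity_thresholds(self):
        from spinecobb import severity

        for angle in (0.0, 9.0, 10.0, 24.9, 25.0, 44.0, 60.0, 80.0):
            level = severity(angle).level
            assert (level >= 2) == (angle >= 25.0)


class TestQuantileAndBootstrap:
    def test_abs_dev_quantile_hand_value(self):
        dl = [10.0, 11.0, 12.0, 13.0, 14.0]
        ref = [10.0, 10.0, 10.0, 10.0, 10.0]
        assert abs_dev_quantile(dl, ref, q=0.5) == pytest.approx(2.0)

    def test_bootstrap_ci_brackets_the_mean_and_is_seeded(self):
        rng = np.random.default_rng(5)
        x = rng.normal(4.0, 1.0, 100)
        lo, hi = bootstrap_ci(np.mean, x, n_boot=2000, seed=9)
        assert lo < x.mean() < hi
        assert (lo, hi) == bootstrap_ci(np.mean, x, n_boot=2000, seed=9)


class TestCalibrateTolerance:
    @staticmethod
    def _cases(n=4, seed=0):
        from spinecobb import extract_centerline, find_breakpoints, fit_curve, normalize_length
        from spinecobb import rasterize, spec_for_angle

        cases = []
        for i, target in enumerate(np.linspace(20, 55, n)):
            spec = spec_for_angle(float(target), family="s_curve", seed=seed + i)
            _, mask = rasterize(spec)
            cl = normalize_length(extract_centerline(mask))
            curve = fit_curve(cl)
            cases.append((curve, find_breakpoints(curve)))
        return cases

    def test_single_candidate_grid(self):
        cases = self._cases(2)
        out = calibrate_tolerance(cases, [30.0, 40.0], grid=[0.15])
        assert out.best_tolerance == 0.15

    def test_self_consistent_panel_recovers_default(self):
        from spinecobb.agreement import main_angle_at_tolerance

        cases = self._cases(4)
        avgs = [main_angle_at_tolerance(c, b, 0.15) for c, b in cases]
        out = calibrate_tolerance(cases, avgs, grid=[0.05, 0.10, 0.15, 0.20, 0.25, 0.30])
        assert out.best_tolerance == 0.15
        assert out.objective == 0.0

    def test_objective_trace_is_auditable(self):
        cases = self._cases(2)
        out = calibrate_tolerance(cases, [25.0, 45.0], grid=[0.1, 0.2])
        # the returned objective equals an independent recomputation at best Lt
        from spinecobb.agreement import main_angle_at_tolerance

        dk = [main_angle_at_tolerance(c, b, out.best_tolerance) for c, b in cases]
        assert out.objective == pytest.approx(sum(abs(d - r) for d, r in zip(dk, [25.0, 45.0])))
        assert set(out.trace) == {0.1, 0.2}

    def test_tie_goes_to_smallest_tolerance(self):
        # exactly linear curve: theta is window-independent, so every
        # tolerance yields an identical (zero) objective
        from spinecobb import FittedCurve, find_breakpoints

        dom = [0.0, 571.0]
        poly = np.polynomial.Polynomial([5.0, 0.3], domain=dom, window=dom)
        curve = FittedCurve(poly=poly, domain=(0.0, 571.0), degree=1)
        cases = [(curve, find_breakpoints(curve))]
        out = calibrate_tolerance(cases, [0.0], grid=[0.30, 0.10, 0.20])
        assert out.best_tolerance == 0.10

    def test_empty_grid_rejected(self):
        with pytest.raises(ParameterError):
            calibrate_tolerance([], [], grid=[])


class TestReaderTableIO:
    def test_csv_roundtrip(self, tmp_path):
        t = table([[10.5, 12.0], [30.0, 28.5]])
        p = tmp_path / "readers.csv"
        t.to_csv(p)
        back = ReaderTable.from_csv(p)
        np.testing.assert_allclose(back.values, t.values)
        assert back.rater_ids == t.rater_ids

    def test_missing_cells_rejected(self, tmp_path):
        p = tmp_path / "readers.csv"
        p.write_text("case_id,r0,r1\nc0,10,\nc1,20,21\n")
        with pytest.raises(PreconditionError):
            ReaderTable.from_csv(p)

    def test_negative_angles_rejected(self):
        with pytest.raises(PreconditionError):
            table([[10, -2]])

    def test_single_rater_rejected(self):
        with pytest.raises(PreconditionError):
            ReaderTable(values=np.array([[1.0]]), case_ids=("c0",), rater_ids=("r0",))


class TestSimulatedPanelStatistics:
    def test_noise_free_panel_gives_perfect_agreement(self):
        truths = np.linspace(5, 70, 30)
        panel = make_reader_panel(truths, m=5, bias_sd=0.0, noise_sd=0.0, seed=0)
        assert icc(panel) == pytest.approx(1.0)
        assert pairwise_reader_diff(panel) == 0.0
        d_mean, d_median = deviation_stats(panel, truths)
        assert d_mean == pytest.approx(0.0, abs=1e-12)  # one ulp from the column mean
        assert d_median == 0.0

    def test_pairwise_diff_matches_half_normal_closed_form(self):
        # |x - y| for independent N(0, s^2) readings has mean 2*s/sqrt(pi)
        truths = np.linspace(10, 60, 200)
        panel = make_reader_panel(truths, m=7, bias_sd=0.0, noise_sd=3.0, seed=42)
        expected = 2 * 3.0 / np.sqrt(np.pi)
        assert pairwise_reader_diff(panel) == pytest.approx(expected, rel=0.15)
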