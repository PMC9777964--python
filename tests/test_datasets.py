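"""Schemas, cohort I/O, cohort statistics, and the synthetic generators."""

import numpy as np
import pandas as pd
import pytest

from hpakit.datasets import (
    BasalSeries,
    Cohort,
    HormoneSeries,
    SubjectRecord,
    cohort_mean,
    load_cohort,
    load_results,
    save_cohort,
    save_results,
    synth_basal_series,
    synth_tsst_cohort,
    tsst_time_grid,
)
from hpakit.optimize import OptimizationRun


class TestGrid:
    def test_tsst_grid_is_the_11_point_schedule(self):
        grid = tsst_time_grid()
        np.testing.assert_array_equal(
            grid, [-30, -15, 0, 10, 20, 35, 50, 65, 80, 95, 110]
        )

    def test_post_test_spacing_is_15_min(self):
        grid = tsst_time_grid()
        post = grid[grid >= 20]
        np.testing.assert_array_equal(np.diff(post), 15.0)

    def test_strictly_increasing(self):
        assert np.all(np.diff(tsst_time_grid()) > 0)


class TestContainers:
    def test_series_validation(self):
        with pytest.raises(ValueError, match="increasing"):
            HormoneSeries("cortisol", [0.0, 0.0], [1.0, 2.0])
        with pytest.raises(ValueError, match=">= 0"):
            HormoneSeries("cortisol", [0.0, 1.0], [1.0, -2.0])
        with pytest.raises(ValueError, match="finite"):
            HormoneSeries("cortisol", [0.0, 1.0], [1.0, np.nan])

    def test_subject_requires_shared_grid(self):
        c = HormoneSeries("cortisol", [0.0, 1.0], [1.0, 2.0])
        a = HormoneSeries("acth", [0.0, 2.0], [1.0, 2.0])
        with pytest.raises(ValueError, match="share"):
            SubjectRecord("s", "control", cortisol=c, acth=a)

    def test_cohort_unique_ids_and_shared_grid(self):
        c = HormoneSeries("cortisol", [0.0, 1.0], [1.0, 2.0])
        s = SubjectRecord("s", "control", cortisol=c)
        with pytest.raises(ValueError, match="unique"):
            Cohort(subjects=(s, s))


class TestLoadCohort(object):
    def _write(self, path, rows):
        pd.DataFrame(
            rows, columns=["subject_id", "group", "time_min", "acth", "cortisol"]
        ).to_csv(path, index=False)

    def _complete_rows(self, sid, shift=0.0):
        return [
            (sid, "control", t, 20.0 + shift, 10.0 + shift)
            for t in tsst_time_grid()
        ]

    def test_two_complete_subjects(self, tmp_path):
        p = tmp_path / "c.csv"
        self._write(p, self._complete_rows("s1") + self._complete_rows("s2", 1.0))
        cohort = load_cohort(p, schema="tsst")
        assert len(cohort) == 2
        assert cohort.reference_event == (0.0, 20.0)

    def test_missing_point_excludes_subject(self, tmp_path):
        p = tmp_path / "c.csv"
        incomplete = [r for r in self._complete_rows("s2") if r[2] != 35.0]
        self._write(p, self._complete_rows("s1") + incomplete)
        cohort = load_cohort(p, schema="tsst")
        assert cohort.ids == ["s1"]
        assert cohort.exclusions[0][0] == "s2"

    def test_empty_file_rejected(self, tmp_path):
        p = tmp_path / "c.csv"
        p.write_text("subject_id,group,time_min,acth,cortisol\n")
        with pytest.raises(ValueError, match="empty"):
            load_cohort(p)

    def test_non_numeric_cell_reports_row(self, tmp_path):
        p = tmp_path / "c.csv"
        rows = self._complete_rows("s1")
        rows[3] = ("s1", "control", rows[3][2], "oops", 10.0)
        self._write(p, rows)
        with pytest.raises(ValueError, match="row 5"):
            load_cohort(p)

    def test_basal_schema_cortisol_only(self, tmp_path):
        p = tmp_path / "b.csv"
        rows = [("s1", "control", t, "", 10.0 + t / 100) for t in range(0, 100, 10)]
        self._write(p, rows)
        cohort = load_cohort(p, schema="basal")
        assert cohort.subjects[0].acth is None

    def test_round_trip_through_save_cohort(self, tmp_path):
        cohort = synth_tsst_cohort(5, seed=3)
        p = save_cohort(cohort, tmp_path / "c.csv")
        back = load_cohort(p, schema="tsst")
        assert back.ids == cohort.ids
        for a, b in zip(cohort.subjects, back.subjects):
            np.testing.assert_array_equal(a.cortisol.values, b.cortisol.values)
            np.testing.assert_array_equal(a.acth.values, b.acth.values)


class TestCohortMean:
    def _subject(self, sid, a, c):
        t = np.array([0.0, 1.0])
        return SubjectRecord(
            sid, "control",
            acth=HormoneSeries("acth", t, a),
            cortisol=HormoneSeries("cortisol", t, c),
        )

    def test_single_subject_mean_is_itself(self):
        s = self._subject("s", [2.0, 3.0], [4.0, 5.0])
        stats = cohort_mean(Cohort(subjects=(s,)))
        np.testing.assert_array_equal(stats.mean.cortisol.values, [4.0, 5.0])
        np.testing.assert_array_equal(stats.cortisol_sd, [0.0, 0.0])

    def test_two_subject_hand_computation(self):
        """cortisol 4 and 6 at a point: mean 5, sample SD sqrt(2)."""
        s1 = self._subject("a", [1.0, 1.0], [4.0, 4.0])
        s2 = self._subject("b", [3.0, 3.0], [6.0, 6.0])
        stats = cohort_mean(Cohort(subjects=(s1, s2)))
        assert stats.mean.cortisol.values[0] == pytest.approx(5.0)
        assert stats.cortisol_sd[0] == pytest.approx(np.sqrt(2.0))

    def test_reorder_invariance(self):
        s1 = self._subject("a", [1.0, 2.0], [4.0, 8.0])
        s2 = self._subject("b", [3.0, 5.0], [6.0, 1.0])
        m1 = cohort_mean(Cohort(subjects=(s1, s2)))
        m2 = cohort_mean(Cohort(subjects=(s2, s1)))
        np.testing.assert_allclose(
            m1.mean.cortisol.values, m2.mean.cortisol.values
        )

    def test_against_streaming_welford_oracle(self):
        cohort = synth_tsst_cohort(23, seed=9)
        stats = cohort_mean(cohort)
        # independent streaming recomputation (Welford)
        n = 0
        mean = np.zeros(11)
        m2 = np.zeros(11)
        for s in cohort.subjects:
            n += 1
            delta = s.cortisol.values - mean
            mean += delta / n
            m2 += delta * (s.cortisol.values - mean)
        np.testing.assert_allclose(stats.mean.cortisol.values, mean, atol=1e-12)
        np.testing.assert_allclose(
            stats.cortisol_sd, np.sqrt(m2 / (n - 1)), atol=1e-12
        )

    def test_empty_cohort_rejected(self):
        with pytest.raises(ValueError, match="empty"):
            cohort_mean(Cohort(subjects=()))


class TestSynthTsst:
    def test_seeded_determinism(self):
        a = synth_tsst_cohort(10, anomaly_fraction=0.2, seed=5)
        b = synth_tsst_cohort(10, anomaly_fraction=0.2, seed=5)
        for s, t in zip(a.subjects, b.subjects):
            np.testing.assert_array_equal(s.cortisol.values, t.cortisol.values)
            np.testing.assert_array_equal(s.acth.values, t.acth.values)
            assert s.group == t.group

    def test_cohort_mean_shape(self):
        """Mean cortisol peaks in-test/shortly after; final near baseline."""
        cohort = synth_tsst_cohort(50, anomaly_fraction=0.0, seed=1)
        grid = tsst_time_grid()
        mean_c = cohort_mean(cohort).mean.cortisol.values
        t_peak = grid[np.argmax(mean_c)]
        assert 10.0 <= t_peak <= 50.0
        pre = mean_c[grid < 0].mean()
        assert abs(mean_c[-1] - pre) / pre < 0.25

    def test_anomalous_subject_shape(self):
        cohort = synth_tsst_cohort(1, anomaly_fraction=1.0, seed=2)
        s = cohort.subjects[0]
        assert np.all(np.diff(s.acth.values) < 0)
        grid = tsst_time_grid()
        assert grid[np.argmax(s.cortisol.values)] == 50.0

    def test_shape_property_holds_for_most_subjects(self):
        """>= 95% of non-anomalous subjects rise in-test and return after."""
        cohort = synth_tsst_cohort(100, anomaly_fraction=0.0, seed=4)
        grid = tsst_time_grid()
        good = 0
        for s in cohort.subjects:
            c = s.cortisol.values
            pre = c[grid < 0].mean()
            peak = c[(grid >= 10) & (grid <= 50)].max()
            rises = peak > 1.25 * pre
            # returned: the excursion has decayed at least half-way back, or
            # the final point sits within assay noise of the pre-test level
            returns = (c[-1] - pre) < 0.5 * (peak - pre) or abs(c[-1] - pre) < 0.4 * pre
            flat_pre = abs(c[grid < 0].max() - c[grid < 0].min()) < 0.8 * pre
            good += rises and returns and flat_pre
        assert good >= 95

    def test_group_mix_counts(self):
        cohort = synth_tsst_cohort(
            58, group_mix={"control": 15, "MDD-melancholic": 43}, seed=0
        )
        groups = [s.group for s in cohort.subjects]
        assert groups.count("control") == 15
        assert groups.count("MDD-melancholic") == 43

    def test_values_nonnegative_finite(self):
        cohort = synth_tsst_cohort(30, anomaly_fraction=0.3, seed=6)
        for s in cohort.subjects:
            assert np.all(np.isfinite(s.cortisol.values))
            assert np.all(s.cortisol.values >= 0)
            assert np.all(s.acth.values >= 0)

    def test_invalid_arguments(self):
        with pytest.raises(ValueError):
            synth_tsst_cohort(0, seed=0)
        with pytest.raises(ValueError):
            synth_tsst_cohort(5, anomaly_fraction=1.5, seed=0)


class TestSynthBasal:
    def test_pulse_count_in_documented_range(self):
        basal = synth_basal_series(seed=8)
        c = basal.cortisol.values
        # count interior local maxima of the pulsatile series
        peaks = np.sum((c[1:-1] > c[:-2]) & (c[1:-1] >= c[2:]))
        assert 11 <= peaks <= 19

    def test_envelope_peaks_at_8am(self):
        basal = synth_basal_series(seed=8)
        t = basal.cortisol.times
        env = np.array([basal.envelope(x) for x in t])
        assert abs(t[np.argmax(env)] - 480.0) <= 30.0

    def test_flat_envelope_no_pulses_constant(self):
        from hpakit.models import CircadianDrive

        basal = synth_basal_series(
            circadian_params=CircadianDrive(mesor=1.0, amplitude=0.0),
            n_pulses=0,
            seed=0,
        )
        assert np.ptp(basal.cortisol.values) == pytest.approx(0.0)

    def test_ten_minute_sampling_and_nonnegativity(self):
        basal = synth_basal_series(seed=3)
        np.testing.assert_allclose(np.diff(basal.cortisol.times), 10.0)
        assert np.all(basal.cortisol.values >= 0)
        assert np.all(basal.acth.values >= 0)

    def test_seeded_determinism(self):
        a = synth_basal_series(seed=12)
        b = synth_basal_series(seed=12)
        np.testing.assert_array_equal(a.cortisol.values, b.cortisol.values)


class TestSaveResults:
    def _runs(self):
        return [
            OptimizationRun(
                run_id=f"r{i}", algorithm="de/rand/1/bin", seed=i, popsize=10,
                generations=5,
                best_params={"k_c": 0.1 * (i + 1), "K_i": 8.0, "w_f": 0.03},
                best_cost=0.5 / (i + 1), trace=np.array([1.0, 0.5 / (i + 1)]),
            )
            for i in range(5)
        ]

    def test_parameter_table_shape(self, tmp_path):
        runs = self._runs()
        sols = {
            r.run_id: pd.DataFrame({"time_min": [0.0, 1.0], "cortisol": [1.0, 2.0]})
            for r in runs
        }
        save_results(runs, sols, tmp_path / "res")
        params, solutions = load_results(tmp_path / "res")
        assert len(params) == 5
        assert params.shape[1] >= 6  # metadata + 3 parameter columns
        assert {"param:k_c", "param:K_i", "param:w_f"} <= set(params.columns)
        assert set(solutions["run_id"]) == {r.run_id for r in runs}

    def test_csv_mirror_round_trips_exactly(self, tmp_path):
        runs = self._runs()
        save_results(runs, {}, tmp_path / "res")
        params, _ = load_results(tmp_path / "res")
        for i, r in enumerate(runs):
            assert params.loc[i, "best_cost"] == r.best_cost
            assert params.loc[i, "param:k_c"] == r.best_params["k_c"]

    def test_empty_runs_rejected(self, tmp_path):
        with pytest.raises(ValueError, match="no runs"):
            save_results([], {}, tmp_path / "res")

    def test_workbook_written(self, tmp_path):
        save_results(self._runs(), {}, tmp_path / "res")
        assert (tmp_path / "res.xlsx").exists()
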