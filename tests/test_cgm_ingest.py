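import datetime

import numpy as np
import pandas as pd
import pytest

from conftest import make_grid
from glucoupler.cgm_ingest import (
    CGMFileError,
    PROV_INTERPOLATED,
    PROV_MISSING,
    PROV_OBSERVED,
    PROV_REPLACED,
    accounting,
    build_day_grids,
    clean_day,
    interpolate_gaps,
    is_valid_glucose_day,
    largest_consecutive_block,
    read_cgm_file,
    replace_from_user_scans,
)
from glucoupler.synthetic_data import SimulationConfig, generate_cohort, inject_missingness


def _user(times_values):
    return pd.DataFrame(
        {
            "participant_id": "P001",
            "timestamp": pd.to_datetime([t for t, _ in times_values]),
            "record_type": 1,
            "glucose_mmol_l": [v for _, v in times_values],
        }
    )


class TestReadCgmFile:
    def _write(self, path, rows):
        path.write_text(
            "participant_id,timestamp,record_type,glucose_mmol_l\n" + "\n".join(rows) + "\n"
        )

    def test_counts_preserved_by_source(self, tmp_path):
        rows = [
            f"P001,2016-06-07 {h:02d}:{m:02d},0,5.5"
            for h in range(24)
            for m in (0, 15, 30, 45)
        ] + [f"P001,2016-06-07 10:0{i},1,5.{i}" for i in range(4)]
        f = tmp_path / "cgm.csv"
        self._write(f, rows)
        out = read_cgm_file(f)
        assert len(out) == 100
        assert (out["record_type"] == 0).sum() == 96

    def test_empty_file_gives_empty_frame(self, tmp_path):
        f = tmp_path / "cgm.csv"
        self._write(f, [])
        assert read_cgm_file(f).empty

    def test_nonpositive_glucose_rejected_with_line(self, tmp_path):
        f = tmp_path / "cgm.csv"
        self._write(f, ["P001,2016-06-07 10:00,0,5.0", "P001,2016-06-07 10:15,0,-1.0"])
        with pytest.raises(CGMFileError, match="line 3"):
            read_cgm_file(f)

    def test_unknown_record_type_rejected(self, tmp_path):
        f = tmp_path / "cgm.csv"
        self._write(f, ["P001,2016-06-07 10:00,7,5.0"])
        with pytest.raises(CGMFileError, match="record type"):
            read_cgm_file(f)


class TestBuildDayGrids:
    def _auto(self, start, end, step=15, pid="P001"):
        ts = pd.date_range(start, end, freq=f"{step}min")
        return pd.DataFrame(
            {
                "participant_id": pid,
                "timestamp": ts,
                "record_type": 0,
                "glucose_mmol_l": 5.0,
            }
        )

    def test_fifteen_calendar_days_give_thirteen_complete(self):
        readings = self._auto("2016-06-06 10:07", "2016-06-20 09:52")
        grids = build_day_grids(readings)
        assert len(grids) == 13
        assert all(g.n_slots == 96 for g in grids)
        assert all(not g.partial for g in grids)

    def test_single_day_of_data_yields_no_complete_days(self):
        readings = self._auto("2016-06-07 08:00", "2016-06-07 20:00")
        assert build_day_grids(readings) == []

    def test_missing_slots_reconstructed_between_observations(self):
        readings = self._auto("2016-06-06 10:00", "2016-06-08 10:00")
        readings = readings[
            ~readings["timestamp"].between("2016-06-07 12:00", "2016-06-07 13:59")
        ]
        grids = build_day_grids(readings)
        (g,) = grids
        assert g.n_slots == 96
        assert int((g.provenance == PROV_MISSING).sum()) == 8

    def test_phase_drift_preserved_not_forced_to_96(self):
        cfg = SimulationConfig(
            n_participants=3,
            n_days=6,
            seed=21,
            p_scan_gap_per_night=1.0,
            p_phase_drift=1.0,
            p_point_dropout=0.0,
        )
        cohort = generate_cohort(cfg)
        rng = np.random.default_rng(21)
        cgm, book = inject_missingness(cohort.cgm, cfg, rng)
        grids = build_day_grids(cgm)
        sizes = {g.n_slots for g in grids}
        assert sizes - {95, 96, 97} == set()
        assert sizes != {96}  # drift visibly shifts day sizes


class TestReplacement:
    def test_user_scan_within_window_fills_slot(self):
        grid = make_grid([5.0, None, 5.0], start_minute=9 * 60 + 45)  # missing at 10:00
        out = replace_from_user_scans(grid, _user([("2016-06-07 10:02", 5.4)]))
        assert out.values[1] == 5.4
        assert out.provenance[1] == PROV_REPLACED

    def test_user_scan_outside_window_ignored(self):
        grid = make_grid([5.0, None, 5.0], start_minute=9 * 60 + 45)
        out = replace_from_user_scans(grid, _user([("2016-06-07 10:04", 5.4)]))
        assert np.isnan(out.values[1])

    def test_equal_distance_tie_goes_to_earlier_scan(self):
        grid = make_grid([5.0, None, 5.0], start_minute=9 * 60 + 45)
        out = replace_from_user_scans(
            grid, _user([("2016-06-07 09:58", 5.2), ("2016-06-07 10:02", 5.6)])
        )
        assert out.values[1] == 5.2

    def test_observed_slots_never_touched(self):
        grid = make_grid([5.0, 6.0, 7.0])
        out = replace_from_user_scans(grid, _user([("2016-06-07 00:16", 9.9)]))
        np.testing.assert_array_equal(out.values, [5.0, 6.0, 7.0])


class TestInterpolation:
    def test_two_point_gap_filled_linearly(self):
        grid = make_grid([5.0, None, None, 6.5])
        out = interpolate_gaps(grid)
        np.testing.assert_allclose(out.values, [5.0, 5.5, 6.0, 6.5])
        assert (out.provenance[1:3] == PROV_INTERPOLATED).all()

    def test_three_point_gap_stays_missing(self):
        grid = make_grid([5.0, None, None, None, 6.5])
        out = interpolate_gaps(grid)
        assert np.isnan(out.values[1:4]).all()

    def test_gap_at_day_boundary_stays_missing(self):
        grid = make_grid([None, 5.0, 5.0])
        out = interpolate_gaps(grid)
        assert np.isnan(out.values[0])

    def test_replaced_slot_counts_as_flank_by_default(self):
        grid = make_grid([None, None, 6.0], start_minute=9 * 60 + 45)
        step1 = replace_from_user_scans(grid, _user([("2016-06-07 09:46", 5.0)]))
        out = interpolate_gaps(step1)
        assert out.values[1] == pytest.approx(5.5)
        out2 = interpolate_gaps(step1, bridge_replaced=False)
        assert np.isnan(out2.values[1])


class TestBlocksAndValidity:
    def test_full_day_single_block(self):
        grid = make_grid([5.0] * 96)
        assert largest_consecutive_block(grid) == slice(0, 96)
        assert is_valid_glucose_day(grid)

    def test_max_of_two_runs(self):
        grid = make_grid([5.0] * 50 + [None] * 3 + [5.0] * 40)
        b = largest_consecutive_block(grid)
        assert (b.start, b.stop) == (0, 50)

    def test_equal_runs_tie_to_earlier(self):
        grid = make_grid([5.0] * 40 + [None] + [6.0] * 40)
        b = largest_consecutive_block(grid)
        assert (b.start, b.stop) == (0, 40)

    @pytest.mark.parametrize("n, valid", [(86, True), (85, False), (96, True)])
    def test_consecutive_threshold_boundary(self, n, valid):
        grid = make_grid([5.0] * n + [None] * (96 - n))
        assert is_valid_glucose_day(grid) is valid

    def test_adding_a_filled_slot_never_invalidates(self):
        rng = np.random.default_rng(1)
        for _ in range(50):
            vals = [5.0 if rng.random() < 0.9 else None for _ in range(96)]
            grid = make_grid(vals)
            before = is_valid_glucose_day(grid)
            missing = np.flatnonzero(np.isnan(grid.values))
            if missing.size == 0:
                continue
            grid.values[rng.choice(missing)] = 5.0
            assert is_valid_glucose_day(grid) >= before


class TestCleaningPipelineProperties:
    def test_cleaning_is_idempotent(self):
        rng = np.random.default_rng(8)
        user = _user([("2016-06-07 03:01", 6.1), ("2016-06-07 11:59", 4.9)])
        for _ in range(20):
            vals = [round(rng.uniform(4, 8), 1) if rng.random() < 0.85 else None for _ in range(96)]
            once = clean_day(make_grid(vals), user)
            twice = clean_day(once, user)
            np.testing.assert_array_equal(
                np.nan_to_num(once.values, nan=-1), np.nan_to_num(twice.values, nan=-1)
            )
            np.testing.assert_array_equal(once.provenance, twice.provenance)

    def test_observed_values_conserved(self):
        rng = np.random.default_rng(9)
        vals = [round(rng.uniform(4, 8), 1) if rng.random() < 0.8 else None for _ in range(96)]
        grid = make_grid(vals)
        user = _user([("2016-06-07 05:02", 9.9)])
        cleaned = clean_day(grid, user)
        obs = grid.provenance == PROV_OBSERVED
        np.testing.assert_array_equal(cleaned.values[obs], grid.values[obs])
        assert (cleaned.provenance[obs] == PROV_OBSERVED).all()


class TestAccounting:
    def test_zero_missingness_cohort(self, tiny_cohort):
        grids = [clean_day(g) for g in build_day_grids(tiny_cohort.cgm)]
        report = accounting(grids)
        total = report[report["participant_id"] == "TOTAL"].iloc[0]
        assert total["replaced"] == 0
        assert total["interpolated"] == 0
        assert total["missing"] == 0
        assert total["observed"] == total["total_slots"]

    def test_bookkeeping_identity_single_day(self):
        vals = [5.0] * 40 + [None] + [5.0] * 20 + [None, None] + [5.0] * 33
        grid = make_grid(vals)
        user = _user([("2016-06-07 10:01", 5.5)])  # covers the slot at 10:00
        cleaned = clean_day(grid, user)
        report = accounting([cleaned])
        row = report.iloc[0]
        assert row["replaced"] == 1
        assert row["interpolated"] == 2
        assert row["observed"] + row["replaced"] + row["interpolated"] + row["missing"] == 96

    def test_totals_match_injected_counts_without_drift(self):
        cfg = SimulationConfig(
            n_participants=6, n_days=8, seed=33, p_phase_drift=0.0, user_scans_per_day=0.0
        )
        cohort = generate_cohort(cfg)
        rng = np.random.default_rng(33)
        cgm, book = inject_missingness(cohort.cgm, cfg, rng)
        grids = [clean_day(g) for g in build_day_grids(cgm, include_partial=True)]
        report = accounting(grids)
        total = report[report["participant_id"] == "TOTAL"].iloc[0]
        injected = int(book["gap_deleted"].sum() + book["dropout_deleted"].sum())
        recovered = int(total["replaced"] + total["interpolated"] + total["missing"])
        assert recovered == injected
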