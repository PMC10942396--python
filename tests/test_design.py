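"""Aperture geometry, trial-schedule statistics, and design-matrix structure."""

import numpy as np
import pytest
from scipy import stats

from anticiprf import design
from anticiprf.design import (
    BLANK_INDEX,
    CONDITIONS,
    InvalidConfigurationError,
    build_bar_apertures,
    build_balanced_schedule,
    build_design_matrix,
    build_trial_schedule,
    mapping_column,
    target_column,
)


class TestApertures:
    def test_counts_orientations_and_blank(self, apertures128):
        ap = apertures128
        assert ap.apertures.shape == (49, 128, 128)
        assert ap.orientations.count("vertical") == 24
        assert ap.orientations.count("horizontal") == 24
        assert ap.apertures[BLANK_INDEX].sum() == 0

    def test_lit_pixels_inside_circular_window(self, apertures128):
        X, Y = apertures128.pixel_coords()
        r2 = X**2 + Y**2
        for mask in apertures128.apertures:
            assert np.all(r2[mask.astype(bool)] <= apertures128.grid_extent**2)

    def test_adjacent_bars_share_two_degree_band(self):
        # brute-force pixel counting at fine resolution: shared lit columns
        # of two adjacent vertical bars span 2 degrees
        ap = build_bar_apertures(3, 1, 12.4, 512)
        a, b = ap.apertures[11].astype(bool), ap.apertures[12].astype(bool)
        shared_cols = np.any(a & b, axis=0)
        pitch = 2 * ap.grid_extent / ap.grid_resolution
        width = shared_cols.sum() * pitch
        assert width == pytest.approx(2.0, abs=2 * pitch)

    def test_union_covers_window_in_both_orientations(self, apertures128):
        ap = apertures128
        X, Y = ap.pixel_coords()
        inside = X**2 + Y**2 <= ap.grid_extent**2
        vert = np.any(ap.apertures[:24].astype(bool), axis=0)
        horz = np.any(ap.apertures[24:48].astype(bool), axis=0)
        assert np.all(vert[inside])
        assert np.all(horz[inside])

    def test_bar_offsets_symmetric_one_degree_steps(self, apertures128):
        offsets = apertures128.bar_offsets[:24]
        assert np.allclose(np.diff(offsets), 1.0)
        assert np.allclose(offsets, -offsets[::-1])

    @pytest.mark.parametrize("kwargs", [
        {"width_deg": -1}, {"step_deg": 0}, {"window_radius_deg": -2},
        {"resolution": 16},
    ])
    def test_invalid_geometry_rejected(self, kwargs):
        with pytest.raises(InvalidConfigurationError):
            build_bar_apertures(**kwargs)


class TestTrialSchedule:
    def test_focal_distributed_split_matches_binomial(self):
        sched = build_trial_schedule(520, seed=3)
        n_focal = sum(t.cue != "distributed" for t in sched)
        # expectation 416, sd ~9.1; allow 4 sd
        assert abs(n_focal - 416) < 4 * np.sqrt(520 * 0.8 * 0.2)

    def test_expected_valid_count_over_seeds(self):
        # closed-form expectation: 520 * 0.8 * 0.75 = 312 valid trials
        counts = [
            sum(t.validity == "valid" for t in build_trial_schedule(520, seed=s))
            for s in range(30)
        ]
        se = np.sqrt(520 * 0.6 * 0.4 / 30)
        assert np.mean(counts) == pytest.approx(312, abs=4 * se)

    def test_trials_are_tr_aligned_and_consistent(self):
        for t in build_trial_schedule(200, seed=1):
            assert t.duration_tr in (4, 5)
            assert t.duration_tr == t.bar_duration_s + 3
            assert (t.validity == "neutral") == (t.cue == "distributed")
            if t.validity == "valid":
                assert t.response_cue_location == t.cue
            if t.validity == "invalid":
                assert t.response_cue_location != t.cue
            assert t.onset_tr <= t.target_tr < t.onset_tr + t.duration_tr

    def test_isi_family_matches_configured_proportions(self):
        sched = build_trial_schedule(8000, seed=9)
        counts = {isi: sum(t.isi_ms == isi for t in sched) for isi in (50, 300, 400, 500)}
        expected = np.array([0.1, 0.3, 0.3, 0.3]) * 8000
        chi2 = stats.chisquare(list(counts.values()), expected)
        assert chi2.pvalue > 0.01

    def test_reproducible_under_seed(self):
        a = build_trial_schedule(50, seed=11)
        b = build_trial_schedule(50, seed=11)
        assert a == b

    def test_bad_proportions_rejected(self):
        with pytest.raises(InvalidConfigurationError):
            build_trial_schedule(10, seed=0, proportions={"cue": {"focal": 0.5, "distributed": 0.2}})

    def test_balanced_schedule_covers_every_cell(self):
        sched = build_balanced_schedule(repeats=1, seed=0)
        cells = {(t.cue, t.bar_index) for t in sched}
        assert len(sched) == 245
        assert len(cells) == 245


class TestDesignMatrix:
    def test_shape_and_column_split(self):
        sched = build_trial_schedule(52, seed=2)
        dm = build_design_matrix(sched, design.schedule_n_tr(sched))
        assert dm.values.shape[1] == 250
        assert sum(lab.startswith("map_") for lab in dm.column_labels) == 245

    def test_empty_schedule_all_zero(self):
        dm = build_design_matrix([], 20)
        assert not dm.values.any()

    def test_single_two_second_trial_indicator_sums(self):
        trial = design.TrialRecord(
            cue="left", bar_index=5, bar_duration_s=2, isi_ms=300,
            response_cue_location="left", validity="valid",
            onset_tr=0, duration_tr=5,
        )
        dm = build_design_matrix([trial], 10)
        assert dm.values[:, mapping_column("left", 5)].sum() == 2
        assert dm.values[:, target_column("left")].sum() == 1

    def test_row_sums_over_mapping_columns_at_most_one(self):
        sched = build_trial_schedule(200, seed=5)
        dm = build_design_matrix(sched, design.schedule_n_tr(sched))
        row_sums = dm.values[:, :245].sum(axis=1)
        assert set(np.unique(row_sums)) <= {0.0, 1.0}
        assert set(np.unique(dm.values)) <= {0.0, 1.0}

    def test_trial_exceeding_scan_length_raises(self):
        sched = build_trial_schedule(10, seed=0)
        with pytest.raises(IndexError):
            build_design_matrix(sched, design.schedule_n_tr(sched) - 1)


def test_schedule_tsv_roundtrip(tmp_path):
    sched = build_trial_schedule(30, seed=4)
    path = tmp_path / "trials.tsv"
    design.save_schedule_tsv(sched, path)
    assert design.load_schedule_tsv(path) == sched


def test_apertures_h5_roundtrip(tmp_path, apertures64):
    design.save_apertures_h5(apertures64, tmp_path / "a.h5", tmp_path / "a.json")
    loaded = design.load_apertures_h5(tmp_path / "a.h5", tmp_path / "a.json")
    assert np.array_equal(loaded.apertures, apertures64.apertures)
    assert loaded.grid_extent == apertures64.grid_extent
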