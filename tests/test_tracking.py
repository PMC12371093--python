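"""Localisation ingestion, track linking, D* estimation and binning."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given
from hypothesis import strategies as st

from dnaakit.tracking import (DiffusionHistogram, Track, apparent_D,
                              apparent_D_batch, assign_cells, build_histogram,
                              link_tracks, read_localisations,
                              tracks_to_histogram)


def _df(rows, cols=("frame", "x [nm]", "y [nm]")):
    return pd.DataFrame(rows, columns=list(cols))


class TestReadLocalisations:
    def test_empty_table(self):
        out = read_localisations(_df([]))
        assert len(out) == 0

    def test_nm_to_um_and_frame_cutoff(self):
        out = read_localisations(_df([(600, 1190.0, 0.0)]))
        assert len(out) == 1
        assert out.loc[0, "x"] == pytest.approx(1.19)
        assert out.loc[0, "y"] == 0.0

    def test_early_frames_dropped_and_counted(self):
        out = read_localisations(_df([(10, 0, 0), (499, 1, 1), (500, 2, 2)]))
        assert list(out["frame"]) == [500]
        assert out.attrs["n_dropped_frames"] == 2

    def test_missing_column_rejected(self):
        with pytest.raises(ValueError, match="frame"):
            read_localisations(pd.DataFrame({"x [nm]": [1], "y [nm]": [2]}))

    def test_non_numeric_cell_reports_row(self):
        with pytest.raises(ValueError, match="row 1"):
            read_localisations(_df([(600, 1.0, 0.0), (601, "oops", 0.0)]))

    def test_plain_columns_need_unit(self):
        df = _df([(600, 1.0, 2.0)], cols=("frame", "x", "y"))
        with pytest.raises(ValueError, match="unit"):
            read_localisations(df)
        out = read_localisations(df, unit="um")
        assert out.loc[0, "x"] == 1.0


class TestAssignCells:
    def test_label_mask_lookup(self):
        mask = np.zeros((10, 10), dtype=int)
        mask[2:5, 2:5] = 7
        locs = pd.DataFrame({"frame": [500, 500], "x": [0.4, 1.0],
                             "y": [0.4, 1.0]})
        out = assign_cells(locs, mask, pixel_size_um=0.119)
        # (0.4, 0.4) um -> pixel (3, 3) inside label 7; (1.0, 1.0) -> outside
        assert list(out["cell_id"]) == [7]
        assert out.attrs["n_discarded_outside"] == 1

    def test_polygon_assignment_and_discard(self):
        from shapely.geometry import box

        locs = pd.DataFrame({"frame": [500] * 3, "x": [0.5, 2.5, 9.0],
                             "y": [0.5, 2.5, 9.0]})
        out = assign_cells(locs, [box(0, 0, 1, 1), box(2, 2, 3, 3)])
        assert list(out["cell_id"]) == [1, 2]
        assert out.attrs["n_discarded_outside"] == 1

    def test_overlapping_polygons_rejected(self):
        from shapely.geometry import box

        locs = pd.DataFrame({"frame": [500], "x": [0.5], "y": [0.5]})
        with pytest.raises(ValueError, match="overlap"):
            assign_cells(locs, [box(0, 0, 2, 2), box(1, 1, 3, 3)])


class TestLinkTracks:
    def _locs(self, pts):
        return pd.DataFrame(pts, columns=["frame", "x", "y"])

    def test_single_particle_single_track(self):
        locs = self._locs([(f, 0.01 * f, 0.0) for f in range(500, 510)])
        tracks = link_tracks(locs, r_max=1.0)
        assert len(tracks) == 1
        assert tracks[0].n_locs == 10

    def test_threshold_splits_tracks(self):
        locs = self._locs([(500, 0.0, 0.0), (501, 2.0, 0.0)])
        tracks = link_tracks(locs, r_max=1.0)
        assert sorted(t.n_locs for t in tracks) == [1, 1]

    def test_frame_gap_closes_track(self):
        locs = self._locs([(500, 0.0, 0.0), (502, 0.0, 0.0)])
        tracks = link_tracks(locs, r_max=1.0)
        assert len(tracks) == 2

    def test_two_distant_particles_never_swap(self):
        rows = []
        for f in range(500, 508):
            rows.append((f, 0.05 * (f - 500), 0.0))
            rows.append((f, 0.05 * (507 - f), 3.0))
        tracks = link_tracks(self._locs(rows), r_max=1.0)
        assert len(tracks) == 2
        for t in tracks:
            assert len(set(np.round(t.xy[:, 1], 6))) == 1  # y stays constant

    def test_global_assignment_beats_greedy(self):
        # prev points at x = 0 and 0.5; next at 0.45 and 0.95.  The global
        # minimum pairs 0 -> 0.45 and 0.5 -> 0.95 (total 0.9), which the
        # exhaustive assignment oracle confirms beats the greedy pairing
        # 0.5 -> 0.45, 0 -> 0.95 (total 1.0).
        locs = self._locs([(500, 0.0, 0.0), (500, 0.5, 0.0),
                           (501, 0.45, 0.0), (501, 0.95, 0.0)])
        tracks = link_tracks(locs, r_max=1.0)
        assert len(tracks) == 2
        steps = sorted(round(abs(t.xy[1, 0] - t.xy[0, 0]), 6) for t in tracks)
        assert steps == [0.45, 0.45]

    def test_infinite_rmax_recovers_full_trajectory(self, rng):
        xy = np.cumsum(rng.normal(0, 0.1, size=(30, 2)), axis=0)
        locs = self._locs([(500 + i, x, y) for i, (x, y) in enumerate(xy)])
        tracks = link_tracks(locs, r_max=np.inf)
        assert len(tracks) == 1 and tracks[0].n_locs == 30

    def test_cells_never_mix(self):
        locs = pd.DataFrame({
            "frame": [500, 501, 500, 501],
            "x": [0.0, 0.01, 0.02, 0.03],
            "y": [0.0, 0.0, 0.0, 0.0],
            "cell_id": [1, 1, 2, 2],
        })
        tracks = link_tracks(locs, r_max=1.0)
        assert sorted((t.cell_id, t.n_locs) for t in tracks) == [(1, 2), (2, 2)]


class TestApparentD:
    def test_static_track_is_zero(self):
        t = Track(0, 1, np.arange(3), np.zeros((3, 2)))
        assert apparent_D(t) == 0.0

    def test_hand_computed_example(self):
        # two 0.2 um steps at 10 ms: msd = 0.04 um^2 -> D* = 1.0 um^2/s
        xy = np.array([[0.0, 0.0], [0.2, 0.0], [0.4, 0.0]])
        t = Track(0, 1, np.arange(3), xy)
        assert apparent_D(t, t_frame=0.01) == pytest.approx(1.0)

    def test_short_track_rejected(self):
        t = Track(0, 1, np.arange(2), np.zeros((2, 2)))
        with pytest.raises(ValueError):
            apparent_D(t)

    @given(st.integers(0, 1000))
    def test_rigid_motion_invariance(self, seed):
        rng = np.random.default_rng(seed)
        xy = rng.normal(0, 0.1, size=(6, 2))
        phi = rng.uniform(0, 2 * np.pi)
        rot = np.array([[np.cos(phi), -np.sin(phi)],
                        [np.sin(phi), np.cos(phi)]])
        moved = xy @ rot.T + rng.normal(0, 5, size=2)
        d0 = apparent_D(Track(0, 1, np.arange(6), xy))
        d1 = apparent_D(Track(0, 1, np.arange(6), moved))
        assert d1 == pytest.approx(d0, rel=1e-9)

    def test_batch_matches_scalar(self, rng):
        n_locs = rng.integers(1, 9, size=20)
        xy = rng.normal(0, 0.2, size=(20, 9, 2))
        batch = apparent_D_batch(xy, n_locs, t_frame=0.01)
        for i, n in enumerate(n_locs):
            if n < 3:
                assert np.isnan(batch[i])
            else:
                t = Track(i, 1, np.arange(n), xy[i, :n])
                assert batch[i] == pytest.approx(apparent_D(t, 0.01))


class TestHistogram:
    def test_edge_layout(self):
        h = build_histogram([])
        assert len(h.edges) == 86
        assert h.edges[0] == 0.04 and h.edges[-1] == pytest.approx(10.0)
        ratios = h.edges[1:] / h.edges[:-1]
        assert np.allclose(ratios, ratios[0])
        assert h.n_tracks == 0 and h.fractions.sum() == 0

    def test_single_value_bin_index(self):
        h = build_histogram([0.063])
        expected = int(np.floor(85 * np.log(0.063 / 0.04) / np.log(10 / 0.04)))
        assert np.flatnonzero(h.fractions) == [expected]

    def test_boundary_values(self):
        h = build_histogram([0.04, 10.0])
        nz = np.flatnonzero(h.fractions)
        assert list(nz) == [0, 84]

    def test_out_of_range_dropped_not_clamped(self):
        h = build_histogram([0.01, 1.0, 11.0])
        assert h.n_tracks == 1 and h.n_dropped == 2

    @given(st.lists(st.floats(0.04, 10.0), min_size=1, max_size=200))
    def test_fractions_sum_to_one(self, values):
        h = build_histogram(values)
        assert h.fractions.sum() == pytest.approx(1.0, abs=1e-12)

    def test_roundtrip_dataframe(self):
        h = build_histogram([0.1, 0.2, 5.0])
        h2 = DiffusionHistogram.from_dataframe(h.to_dataframe(), n_tracks=3)
        assert np.allclose(h2.edges, h.edges)
        assert np.allclose(h2.fractions, h.fractions)

    def test_tracks_to_histogram_eligibility(self):
        short = Track(0, 1, np.arange(2), np.zeros((2, 2)))
        ok = Track(1, 1, np.arange(3),
                   np.array([[0, 0], [0.1, 0], [0.2, 0]], dtype=float))
        h = tracks_to_histogram([short, ok])
        assert h.n_tracks == 1
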