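"""Detection, LAP linking, gap closing, filtering and track I/O."""

from itertools import permutations

import numpy as np
import pytest

from macromigr import simkit, trackio
from macromigr.core import Calibration, Track
from macromigr.trackio import (
    Detection,
    TrackingConfig,
    detect_cells,
    filter_tracks,
    link_tracks,
    read_tracks,
    write_tracks,
)

from conftest import random_tracks

CFG = TrackingConfig()


def _spot_image(positions, shape=(128, 128), sigma=2.5, intensity=50_000.0):
    img = np.zeros(shape)
    yy, xx = np.mgrid[0 : shape[0], 0 : shape[1]]
    for x, y in positions:
        img += (intensity / (2 * np.pi * sigma**2)) * np.exp(
            -0.5 * (((xx - x) ** 2 + (yy - y) ** 2) / sigma**2)
        )
    return img


class TestDetect:
    def test_single_spot_subpixel(self):
        dets = detect_cells(_spot_image([(40.0, 60.0)]), CFG)
        assert len(dets) == 1
        assert abs(dets[0].x - 40.0) <= 1.0 and abs(dets[0].y - 60.0) <= 1.0

    def test_blank_image_no_detections(self):
        assert detect_cells(np.zeros((64, 64)), CFG) == []

    def test_grid_of_spots_within_1px(self):
        pos = [(20 + 20 * i + 0.3, 20 + 20 * j + 0.7) for i in range(5) for j in range(5)]
        dets = detect_cells(_spot_image(pos, shape=(140, 140)), CFG)
        assert len(dets) == 25
        found = {(round(d.x), round(d.y)) for d in dets}
        for x, y in pos:
            match = [d for d in dets if np.hypot(d.x - x, d.y - y) <= 1.0]
            assert len(match) == 1
        assert len(found) == 25

    def test_invalid_images_rejected(self):
        with pytest.raises(ValueError):
            detect_cells(np.zeros((0, 5)), CFG)
        with pytest.raises(ValueError):
            detect_cells(np.full((8, 8), np.nan), CFG)
        with pytest.raises(ValueError):
            detect_cells(np.zeros((4, 4, 4)), CFG)


def _brute_force_link(prev, cur, d_max):
    """Exhaustive minimum-cost matching between two frames.

    Cost = sum of squared link distances + d_max^2 per unmatched
    detection on either side; links beyond d_max are forbidden.
    """
    n1, n2 = len(prev), len(cur)
    b = d_max**2
    best, best_cost = [], np.inf
    indices = list(range(n2)) + [None] * n1  # None = unmatched
    for perm in set(permutations(indices, n1)):
        links, cost, used = [], 0.0, set()
        ok = True
        for i, j in enumerate(perm):
            if j is None:
                cost += b
                continue
            if j in used:
                ok = False
                break
            used.add(j)
            d = np.hypot(prev[i][0] - cur[j][0], prev[i][1] - cur[j][1])
            if d > d_max:
                ok = False
                break
            cost += d**2
            links.append((i, j))
        if not ok:
            continue
        cost += b * (n2 - len(used))
        if cost < best_cost - 1e-9:
            best_cost, best = cost, sorted(links)
    return best


class TestLink:
    def test_distance_bound_inclusive(self):
        one = link_tracks([Detection(0, 0, 0, 1), Detection(1, 70.0, 0, 1)], CFG)
        assert len(one) == 1 and len(one[0]) == 2
        two = link_tracks([Detection(0, 0, 0, 1), Detection(1, 70.1, 0, 1)], CFG)
        assert len(two) == 2

    @pytest.mark.parametrize("gap,n_expected", [(10, 1), (11, 2)])
    def test_gap_closing_bound(self, gap, n_expected):
        dets = [Detection(f, 10.0 + f, 5.0, 1) for f in (0, 1)]
        dets += [Detection(f, 10.0 + f, 5.0, 1) for f in (2 + gap, 3 + gap)]
        tracks = link_tracks(dets, CFG)
        assert len(tracks) == n_expected
        if n_expected == 1:
            assert tracks[0].duration_frames == 4 + gap
            assert np.all(np.diff(tracks[0].frames) <= CFG.max_gap_frames + 1)

    def test_frame_to_frame_matches_brute_force(self, rng):
        for trial in range(30):
            n1, n2 = rng.integers(1, 5), rng.integers(1, 5)
            prev = rng.uniform(0, 100, (n1, 2))
            cur = prev[:n2] + rng.normal(0, 8, (min(n1, n2), 2)) if n2 <= n1 else \
                np.vstack([prev + rng.normal(0, 8, (n1, 2)),
                           rng.uniform(0, 100, (n2 - n1, 2))])
            dets = [Detection(0, x, y, 1) for x, y in prev]
            dets += [Detection(1, x, y, 1) for x, y in cur]
            tracks = link_tracks(dets, CFG)
            got = sorted(
                (int(np.argmin(np.hypot(prev[:, 0] - t.x[0], prev[:, 1] - t.y[0]))),
                 int(np.argmin(np.hypot(cur[:, 0] - t.x[-1], cur[:, 1] - t.y[-1]))))
                for t in tracks if len(t) == 2
            )
            expected = _brute_force_link(prev, cur, CFG.max_link_distance)
            assert got == expected, f"trial {trial}"

    def test_crossing_cells_resolved_optimally(self):
        # two cells approach and pass; small steps keep identity
        a = [(10 + 2 * f, 20.0) for f in range(10)]
        b = [(30 - 2 * f, 22.0) for f in range(10)]
        dets = [Detection(f, *a[f], 1) for f in range(10)]
        dets += [Detection(f, *b[f], 1) for f in range(10)]
        tracks = link_tracks(dets, CFG)
        assert len(tracks) == 2
        for t in tracks:
            dx = np.diff(t.x)
            assert np.all(dx > 0) or np.all(dx < 0)  # no identity swap

    def test_detections_partitioned(self, rng):
        dets = [Detection(int(f), *rng.uniform(0, 200, 2), 1.0)
                for f in rng.integers(0, 10, 60)]
        tracks = link_tracks(dets, CFG)
        total = sum(len(t) for t in tracks)
        assert total == len(dets)

    def test_empty_input(self):
        assert link_tracks([], CFG) == []

    def test_links_respect_distance_in_calibrated_units(self):
        # 40 px at 2 µm/px = 80 µm > 70 -> split
        cal = Calibration(microns_per_pixel=2.0)
        dets = [Detection(0, 0, 0, 1), Detection(1, 40.0, 0, 1)]
        assert len(link_tracks(dets, CFG, cal)) == 2


def _brute_force_filter(tracks, cfg):
    out = []
    for t in tracks:
        p = np.column_stack([t.x, t.y]) * t.calibration.microns_per_pixel
        path = sum(
            float(np.hypot(*(p[i + 1] - p[i]))) for i in range(len(p) - 1)
        )
        intervals = t.frames[-1] - t.frames[0]
        if (
            t.frames[-1] - t.frames[0] + 1 >= cfg.min_duration_frames
            and (path / intervals if intervals else 0.0) >= cfg.min_mean_speed
            and float(np.hypot(*(p[-1] - p[0]))) >= cfg.min_displacement
        ):
            out.append(t)
    return out


class TestFilter:
    def test_duration_below_minimum_rejected(self):
        t = Track(0, np.arange(19), np.arange(19) * 5.0, np.zeros(19))
        assert filter_tracks([t], CFG) == []

    def test_exact_thresholds_retained(self):
        # duration 20 frames, mean speed exactly 2.00, displacement 8.00:
        # 1-D walk with exactly representable steps: forward 8x2.5 + 1x3.0
        # (= 23), back 10x1.5 (= 15) -> path 38 over 19 intervals = 2.00,
        # net 23 - 15 = 8.00, all exact in binary floating point
        steps = np.array([2.5] * 8 + [3.0] + [-1.5] * 10)
        x = np.concatenate([[0.0], np.cumsum(steps)])
        t = Track(0, np.arange(20), x, np.zeros(20))
        assert t.duration_frames == 20
        assert t.path_length_um() / 19 == pytest.approx(2.0)
        assert t.net_displacement_um() == pytest.approx(8.0)
        assert filter_tracks([t], CFG) == [t]

    def test_matches_brute_force_on_random_tracks(self, rng):
        tracks = random_tracks(rng, 1000)
        ours = filter_tracks(tracks, CFG)
        oracle = _brute_force_filter(tracks, CFG)
        assert [t.track_id for t in ours] == [t.track_id for t in oracle]

    def test_idempotent_and_equals_single_criterion_conjunction(self, rng):
        tracks = random_tracks(rng, 200)
        once = filter_tracks(tracks, CFG)
        assert filter_tracks(once, CFG) == once
        loose = TrackingConfig(min_duration_frames=0, min_mean_speed=0,
                               min_displacement=0)
        only_dur = TrackingConfig(min_duration_frames=CFG.min_duration_frames,
                                  min_mean_speed=0, min_displacement=0)
        only_speed = TrackingConfig(min_duration_frames=0,
                                    min_mean_speed=CFG.min_mean_speed,
                                    min_displacement=0)
        only_disp = TrackingConfig(min_duration_frames=0, min_mean_speed=0,
                                   min_displacement=CFG.min_displacement)
        conj = [t for t in tracks
                if t in filter_tracks(tracks, only_dur)
                and t in filter_tracks(tracks, only_speed)
                and t in filter_tracks(tracks, only_disp)]
        assert filter_tracks(tracks, loose) == tracks
        assert once == conj


class TestRoundTrip:
    def test_movie_tracking_recovers_ground_truth(self):
        mode = simkit.ModeParams(mean_step_speed=0.2, angular_sd=1.5,
                                 circ_baseline=0.7, circ_noise_sd=0.02)
        params = simkit.SimParams(n_cells=12, n_frames=40, seed=21, mode=mode,
                                  field_size=(500, 420), placement="grid",
                                  margin_px=60)
        truth = simkit.simulate_tracks(params)
        movie = simkit.render_movie(truth, params)
        tracks = trackio.track_movie(movie, apply_filters=False)
        assert len(tracks) == 12
        matched = 0
        for t in tracks:
            d0 = [np.hypot(tt.x[0] - t.x[0], tt.y[0] - t.y[0]) for tt in truth.tracks]
            tt = truth.tracks[int(np.argmin(d0))]
            assert len(t) == len(tt)
            err = np.hypot(t.x - tt.x, t.y - tt.y)
            assert np.all(err <= 1.0)
            matched += 1
        assert matched == 12


class TestIO:
    def test_write_read_round_trip(self, tmp_path, rng):
        tracks = random_tracks(rng, 10)
        path = tmp_path / "tracks.csv"
        write_tracks(tracks, path)
        back = read_tracks(path)
        assert len(back) == len(tracks)
        for a, b in zip(tracks, back):
            assert a.track_id == b.track_id
            np.testing.assert_array_equal(a.frames, b.frames)
            np.testing.assert_allclose(a.x, b.x, atol=1e-6)
            np.testing.assert_allclose(a.y, b.y, atol=1e-6)

    def test_missing_column_named_in_error(self, tmp_path):
        path = tmp_path / "bad.csv"
        path.write_text("track_id,frame,x\n0,0,1.0\n0,1,2.0\n")
        with pytest.raises(ValueError, match="y"):
            read_tracks(path)

    def test_trackmate_dialect_parsed(self, tmp_path):
        # TrackMate exports carry extra columns and repeated textual
        # header rows; both must be tolerated
        path = tmp_path / "tm.csv"
        path.write_text(
            "LABEL,ID,TRACK_ID,QUALITY,POSITION_X,POSITION_Y,POSITION_Z,FRAME\n"
            "Label,Spot ID,Track ID,Quality,X,Y,Z,Frame\n"
            ",,,,(micron),(micron),(micron),\n"
            "ID1,1,0,50.0,10.5,20.5,0,0\n"
            "ID2,2,0,48.0,11.5,21.5,0,1\n"
            "ID3,3,1,47.0,50.0,60.0,0,0\n"
            "ID4,4,1,46.0,51.0,61.0,0,1\n"
        )
        tracks = read_tracks(path)
        assert [t.track_id for t in tracks] == [0, 1]
        np.testing.assert_allclose(tracks[0].x, [10.5, 11.5])

    def test_non_monotone_frames_rejected(self, tmp_path):
        path = tmp_path / "dup.csv"
        path.write_text("track_id,frame,x,y\n0,0,1,1\n0,0,2,2\n")
        with pytest.raises(ValueError, match="strictly increasing"):
            read_tracks(path)
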