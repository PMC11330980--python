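"""Projection, spot detection, and linking against brute-force oracles."""

import numpy as np
import pytest
from scipy.optimize import linear_sum_assignment

from aggretrack import detect_track as D
from aggretrack import synthgen as S


def gaussian_spot(shape, x, y, amplitude, sigma=1.3):
    yy, xx = np.mgrid[: shape[0], : shape[1]]
    return amplitude * np.exp(-((xx - x) ** 2 + (yy - y) ** 2) / (2 * sigma ** 2))


class TestMaxProject:
    def test_single_voxel(self):
        stack = np.zeros((5, 8, 9))
        stack[3, 2, 4] = 7.0
        proj = D.max_project(stack)
        assert proj[2, 4] == 7.0
        assert proj.sum() == 7.0

    def test_all_zero(self):
        assert D.max_project(np.zeros((2, 4, 4))).sum() == 0

    def test_matches_bruteforce_loop(self, rng):
        stack = rng.integers(0, 4096, size=(12, 10, 11)).astype(float)
        proj = D.max_project(stack)
        for y in range(10):
            for x in range(11):
                assert proj[y, x] == max(stack[z, y, x] for z in range(12))

    def test_channel_axis_preserved(self, rng):
        stack = rng.random((2, 5, 6, 7))
        proj = D.max_project(stack)
        assert proj.shape == (2, 6, 7)

    def test_empty_stack_rejected(self):
        with pytest.raises(ValueError):
            D.max_project(np.zeros((0, 4, 4)))


class TestDetectSpots:
    def test_blank_noise_image_yields_nothing(self, rng):
        img = rng.poisson(50.0, size=(120, 160)).astype(float)
        assert D.detect_spots(img) == []

    def test_single_punctum_found_within_one_pixel(self, rng):
        noise_sigma = 7.0
        img = rng.normal(100.0, noise_sigma, size=(256, 256))
        img += gaussian_spot(img.shape, 200.0, 100.0, 10 * noise_sigma)
        dets = D.detect_spots(img)
        assert len(dets) == 1
        assert abs(dets[0].x - 200.0) < 1.0
        assert abs(dets[0].y - 100.0) < 1.0
        # argmax oracle: the brightest pixel is where the detector looked
        py, px = np.unravel_index(np.argmax(img), img.shape)
        assert abs(px - dets[0].x) <= 2 and abs(py - dets[0].y) <= 2

    def test_two_puncta_ten_pixels_apart(self, rng):
        img = rng.normal(100.0, 5.0, size=(128, 128))
        img += gaussian_spot(img.shape, 60.0, 64.0, 80.0)
        img += gaussian_spot(img.shape, 70.0, 64.0, 80.0)
        dets = D.detect_spots(img)
        assert len(dets) == 2
        xs = sorted(d.x for d in dets)
        assert xs[0] == pytest.approx(60.0, abs=1.0)
        assert xs[1] == pytest.approx(70.0, abs=1.0)

    def test_nonfinite_pixels_rejected(self):
        img = np.zeros((32, 32))
        img[3, 3] = np.nan
        with pytest.raises(ValueError):
            D.detect_spots(img)

    def test_identical_parameters_are_deterministic(self, rng):
        img = rng.normal(100.0, 5.0, size=(128, 128))
        img += gaussian_spot(img.shape, 40.0, 50.0, 90.0)
        a = D.detect_spots(img)
        b = D.detect_spots(img)
        assert [(d.x, d.y) for d in a] == [(d.x, d.y) for d in b]


class TestLinking:
    @staticmethod
    def det(frame, x, y):
        return D.Detection(frame=frame, channel="L1", x=x, y=y, z_best=0,
                           peak_intensity=100.0, area=5.0)

    def test_stationary_point_single_track(self):
        dets = [self.det(f, 30.0, 40.0) for f in range(50)]
        tracks, merges = D.link_tracks(dets)
        assert len(tracks) == 1
        assert len(tracks[0].detections) == 50
        assert merges == []

    def test_two_linear_paths_keep_identity(self):
        dets = []
        for f in range(30):
            dets.append(self.det(f, 10.0 + 2.0 * f, 10.0))
            dets.append(self.det(f, 10.0 + 2.0 * f, 40.0))
        tracks, _ = D.link_tracks(dets)
        assert len(tracks) == 2
        for tr in tracks:
            ys = {d.y for d in tr.detections}
            assert len(ys) == 1  # never jumps between the two paths
            assert len(tr.detections) == 30
        # cross-check against an independent per-frame optimal assignment
        prev = [(10.0, 10.0), (10.0, 40.0)]
        for f in range(1, 30):
            cur = [(10.0 + 2.0 * f, 10.0), (10.0 + 2.0 * f, 40.0)]
            cost = np.array([[np.hypot(px - cx, py - cy) for (cx, cy) in cur]
                             for (px, py) in prev])
            rows, cols = linear_sum_assignment(cost)
            assert list(cols) == [0, 1]
            prev = cur

    def test_gap_longer_than_gap_max_starts_new_track(self):
        cfg = D.LinkConfig(gap_max=2)
        dets = [self.det(f, 20.0, 20.0) for f in range(5)]
        dets += [self.det(f, 20.0, 20.0) for f in range(8, 20)]  # 3-frame gap
        tracks, _ = D.link_tracks(dets, cfg)
        assert len(tracks) == 2
        # a 2-frame gap is bridged
        dets2 = [self.det(f, 20.0, 20.0) for f in range(5)]
        dets2 += [self.det(f, 20.0, 20.0) for f in range(7, 20)]
        tracks2, _ = D.link_tracks(dets2, cfg)
        assert len(tracks2) == 1

    def test_invalid_dmax_rejected(self):
        with pytest.raises(ValueError):
            D.link_tracks([], D.LinkConfig(d_max=0.0))

    def test_count_conservation(self):
        rng = np.random.default_rng(3)
        dets = []
        for f in range(20):
            for k in range(rng.integers(1, 5)):
                dets.append(self.det(f, float(rng.uniform(0, 100)),
                                     float(rng.uniform(0, 100))))
        tracks, _ = D.link_tracks(dets)
        per_frame = {f: 0 for f in range(20)}
        for tr in tracks:
            for d in tr.detections:
                per_frame[d.frame] += 1
        for f in range(20):
            assert per_frame[f] == sum(1 for d in dets if d.frame == f)


@pytest.fixture(scope="module")
def rendered():
    cfg = S.SimConfig(geometry=S.GeometryConfig().scaled(0.5))
    cfg.geometry.n_z = 4
    cfg.render_burn_in = 120.0
    cfg.horizon = 20.0
    res = S.simulate_experiment("longterm_WT", cfg, seed=42)
    dets = D.detect_series(res.series, "L1")
    return res, dets


class TestOnSyntheticSeries:
    @staticmethod
    def match_count(gt, dd, radius=2.0):
        if len(gt) == 0 or len(dd) == 0:
            return 0
        cost = np.full((len(gt), len(dd)), 1e6)
        for i, (_, g) in enumerate(gt.iterrows()):
            for j, d in enumerate(dd):
                dist = np.hypot(d.x - g.x, d.y - g.y)
                if dist <= radius:
                    cost[i, j] = dist
        rows, cols = linear_sum_assignment(cost)
        return int(sum(cost[i, j] < 1e6 for i, j in zip(rows, cols)))

    def test_recall_and_precision_at_default_snr(self, rendered):
        res, dets = rendered
        tr = res.truth.aggregates
        # exclude puncta unresolvably close to a brighter neighbour:
        # coincident objects merge optically in any detector
        n_true = n_det = n_hit = n_hit_all = 0
        for f in range(res.series.n_frames):
            gt_all = tr[tr.frame == f]
            # recall is judged on resolvable puncta: coincident objects
            # merge optically in any detector
            xy = gt_all[["x", "y"]].to_numpy()
            keep = np.ones(len(gt_all), dtype=bool)
            for i in range(len(gt_all)):
                for j in range(len(gt_all)):
                    if i != j and np.hypot(*(xy[i] - xy[j])) < 3.0:
                        keep[i] = keep[i] and i < j
            gt = gt_all[keep]
            dd = [d for d in dets if d.frame == f]
            n_true += len(gt)
            n_det += len(dd)
            n_hit += self.match_count(gt, dd)
            n_hit_all += self.match_count(gt_all, dd)
        recall = n_hit / n_true
        precision = n_hit_all / n_det  # every real punctum legitimizes its detection
        assert recall >= 0.95
        assert precision >= 0.95

    def test_track_identity_fraction(self, rendered):
        res, dets = rendered
        tracks, _ = D.link_tracks(dets)
        tracks = [t for t in tracks if len(t.detections) >= 5]
        tr = res.truth.aggregates
        correct = total = 0
        for t_ in tracks:
            # majority truth id over the track's detections
            ids = []
            for d in t_.detections:
                g = tr[tr.frame == d.frame]
                if len(g) == 0:
                    continue
                dist = np.hypot(g.x - d.x, g.y - d.y)
                i = dist.idxmin()
                if dist[i] < 2.0:
                    ids.append(g.loc[i, "aggregate_id"])
            if not ids:
                continue
            vals, counts = np.unique(ids, return_counts=True)
            correct += counts.max()
            total += len(t_.detections)
        assert total > 0
        assert correct / total >= 0.9

    def test_detection_is_deterministic(self, rendered):
        res, dets = rendered
        again = D.detect_series(res.series, "L1")
        assert [(d.frame, d.x, d.y) for d in dets] == [
            (d.frame, d.x, d.y) for d in again
        ]
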