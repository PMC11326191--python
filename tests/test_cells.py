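"""Segmentation, Crocker-Grier track linking (vs exhaustive search), and
debris filtering."""

import dataclasses
import itertools

import numpy as np
import pandas as pd
import pytest

from qdf import simulate as sim
from qdf.cells import filter_debris, link_tracks, segment_cells


# ---------------------------------------------------------------------------
# segmentation


class TestSegmentCells:
    def test_blank_field_gives_no_labels(self):
        rng = np.random.default_rng(0)
        out = segment_cells(rng.normal(0, 0.02, (64, 64)), pixel_size_um=0.5)
        assert out.n_cells == 0

    def test_two_separated_cells(self, optics):
        bodies = (
            sim.BodySpec(center_um=(18.0, 18.0), radius_um=9.0, height_um=2.0),
            sim.BodySpec(center_um=(46.0, 46.0), radius_um=7.0, height_um=2.0),
        )
        scene = dataclasses.replace(sim.SceneSpec(field_size=(128, 128), bodies=bodies),
                                    phase_background_coeffs=((0.0,),))
        phase = sim.render_phase(scene, optics)
        out = segment_cells(phase.phase, pixel_size_um=0.5, min_area_um2=20.0)
        assert out.n_cells == 2
        for body in bodies:
            truth = body.height_map((128, 128), 0.5) > 0
            ids, counts = np.unique(out.labels[truth], return_counts=True)
            best = ids[np.argmax(counts)]
            overlap = (out.labels[truth] == best).mean()
            assert best > 0 and overlap > 0.95

    def test_touching_cells_split_by_watershed(self):
        # two smooth phase bumps whose skirts overlap -> two labels, one per peak
        yy, xx = np.mgrid[0:64, 0:64].astype(float)
        bump = lambda cx, cy: 1.5 * np.exp(-(((xx - cx) ** 2 + (yy - cy) ** 2) / (2 * 8.0**2)))
        phase = bump(24, 32) + bump(42, 32)
        out = segment_cells(phase, pixel_size_um=0.5, h_depth=0.2, min_phase=0.2)
        assert out.n_cells == 2
        assert out.labels[32, 24] != out.labels[32, 42]
        assert out.labels[32, 24] > 0 and out.labels[32, 42] > 0

    def test_labels_partition_foreground(self):
        yy, xx = np.mgrid[0:64, 0:64].astype(float)
        phase = 1.0 * (np.hypot(xx - 32, yy - 32) < 12)
        out = segment_cells(phase, pixel_size_um=0.5, min_phase=0.3)
        from skimage import filters

        smoothed = filters.gaussian(phase, sigma=2.0, preserve_range=True)
        fg = smoothed > 0.3
        # every labelled pixel is foreground; dropped specks aside, fg is labelled
        assert np.all(fg[out.labels > 0])
        assert (out.labels[fg] > 0).mean() > 0.99


# ---------------------------------------------------------------------------
# tracking


def link_cost(tracks, frames, max_disp):
    """Crocker-Grier objective of a linking result over consecutive frames."""
    cost = 0.0
    for t in range(len(frames) - 1):
        linked_prev, linked_cur = set(), set()
        for track in tracks:
            for (fa, ia), (fb, ib) in zip(zip(track.frames, track.indices),
                                          zip(track.frames[1:], track.indices[1:])):
                if fa == t and fb == t + 1:
                    d2 = np.sum((frames[t][ia] - frames[t + 1][ib]) ** 2)
                    cost += d2
                    linked_prev.add(ia)
                    linked_cur.add(ib)
        cost += max_disp**2 * (len(frames[t]) - len(linked_prev))
        cost += max_disp**2 * (len(frames[t + 1]) - len(linked_cur))
    return cost


def brute_force_cost(prev, cur, max_disp):
    """Exhaustive minimum of sum d^2 + L^2 * (#unmatched) over gated matchings."""
    l2 = max_disp**2
    n, m = len(prev), len(cur)
    if n == 0 or m == 0:
        return l2 * (n + m)
    d2 = np.sum((prev[:, None, :] - cur[None, :, :]) ** 2, axis=-1)
    best = float("inf")
    for k in range(0, min(n, m) + 1):
        for rows in itertools.combinations(range(n), k):
            for cols in itertools.permutations(range(m), k):
                if any(d2[r, c] > l2 for r, c in zip(rows, cols)):
                    continue
                cost = sum(d2[r, c] for r, c in zip(rows, cols)) + l2 * (n + m - 2 * k)
                best = min(best, cost)
    return best


class TestLinkTracks:
    def test_single_particle_two_frames(self):
        frames = [np.array([[0.0, 0.0]]), np.array([[1.0, 1.0]])]
        tracks = link_tracks(frames, max_disp=5.0)
        assert len(tracks) == 1 and len(tracks[0]) == 2

    def test_gate_splits_tracks(self):
        frames = [np.array([[0.0, 0.0]]), np.array([[10.0, 0.0]])]
        tracks = link_tracks(frames, max_disp=5.0)
        assert len(tracks) == 2 and all(len(t) == 1 for t in tracks)

    def test_crossing_particles_minimise_total_cost(self):
        # two particles taking small steps; greedy nearest-neighbour would swap
        frames = [np.array([[0.0, 0.0], [3.0, 0.0]]),
                  np.array([[1.0, 0.1], [2.0, -0.1]])]
        tracks = link_tracks(frames, max_disp=5.0)
        cost = link_cost(tracks, frames, 5.0)
        assert cost == pytest.approx(brute_force_cost(frames[0], frames[1], 5.0))

    @pytest.mark.parametrize("seed", range(25))
    def test_matches_exhaustive_search(self, seed):
        rng = np.random.default_rng(seed)
        n, m = rng.integers(0, 7, size=2)
        prev = rng.uniform(0, 20, (n, 2))
        cur = rng.uniform(0, 20, (m, 2))
        max_disp = float(rng.uniform(3, 12))
        tracks = link_tracks([prev, cur], max_disp)
        cost = link_cost(tracks, [prev, cur], max_disp)
        assert cost == pytest.approx(brute_force_cost(prev, cur, max_disp), rel=1e-9)

    def test_invariant_under_input_permutation(self):
        rng = np.random.default_rng(7)
        prev = rng.uniform(0, 20, (5, 2))
        cur = rng.uniform(0, 20, (5, 2))
        t1 = link_tracks([prev, cur], max_disp=8.0)
        perm = rng.permutation(5)
        t2 = link_tracks([prev, cur[perm]], max_disp=8.0)
        links1 = {(ta.centroids_um[0], ta.centroids_um[-1]) for ta in t1 if len(ta) == 2}
        links2 = {(ta.centroids_um[0], ta.centroids_um[-1]) for ta in t2 if len(ta) == 2}
        assert links1 == links2

    def test_memory_bridges_gaps(self):
        frames = [np.array([[0.0, 0.0]]), np.empty((0, 2)), np.array([[0.5, 0.0]])]
        no_memory = link_tracks(frames, max_disp=5.0, memory=0)
        assert len(no_memory) == 2
        with_memory = link_tracks(frames, max_disp=5.0, memory=1)
        assert len(with_memory) == 1 and with_memory[0].frames == [0, 2]

    def test_rejects_empty_input(self):
        with pytest.raises(ValueError):
            link_tracks([], max_disp=1.0)


# ---------------------------------------------------------------------------
# debris filtering


class TestFilterDebris:
    @pytest.fixture()
    def table(self):
        return pd.DataFrame({
            "area_um2": [10.0, 50.0, 200.0, 400.0, 2000.0],
            "track_length": [1, 5, 5, 2, 5],
            "mean_phase": [0.05, 0.4, 0.6, 0.9, 0.2],
        })

    def test_all_pass_is_identity(self, table):
        out = filter_debris(table, {"area_um2": (None, None)})
        pd.testing.assert_frame_equal(out, table)

    def test_impossible_bound_empties_table(self, table):
        assert len(filter_debris(table, {"area_um2": (1e6, None)})) == 0

    def test_hand_enumerated_bounds(self, table):
        # area in [20, 1000] keeps rows 1-3; track_length >= 3 then drops row 3;
        # mean_phase >= 0.3 keeps rows 1 and 2
        out, report = filter_debris(
            table,
            {"area_um2": (20.0, 1000.0), "track_length": (3, None), "mean_phase": (0.3, None)},
            return_report=True,
        )
        assert list(out.index) == [1, 2]
        assert report == {"area_um2": 2, "track_length": 2, "mean_phase": 2}

    def test_unknown_metric_rejected(self, table):
        with pytest.raises(ValueError, match="unknown"):
            filter_debris(table, {"perimeter": (0, 1)})
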