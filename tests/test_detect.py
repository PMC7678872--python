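"""Event calling: grid partition, traces, peak calling, spillover, matching."""

import math

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

import alphaflash as af
from alphaflash.detect import PeakCall, partition_grid


class TestPartitionGrid:
    def test_solid_20x30_gives_six_squares(self):
        grid = partition_grid(np.ones((20, 30), dtype=bool))
        assert grid.n_squares == 6
        # 2x3 tile grid: 4 corner tiles with 3 neighbors, 2 middle with 5
        counts = sorted(len(grid.neighbors[i]) for i in range(6))
        assert counts == [3, 3, 3, 3, 5, 5]

    def test_single_square_no_neighbors(self):
        grid = partition_grid(np.ones((10, 10), dtype=bool))
        assert grid.n_squares == 1
        assert grid.neighbors[0] == frozenset()

    def test_anchored_at_bounding_box(self):
        mask = np.zeros((40, 40), dtype=bool)
        mask[7:27, 13:33] = True
        grid = partition_grid(mask)
        assert grid.squares[0].row_start == 7
        assert grid.squares[0].col_start == 13
        assert grid.n_squares == 4

    def test_partial_edge_squares_retained(self):
        grid = partition_grid(np.ones((15, 10), dtype=bool))
        assert grid.n_squares == 2
        assert grid.squares[1].row_stop - grid.squares[1].row_start == 5

    def test_rejects_bad_inputs(self):
        with pytest.raises(ValueError):
            partition_grid(np.zeros((10, 10), dtype=bool))
        with pytest.raises(ValueError):
            partition_grid(np.ones((10, 10), dtype=bool), square_size_px=1)

    @settings(deadline=None, max_examples=30, derandomize=True)
    @given(st.integers(0, 2 ** 31 - 1))
    def test_partition_invariants_random_masks(self, seed):
        rng = np.random.default_rng(seed)
        mask = np.zeros((37, 41), dtype=bool)
        n_blobs = rng.integers(1, 4)
        for _ in range(n_blobs):
            r, c = rng.integers(0, 30), rng.integers(0, 34)
            mask[r:r + rng.integers(3, 12), c:c + rng.integers(3, 12)] = True
        grid = partition_grid(mask)
        # symmetry of the neighbor relation
        for i, nbrs in grid.neighbors.items():
            for j in nbrs:
                assert i in grid.neighbors[j]
                assert i != j
        # every mask pixel belongs to exactly one retained square
        for r, c in np.argwhere(mask):
            assert grid.square_at(int(r), int(c)) is not None
        # squares do not overlap
        seen = np.zeros(mask.shape, dtype=int)
        for sq in grid.squares:
            seen[sq.row_start:sq.row_stop, sq.col_start:sq.col_stop] += 1
        assert seen.max() <= 1


class TestExtractTraces:
    def test_constant_movie(self, square30, acq):
        movie = af.MovieStack(np.full((5, 30, 30), 100.0), acq)
        traces = af.extract_traces(movie, partition_grid(square30.mask))
        for t in traces:
            np.testing.assert_array_equal(t.values, 100.0)

    def test_single_bright_pixel_mean(self, square30, acq):
        data = np.zeros((3, 30, 30))
        data[1, 5, 5] = 200.0
        traces = af.extract_traces(af.MovieStack(data, acq),
                                   partition_grid(square30.mask))
        t0 = next(t for t in traces if t.square_id == 0)
        assert t0.values[1] == pytest.approx(2.0)  # 200 / 100 px
        assert t0.values[0] == 0.0

    def test_matches_bruteforce_per_pixel_averaging(self, acq):
        rng = np.random.default_rng(0)
        mask = np.ones((25, 32), dtype=bool)
        movie = af.MovieStack(rng.uniform(0, 1000, (12, 25, 32)), acq)
        grid = partition_grid(mask)
        traces = {t.square_id: t.values for t in af.extract_traces(movie, grid)}
        for sq in grid.squares:
            for f in range(12):
                acc, n = 0.0, 0
                for r in range(sq.row_start, sq.row_stop):
                    for c in range(sq.col_start, sq.col_stop):
                        acc += movie.data[f, r, c]
                        n += 1
                assert traces[sq.index][f] == pytest.approx(acc / n, rel=1e-12)

    def test_raster_mismatch_rejected(self, acq):
        movie = af.MovieStack(np.zeros((2, 20, 20)), acq)
        with pytest.raises(ValueError):
            af.extract_traces(movie, partition_grid(np.ones((30, 30), bool)))


def _oracle_peaks(values, window, k_sigma, min_sep):
    """Brute-force re-derivation of the peak rule for cross-checking."""
    values = np.asarray(values, dtype=float)
    half = window // 2
    padded = np.pad(values, half, mode="edge")
    baseline = np.array(
        [np.median(padded[i:i + window]) for i in range(len(values))]
    )
    resid = values - baseline
    sd = 1.4826 * np.median(np.abs(resid - np.median(resid)))
    candidates = [
        i for i in range(1, len(values) - 1)
        if values[i - 1] < values[i] > values[i + 1]
        and resid[i] > k_sigma * sd and resid[i] > 0
    ]
    accepted = []
    for i in sorted(candidates, key=lambda i: (-resid[i], i)):
        if all(abs(i - j) >= min_sep for j in accepted):
            accepted.append(i)
    return sorted(accepted)


class TestDetectPeaks:
    def test_single_spike_on_flat_trace(self):
        trace = np.zeros(100)
        trace[40] = 50.0
        peaks = af.detect_peaks(trace)
        assert len(peaks) == 1
        assert peaks[0].frame == 40
        assert peaks[0].amplitude == pytest.approx(50.0)

    def test_constant_trace_has_no_peaks(self):
        assert af.detect_peaks(np.full(100, 7.0)) == []

    def test_rejects_nonfinite_and_short_traces(self):
        bad = np.zeros(100)
        bad[3] = np.nan
        with pytest.raises(ValueError):
            af.detect_peaks(bad)
        with pytest.raises(ValueError):
            af.detect_peaks(np.zeros(10), baseline_window_frames=21)

    def test_matches_bruteforce_oracle_on_noisy_spiky_trace(self):
        rng = np.random.default_rng(1234)
        n = 3000
        values = rng.normal(100.0, 1.0, n)
        spike_frames = rng.choice(np.arange(30, n - 30), size=200, replace=False)
        values[spike_frames] += 8.0  # SNR 8
        calls = af.detect_peaks(values, 21, 5.0, 3)
        got = [p.frame for p in calls]
        assert got == _oracle_peaks(values, 21, 5.0, 3)
        # sanity: most injected spikes are recovered
        assert len(set(got) & set(spike_frames.tolist())) > 150


def _peak(square, frame, amp):
    return PeakCall(square_id=square, frame=frame, amplitude=amp, baseline=0.0)


@pytest.fixture(scope="module")
def grid():
    return partition_grid(np.ones((30, 30), dtype=bool))  # 3x3 squares


class TestRejectSpillover:

    def test_lower_neighbor_same_frame_removed(self, grid):
        # squares 0 and 1 are neighbors
        events = af.reject_spillover([_peak(0, 10, 100.0), _peak(1, 10, 60.0)],
                                     grid, 0.09)
        assert [(e.square_id, e.frame) for e in events] == [(0, 10)]

    def test_non_adjacent_same_frame_both_kept(self, grid):
        # squares 0 (corner) and 8 (opposite corner) are not neighbors
        events = af.reject_spillover([_peak(0, 10, 100.0), _peak(8, 10, 60.0)],
                                     grid, 0.09)
        assert len(events) == 2

    def test_equal_amplitude_tie_keeps_lower_index(self, grid):
        events = af.reject_spillover([_peak(1, 5, 80.0), _peak(0, 5, 80.0)],
                                     grid, 0.09)
        assert [(e.square_id,) for e in events] == [(0,)]

    def test_chain_raw_peak_set_semantics(self, grid):
        # A(0)=100 - B(1)=80 - C(2)=60 in a row: A-B and B-C adjacent,
        # A-C not.  B removed by A; C removed by B's *raw* peak.
        peaks = [_peak(0, 7, 100.0), _peak(1, 7, 80.0), _peak(2, 7, 60.0)]
        events = af.reject_spillover(peaks, grid, 0.09)
        assert [(e.square_id,) for e in events] == [(0,)]

    def test_chain_survivor_variant_keeps_third(self, grid):
        peaks = [_peak(0, 7, 100.0), _peak(1, 7, 80.0), _peak(2, 7, 60.0)]
        events = af.reject_spillover(peaks, grid, 0.09, use_raw_peaks=False)
        assert [(e.square_id,) for e in events] == [(0,), (2,)]

    def test_different_frames_not_compared(self, grid):
        events = af.reject_spillover([_peak(0, 10, 100.0), _peak(1, 11, 60.0)],
                                     grid, 0.09)
        assert len(events) == 2

    def test_unknown_square_rejected(self, grid):
        with pytest.raises(ValueError):
            af.reject_spillover([_peak(99, 0, 1.0)], grid, 0.09)

    @settings(deadline=None, max_examples=30, derandomize=True)
    @given(st.integers(0, 2 ** 31 - 1))
    def test_never_increases_and_keeps_isolated_peaks(self, seed):
        grid = partition_grid(np.ones((30, 30), dtype=bool))
        rng = np.random.default_rng(seed)
        peaks = []
        used = set()
        for _ in range(rng.integers(1, 15)):
            sq, fr = int(rng.integers(0, 9)), int(rng.integers(0, 5))
            if (sq, fr) in used:
                continue
            used.add((sq, fr))
            peaks.append(_peak(sq, fr, float(rng.uniform(1, 100))))
        events = af.reject_spillover(peaks, grid, 0.09)
        assert len(events) <= len(peaks)
        kept = {(e.square_id, e.frame) for e in events}
        for p in peaks:
            same_frame_neighbors = [
                q for q in peaks
                if q.frame == p.frame and q.square_id in grid.neighbors[p.square_id]
            ]
            if not same_frame_neighbors:
                assert (p.square_id, p.frame) in kept


class TestNormalizeRate:
    @pytest.mark.parametrize(
        "n,area,duration,expected",
        [(6, 100.0, 60.0, 6.0), (5, 200.0, 120.0, 1.25), (0, 37.0, 55.0, 0.0)],
    )
    def test_examples(self, n, area, duration, expected):
        assert af.normalize_rate(n, area, duration).rate == expected

    def test_linear_scaling_exact(self):
        base = af.normalize_rate(12, 150.0, 90.0).rate
        assert af.normalize_rate(12, 300.0, 90.0).rate == base / 2
        assert af.normalize_rate(12, 150.0, 180.0).rate == base / 2
        assert af.normalize_rate(24, 150.0, 90.0).rate == base * 2

    def test_rejects_degenerate_inputs(self):
        for kwargs in ({"area_um2": 0.0, "duration_s": 10.0},
                       {"area_um2": 10.0, "duration_s": 0.0},
                       {"area_um2": -5.0, "duration_s": 10.0}):
            with pytest.raises(ValueError):
                af.normalize_rate(1, **kwargs)


def _optimal_matching_size(detected, truth, grid, tol):
    import networkx as nx

    g = nx.Graph()
    d_nodes = [("d", i) for i in range(len(detected))]
    t_nodes = [("t", i) for i in range(len(truth))]
    g.add_nodes_from(d_nodes)
    g.add_nodes_from(t_nodes)
    for i, d in enumerate(detected):
        allowed = {d.square_id} | set(grid.neighbors[d.square_id])
        for j, e in enumerate(truth):
            sq = grid.square_at(int(math.floor(e.y_px + 0.5)),
                                int(math.floor(e.x_px + 0.5)))
            if sq in allowed and abs(e.frame - d.frame) <= tol:
                g.add_edge(("d", i), ("t", j))
    m = nx.bipartite.maximum_matching(g, top_nodes=d_nodes)
    return len(m) // 2


class TestMatchToTruth:
    def _truth(self, frame, y, x):
        return af.GroundTruthEvent(time_s=frame * 0.09, frame=frame,
                                   x_px=x, y_px=y, amplitude=100.0)

    def test_perfect_detection(self):
        grid = partition_grid(np.ones((30, 30), dtype=bool))
        truth = [self._truth(10, 5.0, 5.0), self._truth(40, 25.0, 25.0)]
        detected = [
            af.DetectedEvent(grid.square_at(5, 5), 10, 0.9, 50.0),
            af.DetectedEvent(grid.square_at(25, 25), 40, 3.6, 50.0),
        ]
        m = af.match_to_truth(detected, truth, grid)
        assert (m.precision, m.recall, m.f1) == (1.0, 1.0, 1.0)

    def test_no_detections_flagged(self):
        grid = partition_grid(np.ones((30, 30), dtype=bool))
        m = af.match_to_truth([], [self._truth(5, 5.0, 5.0)], grid)
        assert m.precision == 0.0 and not m.precision_defined
        assert m.recall == 0.0 and m.f1 == 0.0

    def test_frame_tolerance_enforced(self):
        grid = partition_grid(np.ones((30, 30), dtype=bool))
        truth = [self._truth(10, 5.0, 5.0)]
        near = [af.DetectedEvent(0, 12, 1.08, 10.0)]
        far = [af.DetectedEvent(0, 13, 1.17, 10.0)]
        assert af.match_to_truth(near, truth, grid).n_matched == 1
        assert af.match_to_truth(far, truth, grid).n_matched == 0

    @settings(deadline=None, max_examples=30, derandomize=True)
    @given(st.integers(0, 2 ** 31 - 1))
    def test_greedy_within_bound_of_optimal(self, seed):
        grid = partition_grid(np.ones((30, 30), dtype=bool))
        rng = np.random.default_rng(seed)
        truth = [
            self._truth(int(rng.integers(0, 20)),
                        float(rng.uniform(0, 29)), float(rng.uniform(0, 29)))
            for _ in range(rng.integers(1, 10))
        ]
        detected = [
            af.DetectedEvent(int(rng.integers(0, 9)), int(rng.integers(0, 20)),
                             0.0, 1.0)
            for _ in range(rng.integers(1, 10))
        ]
        m = af.match_to_truth(detected, truth, grid)
        opt = _optimal_matching_size(detected, truth, grid, 2)
        assert m.n_matched <= opt
        assert 2 * m.n_matched >= opt  # greedy maximal-matching bound


class TestEndToEndNoiseFree:
    def test_single_flash_called_in_correct_square_and_frame(self, square30,
                                                             acq,
                                                             flash_movie_factory):
        e = af.GroundTruthEvent(time_s=50 * 0.09 + 1e-4, frame=50,
                                x_px=14.0, y_px=14.0, amplitude=500.0)
        movie = flash_movie_factory([e], square30, acq)
        events, grid = af.detect_events(movie, square30.mask)
        assert len(events) == 1
        assert events[0].frame == 50
        assert events[0].square_id == grid.square_at(14, 14)

    def test_border_flash_yields_single_event(self, square30, acq,
                                              flash_movie_factory):
        # straddles the vertical border between squares 3 and 4
        e = af.GroundTruthEvent(time_s=50 * 0.09 + 1e-4, frame=50,
                                x_px=9.5, y_px=14.0, amplitude=500.0)
        movie = flash_movie_factory([e], square30, acq)
        events, _ = af.detect_events(movie, square30.mask)
        assert len(events) == 1
        assert events[0].frame == 50
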