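"""Release-event calling on single-cell TIRF movies.

The calling algorithm works on a grid of 10 x 10 pixel squares laid over the
cell footprint: the mean intensity of each square is traced over time, peaks
above a robust noise threshold are called per square, and a peak that
coincides (same frame) with a strictly larger peak in one of the eight
neighboring squares is discarded as optical spillover from that neighbor.
Surviving peaks are the release events; counts are normalized to
events / 100 um^2 / min.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np
from scipy import ndimage, signal as _signal

from .simulate import MovieStack

__all__ = [
    "GridSquare",
    "GridPartition",
    "IntensityTrace",
    "PeakCall",
    "DetectedEvent",
    "EventRateRecord",
    "DetectionParams",
    "MatchResult",
    "partition_grid",
    "extract_traces",
    "detect_peaks",
    "reject_spillover",
    "detect_events",
    "normalize_rate",
    "match_to_truth",
]

#: Scale factor turning a median absolute deviation into a Gaussian sd.
MAD_TO_SD = 1.4826


@dataclass(frozen=True)
class GridSquare:
    index: int
    row_start: int
    row_stop: int
    col_start: int
    col_stop: int
    tile_row: int
    tile_col: int


@dataclass
class GridPartition:
    """Tessellation of the cell bounding box into analysis squares.

    Only squares overlapping the mask are retained; ``neighbors`` maps each
    retained square to its up-to-eight retained 8-connected neighbors.
    """

    square_size_px: int
    squares: tuple[GridSquare, ...]
    neighbors: dict[int, frozenset[int]]
    raster_shape: tuple[int, int]
    _lookup: np.ndarray = field(repr=False)

    @property
    def n_squares(self) -> int:
        return len(self.squares)

    def square_at(self, row: int, col: int) -> int | None:
        """Index of the retained square containing a pixel, or None."""
        h, w = self.raster_shape
        if not (0 <= row < h and 0 <= col < w):
            return None
        idx = int(self._lookup[row, col])
        return idx if idx >= 0 else None


def partition_grid(mask: np.ndarray, square_size_px: int = 10) -> GridPartition:
    """Tile the mask bounding box with squares anchored at its top-left corner.

    Edge tiles may be clipped by the raster border and partial tiles are
    retained whenever they overlap the mask.
    """
    mask = np.asarray(mask, dtype=bool)
    if mask.ndim != 2 or not mask.any():
        raise ValueError("mask must be a non-empty 2-D raster")
    if square_size_px < 2:
        raise ValueError("square_size_px must be >= 2")

    h, w = mask.shape
    rows = np.flatnonzero(mask.any(axis=1))
    cols = np.flatnonzero(mask.any(axis=0))
    r0, r1 = int(rows[0]), int(rows[-1]) + 1
    c0, c1 = int(cols[0]), int(cols[-1]) + 1
    n_tile_rows = math.ceil((r1 - r0) / square_size_px)
    n_tile_cols = math.ceil((c1 - c0) / square_size_px)

    squares: list[GridSquare] = []
    tile_index: dict[tuple[int, int], int] = {}
    lookup = np.full((h, w), -1, dtype=np.int32)
    for i in range(n_tile_rows):
        for j in range(n_tile_cols):
            rs = r0 + i * square_size_px
            re = min(rs + square_size_px, h)
            cs = c0 + j * square_size_px
            ce = min(cs + square_size_px, w)
            if not mask[rs:re, cs:ce].any():
                continue
            idx = len(squares)
            squares.append(GridSquare(idx, rs, re, cs, ce, i, j))
            tile_index[(i, j)] = idx
            lookup[rs:re, cs:ce] = idx

    neighbors: dict[int, frozenset[int]] = {}
    for (i, j), idx in tile_index.items():
        nbrs = set()
        for di in (-1, 0, 1):
            for dj in (-1, 0, 1):
                if di == 0 and dj == 0:
                    continue
                other = tile_index.get((i + di, j + dj))
                if other is not None:
                    nbrs.add(other)
        neighbors[idx] = frozenset(nbrs)

    return GridPartition(
        square_size_px=square_size_px,
        squares=tuple(squares),
        neighbors=neighbors,
        raster_shape=(h, w),
        _lookup=lookup,
    )


@dataclass
class IntensityTrace:
    """Per-frame mean intensity of one grid square."""

    square_id: int
    values: np.ndarray


def extract_traces(movie: MovieStack, grid: GridPartition) -> list[IntensityTrace]:
    """Mean intensity of each retained square per frame."""
    if movie.frame_shape != grid.raster_shape:
        raise ValueError(
            f"movie raster {movie.frame_shape} does not match grid raster "
            f"{grid.raster_shape}"
        )
    traces = []
    for sq in grid.squares:
        block = movie.data[:, sq.row_start:sq.row_stop, sq.col_start:sq.col_stop]
        traces.append(
            IntensityTrace(sq.index, block.mean(axis=(1, 2), dtype=np.float64))
        )
    return traces


@dataclass(frozen=True)
class PeakCall:
    """A candidate release event in one square's trace."""

    square_id: int
    frame: int
    amplitude: float  # peak value minus local baseline
    baseline: float


@dataclass(frozen=True)
class DetectedEvent:
    square_id: int
    frame: int
    time_s: float
    amplitude: float


@dataclass(frozen=True)
class EventRateRecord:
    """Per-condition event count normalized to events / 100 um^2 / min."""

    condition_label: str
    n_events: int
    area_um2: float
    duration_min: float
    rate: float


@dataclass(frozen=True)
class DetectionParams:
    """Tunables of the event caller.

    The rolling-median baseline window (frames), the threshold multiple
    ``k_sigma`` applied to the MAD-based robust noise sd, the minimum frame
    separation between accepted peaks in one square, and whether spillover
    comparisons use the raw per-frame peak set (default) or only surviving
    peaks.
    """

    square_size_px: int = 10
    baseline_window_frames: int = 21
    k_sigma: float = 5.0
    min_separation_frames: int = 3
    spillover_on_raw_peaks: bool = True


def detect_peaks(
    trace,
    baseline_window_frames: int = 21,
    k_sigma: float = 5.0,
    min_separation_frames: int = 3,
) -> list[PeakCall]:
    """Call peaks in one intensity trace.

    A frame is a peak iff it is a local maximum, exceeds the rolling-median
    baseline by ``k_sigma`` times the robust noise sd (1.4826 x MAD of the
    baseline-subtracted trace), and lies at least ``min_separation_frames``
    from a larger accepted peak.  Amplitude is the value minus the baseline
    at the peak frame.
    """
    square_id = int(getattr(trace, "square_id", 0))
    values = np.asarray(getattr(trace, "values", trace), dtype=np.float64)
    if values.ndim != 1:
        raise ValueError("trace must be one-dimensional")
    if not np.all(np.isfinite(values)):
        raise ValueError("trace contains non-finite values")
    if len(values) <= baseline_window_frames:
        raise ValueError("trace must be longer than the baseline window")
    if min_separation_frames < 1:
        raise ValueError("min_separation_frames must be >= 1")

    baseline = ndimage.median_filter(
        values, size=baseline_window_frames, mode="nearest"
    )
    resid = values - baseline
    sd = MAD_TO_SD * float(np.median(np.abs(resid - np.median(resid))))

    candidates, _ = _signal.find_peaks(values)
    threshold = k_sigma * sd
    cand = [
        (float(resid[i]), int(i))
        for i in candidates
        if resid[i] > threshold and resid[i] > 0
    ]
    # keep the largest peak in any min_separation neighborhood
    accepted: list[tuple[float, int]] = []
    for amp, frame in sorted(cand, key=lambda t: (-t[0], t[1])):
        if all(abs(frame - f) >= min_separation_frames for _, f in accepted):
            accepted.append((amp, frame))
    accepted.sort(key=lambda t: t[1])
    return [
        PeakCall(square_id=square_id, frame=f, amplitude=a,
                 baseline=float(baseline[f]))
        for a, f in accepted
    ]


def reject_spillover(
    peaks: Iterable[PeakCall],
    grid: GridPartition,
    frame_interval_s: float,
    use_raw_peaks: bool = True,
) -> list[DetectedEvent]:
    """Discard same-frame peaks that are spillover from a brighter neighbor.

    A peak is removed iff one of its square's eight grid neighbors has a peak
    at the exact same frame with strictly greater amplitude; equal-amplitude
    ties keep the lower square index.  With ``use_raw_peaks`` (default) the
    comparison runs against the raw peak set, so a removed peak still
    suppresses its other neighbors; otherwise only surviving peaks suppress
    (greedy by descending amplitude).
    """
    peaks = list(peaks)
    valid = {sq.index for sq in grid.squares}
    seen: set[tuple[int, int]] = set()
    for p in peaks:
        if p.square_id not in valid:
            raise ValueError(f"peak references unknown square {p.square_id}")
        key = (p.square_id, p.frame)
        if key in seen:
            raise ValueError(f"duplicate peak for square {p.square_id} frame {p.frame}")
        seen.add(key)

    by_frame: dict[int, list[PeakCall]] = {}
    for p in peaks:
        by_frame.setdefault(p.frame, []).append(p)

    def dominates(q: PeakCall, p: PeakCall) -> bool:
        return q.amplitude > p.amplitude or (
            q.amplitude == p.amplitude and q.square_id < p.square_id
        )

    survivors: list[PeakCall] = []
    for frame, group in by_frame.items():
        if use_raw_peaks:
            for p in group:
                nbrs = grid.neighbors[p.square_id]
                if not any(q.square_id in nbrs and dominates(q, p) for q in group):
                    survivors.append(p)
        else:
            kept: list[PeakCall] = []
            for p in sorted(group, key=lambda q: (-q.amplitude, q.square_id)):
                nbrs = grid.neighbors[p.square_id]
                if not any(q.square_id in nbrs for q in kept):
                    kept.append(p)
            survivors.extend(kept)

    survivors.sort(key=lambda p: (p.frame, p.square_id))
    return [
        DetectedEvent(
            square_id=p.square_id,
            frame=p.frame,
            time_s=p.frame * frame_interval_s,
            amplitude=p.amplitude,
        )
        for p in survivors
    ]


def detect_events(
    movie: MovieStack,
    mask: np.ndarray,
    params: DetectionParams | None = None,
    grid: GridPartition | None = None,
) -> tuple[list[DetectedEvent], GridPartition]:
    """Full calling chain: grid -> traces -> peaks -> spillover rejection."""
    if params is None:
        params = DetectionParams()
    if grid is None:
        grid = partition_grid(mask, params.square_size_px)
    traces = extract_traces(movie, grid)
    peaks: list[PeakCall] = []
    for trace in traces:
        peaks.extend(
            detect_peaks(
                trace,
                baseline_window_frames=params.baseline_window_frames,
                k_sigma=params.k_sigma,
                min_separation_frames=params.min_separation_frames,
            )
        )
    events = reject_spillover(
        peaks,
        grid,
        frame_interval_s=movie.acquisition.frame_interval_s,
        use_raw_peaks=params.spillover_on_raw_peaks,
    )
    return events, grid


def normalize_rate(
    n_events: int,
    area_um2: float,
    duration_s: float,
    condition_label: str = "",
) -> EventRateRecord:
    """Events per 100 um^2 per minute."""
    if n_events < 0:
        raise ValueError("n_events must be >= 0")
    if not area_um2 > 0:
        raise ValueError("area_um2 must be > 0")
    if not duration_s > 0:
        raise ValueError("duration_s must be > 0")
    duration_min = duration_s / 60.0
    rate = n_events / (area_um2 / 100.0) / duration_min
    return EventRateRecord(
        condition_label=condition_label,
        n_events=int(n_events),
        area_um2=float(area_um2),
        duration_min=float(duration_min),
        rate=float(rate),
    )


@dataclass(frozen=True)
class MatchResult:
    """Detection-vs-truth benchmark summary."""

    n_truth: int
    n_detected: int
    n_matched: int
    precision: float
    recall: float
    f1: float
    precision_defined: bool
    recall_defined: bool


def match_to_truth(
    detected: Sequence[DetectedEvent],
    truth: Sequence,
    grid: GridPartition,
    frame_tolerance: int = 2,
) -> MatchResult:
    """Greedy one-to-one matching of detections to ground-truth events.

    A detection matches a truth event iff the truth center falls in the
    detection's square or one of its eight neighbors and the frame difference
    is at most ``frame_tolerance``.  Detections are processed in (frame,
    square) order and take the unmatched candidate with the smallest frame
    difference.  When there are no detections, precision is reported as 0.0
    with ``precision_defined=False``.
    """
    truth = list(truth)
    detected = list(detected)
    truth_squares = [
        grid.square_at(int(math.floor(e.y_px + 0.5)), int(math.floor(e.x_px + 0.5)))
        for e in truth
    ]
    matched: set[int] = set()
    n_matched = 0
    for d in sorted(detected, key=lambda d: (d.frame, d.square_id)):
        allowed = {d.square_id} | set(grid.neighbors[d.square_id])
        best: tuple[int, int, int] | None = None  # (|df|, truth frame, index)
        for ti, (e, sq) in enumerate(zip(truth, truth_squares)):
            if ti in matched or sq not in allowed:
                continue
            df = abs(int(e.frame) - d.frame)
            if df > frame_tolerance:
                continue
            key = (df, int(e.frame), ti)
            if best is None or key < best:
                best = key
        if best is not None:
            matched.add(best[2])
            n_matched += 1

    n_t, n_d = len(truth), len(detected)
    precision = n_matched / n_d if n_d else 0.0
    recall = n_matched / n_t if n_t else 0.0
    f1 = (
        2 * precision * recall / (precision + recall)
        if (precision + recall) > 0
        else 0.0
    )
    return MatchResult(
        n_truth=n_t,
        n_detected=n_d,
        n_matched=n_matched,
        precision=precision,
        recall=recall,
        f1=f1,
        precision_defined=n_d > 0,
        recall_defined=n_t > 0,
    )
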