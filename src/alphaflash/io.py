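"""File formats, run configuration, and the end-to-end experiment pipeline.

Movies are multi-page 16-bit grayscale TIFF (quantization to the camera bit
depth happens only here), masks are 8-bit TIFF, events and rates are CSV with
explicit headers, nested results are JSON, and configurations are YAML.  A
run is reproducible from (config, seed) alone; every output bundle carries a
manifest naming the config hash and seed that produced it.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd
import tifffile
import yaml

from . import __version__
from .analysis import (
    ConditionWindow,
    FoldChange,
    RateTable,
    ThresholdResult,
    detect_threshold,
    fold_change,
    rates_per_condition,
    segment_conditions,
)
from .detect import (
    DetectedEvent,
    DetectionParams,
    MatchResult,
    detect_events,
    match_to_truth,
    partition_grid,
)
from .simulate import (
    AcquisitionParams,
    CellGeometry,
    DoseResponseModel,
    FlashParams,
    GroundTruthEvent,
    MovieStack,
    NoiseParams,
    Protocol,
    ProtocolStep,
    Treatment,
    ramp_protocol,
    render_movie,
    sample_events,
    single_step_protocol,
)

logger = logging.getLogger("alphaflash.io")

__all__ = [
    "read_movie",
    "write_movie",
    "read_mask",
    "write_mask",
    "truth_to_csv",
    "truth_from_csv",
    "events_to_csv",
    "events_from_csv",
    "rates_to_csv",
    "protocol_to_dict",
    "protocol_from_dict",
    "RunConfig",
    "run_experiment",
    "ExperimentResult",
    "benchmark_detection",
]

TRUTH_COLUMNS = ["event_id", "frame", "time_s", "x_px", "y_px", "amplitude"]
EVENT_COLUMNS = ["event_id", "square_id", "frame", "time_s", "amplitude"]
RATE_COLUMNS = ["condition", "n_events", "area_um2", "duration_min",
                "rate_per_100um2_min"]


# ---------------------------------------------------------------------------
# TIFF
# ---------------------------------------------------------------------------

def write_movie(stack: MovieStack, path) -> None:
    """Quantize to the camera bit depth and write a multi-page TIFF."""
    ceiling = stack.acquisition.intensity_ceiling
    data = np.clip(np.rint(stack.data), 0, ceiling).astype(np.uint16)
    tifffile.imwrite(path, data, photometric="minisblack")


def read_movie(path, acquisition: AcquisitionParams | None = None) -> MovieStack:
    """Read a single-channel multi-page TIFF into a MovieStack.

    Multi-channel / RGB files are rejected; floating-point input is accepted
    but flagged with a warning since the pipeline expects camera counts.
    """
    try:
        with tifffile.TiffFile(path) as tf:
            page = tf.pages[0]
            if page.samplesperpixel > 1 or page.photometric in (
                tifffile.PHOTOMETRIC.RGB,
                tifffile.PHOTOMETRIC.PALETTE,
            ):
                raise ValueError(
                    f"{path}: multi-channel/RGB TIFF is not supported; provide a "
                    "single-channel grayscale stack"
                )
            if "C" in tf.series[0].axes:
                raise ValueError(f"{path}: multi-channel TIFF is not supported")
            data = np.stack([p.asarray() for p in tf.pages]) \
                if len(tf.pages) > 1 else tf.series[0].asarray()
    except ValueError:
        raise
    except Exception as exc:
        raise ValueError(f"{path}: cannot read TIFF stack ({exc})") from exc

    if data.ndim == 2:
        data = data[None, :, :]
    if data.ndim != 3:
        raise ValueError(f"{path}: expected a (frames, rows, cols) stack")
    if data.dtype.kind == "f":
        logger.warning("%s: non-integer (floating point) TIFF input", path)
    if np.min(data) < 0:
        raise ValueError(f"{path}: negative intensities")
    return MovieStack(
        data=data.astype(np.float32),
        acquisition=acquisition or AcquisitionParams(),
    )


def write_mask(mask: np.ndarray, path) -> None:
    tifffile.imwrite(path, np.asarray(mask, dtype=bool).astype(np.uint8) * 255,
                     photometric="minisblack")


def read_mask(path) -> np.ndarray:
    arr = tifffile.imread(path)
    if arr.ndim != 2:
        raise ValueError(f"{path}: mask must be a single 2-D page")
    return arr > 0


# ---------------------------------------------------------------------------
# CSV
# ---------------------------------------------------------------------------

def truth_to_csv(events: Sequence[GroundTruthEvent], path) -> None:
    df = pd.DataFrame(
        [
            {
                "event_id": i,
                "frame": e.frame,
                "time_s": e.time_s,
                "x_px": e.x_px,
                "y_px": e.y_px,
                "amplitude": e.amplitude,
            }
            for i, e in enumerate(events)
        ],
        columns=TRUTH_COLUMNS,
    )
    df.to_csv(path, index=False)


def truth_from_csv(path) -> list[GroundTruthEvent]:
    df = pd.read_csv(path)
    return [
        GroundTruthEvent(
            time_s=float(r.time_s),
            frame=int(r.frame),
            x_px=float(r.x_px),
            y_px=float(r.y_px),
            amplitude=float(r.amplitude),
        )
        for r in df.itertuples()
    ]


def events_to_csv(events: Sequence[DetectedEvent], path) -> None:
    df = pd.DataFrame(
        [
            {
                "event_id": i,
                "square_id": e.square_id,
                "frame": e.frame,
                "time_s": e.time_s,
                "amplitude": e.amplitude,
            }
            for i, e in enumerate(events)
        ],
        columns=EVENT_COLUMNS,
    )
    df.to_csv(path, index=False)


def events_from_csv(path) -> list[DetectedEvent]:
    df = pd.read_csv(path)
    return [
        DetectedEvent(
            square_id=int(r.square_id),
            frame=int(r.frame),
            time_s=float(r.time_s),
            amplitude=float(r.amplitude),
        )
        for r in df.itertuples()
    ]


def rates_to_csv(table: RateTable, path) -> None:
    table.to_frame().to_csv(path, index=False)


# ---------------------------------------------------------------------------
# YAML configuration
# ---------------------------------------------------------------------------

def protocol_to_dict(protocol: Protocol) -> dict:
    return {
        "label": protocol.label,
        "steps": [
            {
                "glucose_mM": s.glucose_mM,
                "duration_s": s.duration_s,
                "treatment": s.treatment.value,
                **({"gka_conc_uM": s.gka_conc_uM} if s.gka_conc_uM else {}),
                **({"label": s.label} if s.label else {}),
            }
            for s in protocol.steps
        ],
    }


def protocol_from_dict(d: dict) -> Protocol:
    steps = tuple(
        ProtocolStep(
            glucose_mM=float(s["glucose_mM"]),
            duration_s=float(s["duration_s"]),
            treatment=Treatment(s.get("treatment", "none")),
            gka_conc_uM=float(s.get("gka_conc_uM", 0.0)),
            label=s.get("label"),
        )
        for s in d["steps"]
    )
    return Protocol(steps=steps, label=d.get("label", ""))


@dataclass(frozen=True)
class RunConfig:
    """Everything needed to reproduce an experiment from a seed.

    The cell footprint is a disc of ``radius_px`` on a ``frame_shape`` raster
    unless ``mask_path`` points to a TIFF mask.
    """

    acquisition: AcquisitionParams = field(default_factory=AcquisitionParams)
    model: DoseResponseModel = field(default_factory=DoseResponseModel)
    flash: FlashParams = field(default_factory=FlashParams)
    noise: NoiseParams = field(default_factory=NoiseParams)
    detection: DetectionParams = field(default_factory=DetectionParams)
    protocol: Protocol = field(default_factory=ramp_protocol)
    frame_shape: tuple[int, int] = (64, 64)
    radius_px: float = 30.0
    mask_path: str | None = None
    n_cells: int = 8
    label: str = "experiment"

    def build_geometry(self) -> CellGeometry:
        if self.mask_path:
            return CellGeometry(read_mask(self.mask_path),
                                self.acquisition.pixel_size_um)
        return CellGeometry.disc(
            shape=self.frame_shape,
            radius_px=self.radius_px,
            pixel_size_um=self.acquisition.pixel_size_um,
        )

    def to_dict(self) -> dict:
        return {
            "label": self.label,
            "n_cells": self.n_cells,
            "acquisition": {
                "pixel_size_um": self.acquisition.pixel_size_um,
                "frame_interval_s": self.acquisition.frame_interval_s,
                "bit_depth": self.acquisition.bit_depth,
            },
            "geometry": {
                "frame_shape": list(self.frame_shape),
                "radius_px": self.radius_px,
                "mask_path": self.mask_path,
            },
            "model": {
                "r_inhib": self.model.r_inhib,
                "r_stim": self.model.r_stim,
                "stim_range_mM": list(self.model.stim_range_mM),
                "zero_glucose_suppressed": self.model.zero_glucose_suppressed,
                "genotype": self.model.genotype,
                "r_kd": self.model.r_kd,
            },
            "flash": {
                "amplitude_mean": self.flash.amplitude_mean,
                "amplitude_cv": self.flash.amplitude_cv,
                "decay_tau_s": self.flash.decay_tau_s,
                "psf_sigma_um": self.flash.psf_sigma_um,
            },
            "noise": {
                "background_level": self.noise.background_level,
                "read_noise_sd": self.noise.read_noise_sd,
                "shot_noise": self.noise.shot_noise,
                "bleach_rate_per_s": self.noise.bleach_rate_per_s,
            },
            "detection": {
                "square_size_px": self.detection.square_size_px,
                "baseline_window_frames": self.detection.baseline_window_frames,
                "k_sigma": self.detection.k_sigma,
                "min_separation_frames": self.detection.min_separation_frames,
                "spillover_on_raw_peaks": self.detection.spillover_on_raw_peaks,
            },
            "protocol": protocol_to_dict(self.protocol),
        }

    @classmethod
    def from_dict(cls, d: dict) -> "RunConfig":
        geo = d.get("geometry", {})
        return cls(
            acquisition=AcquisitionParams(**d.get("acquisition", {})),
            model=DoseResponseModel(
                **{
                    **d.get("model", {}),
                    "stim_range_mM": tuple(
                        d.get("model", {}).get("stim_range_mM", (1.0, 3.0))
                    ),
                }
            ),
            flash=FlashParams(**d.get("flash", {})),
            noise=NoiseParams(**d.get("noise", {})),
            detection=DetectionParams(**d.get("detection", {})),
            protocol=protocol_from_dict(d["protocol"]) if "protocol" in d
            else ramp_protocol(),
            frame_shape=tuple(geo.get("frame_shape", (64, 64))),
            radius_px=float(geo.get("radius_px", 30.0)),
            mask_path=geo.get("mask_path"),
            n_cells=int(d.get("n_cells", 8)),
            label=d.get("label", "experiment"),
        )

    def to_yaml(self, path=None) -> str:
        text = yaml.safe_dump(self.to_dict(), sort_keys=True)
        if path is not None:
            Path(path).write_text(text)
        return text

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        return cls.from_dict(yaml.safe_load(Path(path).read_text()))

    def config_hash(self) -> str:
        return hashlib.sha256(self.to_yaml().encode()).hexdigest()[:16]


# ---------------------------------------------------------------------------
# End-to-end pipeline
# ---------------------------------------------------------------------------

@dataclass
class ExperimentResult:
    """Bundle produced by :func:`run_experiment`."""

    config: RunConfig
    seed: int
    rates: pd.DataFrame  # long: cell, condition, glucose_mM, treatment, rate, ...
    threshold: ThresholdResult | None
    fold: FoldChange | None
    manifest: dict
    truth_by_cell: list[list[GroundTruthEvent]]
    events_by_cell: list[list[DetectedEvent]]


def _plain_glucose_rates(rates: pd.DataFrame) -> pd.DataFrame:
    plain = rates[(rates["treatment"] == Treatment.NONE.value)
                  & (~rates["is_washout"])]
    return plain[["cell", "glucose_mM", "rate"]]


def run_experiment(config: RunConfig, seed: int, out_dir=None) -> ExperimentResult:
    """Simulate, detect and analyse a full multi-cell experiment.

    Per cell: sample ground-truth events for the configured protocol, render
    the movie, call events, and compute per-condition rates.  Across cells:
    fold change between stimulatory and inhibitory glucose, and the
    glucose-threshold analysis when at least two treatment-free glucose
    levels were recorded.  Deterministic for fixed (config, seed); artifacts
    plus a manifest are written when ``out_dir`` is given.
    """
    geometry = config.build_geometry()
    acq = config.acquisition
    protocol = config.protocol
    n_frames = protocol.n_frames(acq)
    windows = segment_conditions(protocol, acq, n_frames)

    out_path = Path(out_dir) if out_dir is not None else None
    if out_path is not None:
        out_path.mkdir(parents=True, exist_ok=True)
        write_mask(geometry.mask, out_path / "mask.tif")
        config.to_yaml(out_path / "config.yaml")

    cell_seeds = np.random.SeedSequence(seed).spawn(config.n_cells)
    rows = []
    truth_by_cell: list[list[GroundTruthEvent]] = []
    events_by_cell: list[list[DetectedEvent]] = []
    for ci, cs in enumerate(cell_seeds):
        ev_seed, noise_seed = cs.spawn(2)
        truth = sample_events(config.model, protocol, geometry, acq, ev_seed,
                              config.flash)
        movie = render_movie(truth, geometry, acq, config.flash, config.noise,
                             n_frames, noise_seed)
        events, _grid = detect_events(movie, geometry.mask, config.detection)
        table = rates_per_condition(events, windows, geometry.area_um2)
        logger.info(
            "cell %d: %d true events, %d detected (%d washout, %d unassigned)",
            ci, len(truth), len(events), table.n_washout_events,
            table.n_unassigned_events,
        )
        window_by_label = {w.label: w for w in windows}
        for rec in table.records:
            w = window_by_label[rec.condition_label]
            rows.append(
                {
                    "cell": ci,
                    "condition": rec.condition_label,
                    "glucose_mM": w.glucose_mM,
                    "treatment": w.treatment.value,
                    "is_washout": w.is_washout,
                    "n_events": rec.n_events,
                    "area_um2": rec.area_um2,
                    "duration_min": rec.duration_min,
                    "rate": rec.rate,
                }
            )
        truth_by_cell.append(truth)
        events_by_cell.append(events)
        if out_path is not None:
            write_movie(movie, out_path / f"cell{ci:02d}_movie.tif")
            truth_to_csv(truth, out_path / f"cell{ci:02d}_truth.csv")
            events_to_csv(events, out_path / f"cell{ci:02d}_events.csv")
        del movie

    rates = pd.DataFrame(rows)

    threshold: ThresholdResult | None = None
    plain = _plain_glucose_rates(rates)
    if plain["glucose_mM"].nunique() >= 2 and config.n_cells >= 2:
        threshold = detect_threshold(plain)

    fold: FoldChange | None = None
    lo, hi = config.model.stim_range_mM
    stim_labels = {
        r["condition"] for r in rows
        if r["treatment"] == "none" and not r["is_washout"]
        and lo <= r["glucose_mM"] <= hi
    }
    inhib_labels = {
        r["condition"] for r in rows
        if r["treatment"] == "none" and not r["is_washout"]
        and r["glucose_mM"] > hi
    }
    if stim_labels and inhib_labels:
        from .detect import EventRateRecord  # local alias for clarity

        records = [
            EventRateRecord(r["condition"], r["n_events"], r["area_um2"],
                            r["duration_min"], r["rate"])
            for r in rows
        ]
        fold = fold_change(records, stim_labels, inhib_labels)

    manifest = {
        "package": "alphaflash",
        "version": __version__,
        "config_hash": config.config_hash(),
        "seed": int(seed),
        "n_cells": config.n_cells,
        "n_frames": n_frames,
        "area_um2": geometry.area_um2,
        "total_true_events": int(sum(len(t) for t in truth_by_cell)),
        "total_detected_events": int(sum(len(e) for e in events_by_cell)),
        "fold_change": None if fold is None else fold.ratio,
        "regulated": None if threshold is None else threshold.regulated,
    }
    if out_path is not None:
        rates.to_csv(out_path / "rates.csv", index=False)
        if threshold is not None:
            (out_path / "threshold.json").write_text(
                json.dumps(threshold.to_dict(), indent=2, sort_keys=True)
            )
        (out_path / "manifest.json").write_text(
            json.dumps(manifest, indent=2, sort_keys=True)
        )

    return ExperimentResult(
        config=config,
        seed=int(seed),
        rates=rates,
        threshold=threshold,
        fold=fold,
        manifest=manifest,
        truth_by_cell=truth_by_cell,
        events_by_cell=events_by_cell,
    )


# ---------------------------------------------------------------------------
# Detection benchmark
# ---------------------------------------------------------------------------

def benchmark_detection(
    n_movies: int = 20,
    seed: int = 0,
    config: RunConfig | None = None,
    frame_tolerance: int = 2,
) -> dict:
    """Precision/recall/F1 of the event caller against ground truth.

    Renders ``n_movies`` independent movies of a single stimulatory-glucose
    step under the configured (default) noise and pools matches across
    movies.
    """
    if config is None:
        config = RunConfig(protocol=single_step_protocol(2.0, duration_s=180.0),
                           n_cells=1, label="benchmark")
    geometry = config.build_geometry()
    acq = config.acquisition
    n_frames = config.protocol.n_frames(acq)
    grid = partition_grid(geometry.mask, config.detection.square_size_px)

    tp = fp = fn = 0
    movie_seeds = np.random.SeedSequence(seed).spawn(n_movies)
    for ms in movie_seeds:
        ev_seed, noise_seed = ms.spawn(2)
        truth = sample_events(config.model, config.protocol, geometry, acq,
                              ev_seed, config.flash)
        movie = render_movie(truth, geometry, acq, config.flash, config.noise,
                             n_frames, noise_seed)
        events, _ = detect_events(movie, geometry.mask, config.detection,
                                  grid=grid)
        m = match_to_truth(events, truth, grid, frame_tolerance)
        tp += m.n_matched
        fp += m.n_detected - m.n_matched
        fn += m.n_truth - m.n_matched

    precision = tp / (tp + fp) if (tp + fp) else 0.0
    recall = tp / (tp + fn) if (tp + fn) else 0.0
    f1 = (2 * precision * recall / (precision + recall)
          if (precision + recall) else 0.0)
    return {
        "n_movies": n_movies,
        "n_truth": tp + fn,
        "n_detected": tp + fp,
        "precision": precision,
        "recall": recall,
        "f1": f1,
    }
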