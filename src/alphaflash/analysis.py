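"""Protocol-level analysis: condition windows, rates, fold change, threshold.

Maps detected events onto the ordered condition steps of a perifusion
protocol, computes the normalized secretion rate per condition, the fold
change between stimulatory and inhibitory glucose, and — across a panel of
cells that each ran the full glucose ramp — the glucose threshold of
stimulation via repeated-measures ANOVA followed by Scheffé comparisons
against the highest (reference) glucose level.
"""

from __future__ import annotations

import logging
import math
import warnings
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd

from .detect import DetectedEvent, EventRateRecord, normalize_rate
from .simulate import (
    FRAME_COUNT_EPS,
    AcquisitionParams,
    Protocol,
    Treatment,
)
from .stats import AnovaResult, GroupSample, TestResult, one_way_anova, \
    repeated_measures_anova, scheffe_posthoc

logger = logging.getLogger("alphaflash.analysis")

__all__ = [
    "ConditionWindow",
    "RateTable",
    "FoldChange",
    "ThresholdResult",
    "segment_conditions",
    "rates_per_condition",
    "fold_change",
    "detect_threshold",
]


@dataclass(frozen=True)
class ConditionWindow:
    """Half-open frame window [frame_start, frame_end) of one condition."""

    label: str
    glucose_mM: float
    treatment: Treatment
    frame_start: int
    frame_end: int
    duration_min: float
    is_washout: bool

    @property
    def n_frames(self) -> int:
        return self.frame_end - self.frame_start


def _step_label(step, index: int, used: set[str]) -> str:
    if step.label:
        base = step.label
    else:
        base = f"{step.glucose_mM:g}mM"
        if step.treatment is Treatment.WASHOUT:
            base = f"washout_{base}"
        elif step.treatment is not Treatment.NONE:
            base = f"{base}+{step.treatment.value}"
            if step.treatment is Treatment.GKA:
                base = f"{base}{step.gka_conc_uM:g}uM"
    label = base
    suffix = 2
    while label in used:
        label = f"{base}#{suffix}"
        suffix += 1
    used.add(label)
    return label


def segment_conditions(
    protocol: Protocol,
    acquisition: AcquisitionParams,
    n_frames: int,
) -> list[ConditionWindow]:
    """Convert protocol steps into frame windows.

    Step durations are floored to whole frames; windows are consecutive and
    half-open.  Washout windows are produced but flagged so that downstream
    rate analysis can exclude them.
    """
    dt = acquisition.frame_interval_s
    windows: list[ConditionWindow] = []
    used: set[str] = set()
    start = 0
    for i, step in enumerate(protocol.steps):
        frames = int(step.duration_s / dt + FRAME_COUNT_EPS)
        end = start + frames
        windows.append(
            ConditionWindow(
                label=_step_label(step, i, used),
                glucose_mM=float(step.glucose_mM),
                treatment=step.treatment,
                frame_start=start,
                frame_end=end,
                duration_min=frames * dt / 60.0,
                is_washout=step.is_washout,
            )
        )
        start = end
    if start > n_frames:
        raise ValueError(
            f"protocol covers {start} frames but the movie has only {n_frames}"
        )
    return windows


@dataclass
class RateTable:
    """Per-condition rates plus the washout / unassigned event tallies."""

    records: list[EventRateRecord]
    n_washout_events: int
    n_unassigned_events: int

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            [
                {
                    "condition": r.condition_label,
                    "n_events": r.n_events,
                    "area_um2": r.area_um2,
                    "duration_min": r.duration_min,
                    "rate_per_100um2_min": r.rate,
                }
                for r in self.records
            ]
        )


def rates_per_condition(
    events: Sequence[DetectedEvent],
    windows: Sequence[ConditionWindow],
    area_um2: float,
) -> RateTable:
    """Assign events to windows by frame membership and normalize rates.

    Events in washout windows are counted separately and excluded; events
    outside every window go to an "unassigned" tally with a warning.
    """
    counts = {w.label: 0 for w in windows}
    n_washout = 0
    n_unassigned = 0
    for e in events:
        for w in windows:
            if w.frame_start <= e.frame < w.frame_end:
                if w.is_washout:
                    n_washout += 1
                else:
                    counts[w.label] += 1
                break
        else:
            n_unassigned += 1
    if n_unassigned:
        warnings.warn(
            f"{n_unassigned} detected event(s) fall outside all protocol windows",
            stacklevel=2,
        )

    records = [
        normalize_rate(
            counts[w.label],
            area_um2,
            duration_s=w.duration_min * 60.0,
            condition_label=w.label,
        )
        for w in windows
        if not w.is_washout
    ]
    return RateTable(records=records, n_washout_events=n_washout,
                     n_unassigned_events=n_unassigned)


@dataclass(frozen=True)
class FoldChange:
    ratio: float
    defined: bool
    stim_mean: float
    inhib_mean: float


def fold_change(
    records: Sequence[EventRateRecord],
    stim_labels: Sequence[str],
    inhib_labels: Sequence[str],
) -> FoldChange:
    """Mean stimulated rate over mean inhibited rate.

    Records may pool several cells; the means run over every record whose
    condition label is in the respective set.  A zero inhibitory mean flags
    the ratio undefined (NaN).
    """
    stim = set(stim_labels)
    inhib = set(inhib_labels)
    if not stim or not inhib:
        raise ValueError("stimulatory and inhibitory label sets must be non-empty")
    if stim & inhib:
        raise ValueError("stimulatory and inhibitory label sets must be disjoint")
    stim_rates = [r.rate for r in records if r.condition_label in stim]
    inhib_rates = [r.rate for r in records if r.condition_label in inhib]
    if not stim_rates or not inhib_rates:
        raise ValueError("no records found for one of the label sets")
    stim_mean = float(np.mean(stim_rates))
    inhib_mean = float(np.mean(inhib_rates))
    if inhib_mean == 0.0:
        return FoldChange(math.nan, False, stim_mean, inhib_mean)
    return FoldChange(stim_mean / inhib_mean, True, stim_mean, inhib_mean)


@dataclass(frozen=True)
class ThresholdResult:
    """Outcome of the glucose-threshold analysis across a cell panel.

    ``stimulatory_set`` lists the glucose concentrations whose rate is
    significantly elevated over the reference (highest) concentration;
    ``threshold_interval_mM`` brackets the threshold between the highest
    stimulatory and the lowest non-stimulatory concentration above it, never
    interpolating; ``regulated`` is False when the omnibus ANOVA finds no
    difference between concentrations at all (the knockdown phenotype).
    """

    stimulatory_set: tuple[float, ...]
    threshold_interval_mM: tuple[float, float] | None
    regulated: bool
    anova: AnovaResult
    scheffe: tuple[TestResult, ...]
    reference_mM: float
    alpha: float

    def to_dict(self) -> dict:
        return {
            "stimulatory_set": list(self.stimulatory_set),
            "threshold_interval": (
                list(self.threshold_interval_mM)
                if self.threshold_interval_mM is not None
                else None
            ),
            "regulated": bool(self.regulated),
            "reference_mM": self.reference_mM,
            "alpha": self.alpha,
            "anova": {
                "F": self.anova.statistic,
                "df1": self.anova.df[0],
                "df2": self.anova.df[1],
                "p": self.anova.p_value,
                "method": self.anova.method,
            },
            "scheffe": [
                {
                    "pair": list(t.labels),
                    "statistic": t.statistic,
                    "p": t.p_value,
                    "significant": bool(t.significant),
                }
                for t in self.scheffe
            ],
        }


def detect_threshold(
    rates: pd.DataFrame,
    alpha: float = 0.05,
    reference_mM: float | None = None,
    anova: str = "repeated",
) -> ThresholdResult:
    """Find the glucose threshold of stimulation from per-cell rates.

    ``rates`` is a long table with columns ``cell``, ``glucose_mM`` and
    ``rate`` (one row per cell and glucose level, treatment-free steps only).
    An omnibus ANOVA across glucose levels (repeated-measures by default,
    ``anova="oneway"`` for independent groups) is followed by Scheffé
    comparisons of every level against the reference concentration (the
    highest level unless given); levels significantly *above* the reference
    form the stimulatory set.
    """
    required = {"cell", "glucose_mM", "rate"}
    if not required.issubset(rates.columns):
        raise ValueError(f"rates table needs columns {sorted(required)}")
    if anova not in ("repeated", "oneway"):
        raise ValueError(f"unknown anova variant {anova!r}")

    pivot = rates.pivot_table(index="cell", columns="glucose_mM", values="rate")
    if pivot.isna().any().any():
        raise ValueError("every cell must have a rate for every glucose level")
    levels = sorted(float(c) for c in pivot.columns)
    if len(levels) < 2:
        raise ValueError("need at least two glucose levels")
    if len(pivot) < 2:
        raise ValueError("need at least two cells")

    data = pivot[levels].to_numpy(dtype=float)
    if anova == "repeated":
        omnibus = repeated_measures_anova(data)
    else:
        omnibus = one_way_anova(
            [GroupSample(f"{l:g}mM", data[:, i]) for i, l in enumerate(levels)]
        )

    groups = [GroupSample(f"{l:g}", data[:, i]) for i, l in enumerate(levels)]
    ref = float(reference_mM) if reference_mM is not None else max(levels)
    if ref not in levels:
        raise ValueError(f"reference level {ref} mM was not tested")
    ref_idx = levels.index(ref)

    pairwise = scheffe_posthoc(groups, omnibus.ms_error, omnibus.df_error, alpha)
    vs_ref = [
        t for t in pairwise if groups[ref_idx].label in t.labels
    ]
    ref_mean = groups[ref_idx].mean
    stimulatory = []
    for t in vs_ref:
        other_label = t.labels[0] if t.labels[1] == groups[ref_idx].label else t.labels[1]
        other_idx = next(i for i, g in enumerate(groups) if g.label == other_label)
        if t.significant and groups[other_idx].mean > ref_mean:
            stimulatory.append(levels[other_idx])
    stimulatory.sort(reverse=True)

    regulated = bool(omnibus.p_value < alpha)
    interval = None
    if stimulatory:
        hi_stim = max(stimulatory)
        above = [l for l in levels if l > hi_stim]
        if above:
            interval = (hi_stim, min(above))
    logger.info(
        "threshold analysis: regulated=%s stimulatory=%s interval=%s (F=%.3g, p=%.3g)",
        regulated, stimulatory, interval, omnibus.statistic, omnibus.p_value,
    )
    return ThresholdResult(
        stimulatory_set=tuple(stimulatory),
        threshold_interval_mM=interval,
        regulated=regulated,
        anova=omnibus,
        scheffe=tuple(vs_ref),
        reference_mM=ref,
        alpha=alpha,
    )
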