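"""Synthetic single-cell TIRF movies of pHluorin-labelled glucagon granule fusion.

Pancreatic alpha cells secrete glucagon when extracellular glucose falls into
the hypoglycaemic range.  In a TIRF recording of a single alpha cell
expressing a glucagon-pHluorin biosensor, each granule fusion appears as a
sudden, spatially localized flash of fluorescence that decays over a few
hundred milliseconds.  This module generates such recordings with known
ground truth so that every downstream stage (event calling, rate
normalization, dose-response statistics) can be validated end to end:

* a dose-response model mapping glucose concentration and pharmacological
  treatment to a secretion rate in events / 100 um^2 / min,
* a homogeneous Poisson event sampler over a protocol of condition steps,
* a frame-by-frame renderer (Gaussian point-spread flash, exponential decay,
  camera background, photon shot noise, Gaussian read noise, slow bleaching).

All randomness flows through :func:`numpy.random.default_rng`, so any run is
reproducible from its seed.
"""

from __future__ import annotations

import enum
import math
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np

__all__ = [
    "Treatment",
    "AcquisitionParams",
    "CellGeometry",
    "ProtocolStep",
    "Protocol",
    "DoseResponseModel",
    "FlashParams",
    "NoiseParams",
    "GroundTruthEvent",
    "MovieStack",
    "event_rate_at",
    "sample_events",
    "render_movie",
    "ramp_protocol",
    "inhibitor_protocol",
    "gka_series_protocol",
    "single_step_protocol",
]

# ---------------------------------------------------------------------------
# Defaults (acquisition geometry of the imaging setup being emulated)
# ---------------------------------------------------------------------------

DEFAULT_PIXEL_SIZE_UM = 0.277  # camera pixel in the object plane, 4x binned
DEFAULT_FRAME_INTERVAL_S = 0.09  # 90 ms exposure, streamed acquisition
DEFAULT_BIT_DEPTH = 16

#: Effective glucose shift (mM) produced by a glucokinase activator: with the
#: activator bound, 3 mM glucose is metabolized like >=4 mM, so release is
#: inhibited one step earlier.  Concentration-independent over the tested
#: 0.1-10 uM range.
GKA_GLUCOSE_SHIFT_MM = 1.0

#: Guard against binary-float duration/interval ratios landing a hair under
#: an integer frame count (e.g. 180 s / 0.09 s).
FRAME_COUNT_EPS = 1e-9


class Treatment(str, enum.Enum):
    """Pharmacological condition applied during a protocol step."""

    NONE = "none"
    ARGININE_10MM = "arginine_10mM"
    MANNOHEPTULOSE_10MM = "mannoheptulose_10mM"
    DEOXYGLUCOSE_10MM = "deoxyglucose_10mM"
    THIOGLUCOSE_10MM = "thioglucose_10mM"
    GKA = "gka"
    WASHOUT = "washout"


#: Glycolysis inhibitors acting downstream of glucokinase; they lower the
#: metabolic flux so that normally inhibitory glucose acts stimulatory.
GLYCOLYSIS_INHIBITORS = frozenset(
    {Treatment.DEOXYGLUCOSE_10MM, Treatment.THIOGLUCOSE_10MM}
)


@dataclass(frozen=True)
class AcquisitionParams:
    """Camera/optics metadata attached to every movie.

    Parameters
    ----------
    pixel_size_um
        Length of one pixel in the object plane (um); camera binning is
        absorbed into this number.
    frame_interval_s
        Seconds between consecutive frames.
    bit_depth
        Integer intensity ceiling of the camera (intensities are clipped to
        ``[0, 2**bit_depth - 1]`` when quantized).
    """

    pixel_size_um: float = DEFAULT_PIXEL_SIZE_UM
    frame_interval_s: float = DEFAULT_FRAME_INTERVAL_S
    bit_depth: int = DEFAULT_BIT_DEPTH

    def __post_init__(self) -> None:
        if not self.pixel_size_um > 0:
            raise ValueError("pixel_size_um must be > 0")
        if not self.frame_interval_s > 0:
            raise ValueError("frame_interval_s must be > 0")
        if not (1 <= int(self.bit_depth) <= 32):
            raise ValueError("bit_depth must be between 1 and 32")

    @property
    def intensity_ceiling(self) -> float:
        return float(2 ** self.bit_depth - 1)


@dataclass(frozen=True)
class CellGeometry:
    """Binary footprint of the analysed cell on the pixel raster."""

    mask: np.ndarray
    pixel_size_um: float = DEFAULT_PIXEL_SIZE_UM

    def __post_init__(self) -> None:
        mask = np.asarray(self.mask, dtype=bool)
        if mask.ndim != 2:
            raise ValueError("mask must be a 2-D raster")
        if not mask.any():
            raise ValueError("mask must contain at least one pixel")
        if not self.pixel_size_um > 0:
            raise ValueError("pixel_size_um must be > 0")
        object.__setattr__(self, "mask", mask)

    @property
    def area_um2(self) -> float:
        """Footprint area: pixel count times pixel_size_um squared."""
        return float(self.mask.sum()) * self.pixel_size_um ** 2

    @classmethod
    def disc(
        cls,
        shape: tuple[int, int] = (64, 64),
        radius_px: float = 30.0,
        center: tuple[float, float] | None = None,
        pixel_size_um: float = DEFAULT_PIXEL_SIZE_UM,
    ) -> "CellGeometry":
        """Circular footprint, the default stand-in for a well-spread cell."""
        h, w = shape
        if center is None:
            center = ((h - 1) / 2.0, (w - 1) / 2.0)
        rr, cc = np.mgrid[0:h, 0:w]
        mask = (rr - center[0]) ** 2 + (cc - center[1]) ** 2 <= radius_px ** 2
        return cls(mask=mask, pixel_size_um=pixel_size_um)


@dataclass(frozen=True)
class ProtocolStep:
    """One perifusion condition: glucose level, treatment, duration."""

    glucose_mM: float
    duration_s: float
    treatment: Treatment = Treatment.NONE
    gka_conc_uM: float = 0.0
    label: str | None = None

    def __post_init__(self) -> None:
        if self.glucose_mM < 0:
            raise ValueError("glucose_mM must be >= 0")
        if not self.duration_s > 0:
            raise ValueError("duration_s must be > 0")
        treatment = Treatment(self.treatment)
        object.__setattr__(self, "treatment", treatment)
        if treatment is Treatment.GKA:
            if not self.gka_conc_uM > 0:
                raise ValueError("GKA steps need gka_conc_uM > 0")
        elif self.gka_conc_uM != 0.0:
            raise ValueError("gka_conc_uM is only meaningful for GKA steps")

    @property
    def is_washout(self) -> bool:
        return self.treatment is Treatment.WASHOUT


@dataclass(frozen=True)
class Protocol:
    """Ordered sequence of condition steps applied during one recording."""

    steps: tuple[ProtocolStep, ...]
    label: str = ""

    def __post_init__(self) -> None:
        steps = tuple(self.steps)
        if not steps:
            raise ValueError("protocol must contain at least one step")
        object.__setattr__(self, "steps", steps)

    @property
    def total_duration_s(self) -> float:
        return float(sum(s.duration_s for s in self.steps))

    def n_frames(self, acquisition: AcquisitionParams) -> int:
        """Total whole frames covered by the protocol (per-step floor)."""
        return int(
            sum(
                int(s.duration_s / acquisition.frame_interval_s + FRAME_COUNT_EPS)
                for s in self.steps
            )
        )


@dataclass(frozen=True)
class DoseResponseModel:
    """Glucose -> secretion-rate mapping with treatment modifiers.

    Rates are in events / 100 um^2 / min.  The wildtype cell secretes at
    ``r_stim`` when the effectively sensed glucose lies in ``stim_range_mM``
    (hypoglycaemia), at ``r_inhib`` at or above 4 mM, and — because glucose-free
    buffer collapses the ATP/ADP ratio — again at ``r_inhib`` at 0 mM when
    ``zero_glucose_suppressed``.  A glucokinase-knockdown cell secretes at the
    flat intermediate rate ``r_kd`` at every glucose concentration.
    """

    r_inhib: float = 1.0
    r_stim: float = 2.0
    stim_range_mM: tuple[float, float] = (1.0, 3.0)
    zero_glucose_suppressed: bool = True
    genotype: str = "wildtype"
    r_kd: float = 1.5

    def __post_init__(self) -> None:
        if not (self.r_stim > self.r_inhib > 0):
            raise ValueError("need r_stim > r_inhib > 0")
        lo, hi = self.stim_range_mM
        if not (0 <= lo <= hi):
            raise ValueError("stim_range_mM must be an ordered non-negative pair")
        object.__setattr__(self, "stim_range_mM", (float(lo), float(hi)))
        if self.genotype not in ("wildtype", "gk_knockdown"):
            raise ValueError(f"unknown genotype {self.genotype!r}")
        if self.genotype == "gk_knockdown" and not (
            self.r_inhib < self.r_kd < self.r_stim
        ):
            raise ValueError("need r_inhib < r_kd < r_stim for gk_knockdown")


def event_rate_at(model: DoseResponseModel, step: ProtocolStep) -> float:
    """Secretion rate (events / 100 um^2 / min) for one protocol step.

    Treatment modifiers act through an *effective sensed glucose*:

    * glycolysis inhibitors (2-deoxy-glucose, 5-thio-glucose) cut the flux so
      any non-zero glucose is sensed as stimulatory,
    * a glucokinase activator shifts sensing up by ``GKA_GLUCOSE_SHIFT_MM``
      (3 mM then inhibits like 4 mM), irrespective of concentration within
      the tested range,
    * mannoheptulose cannot enter rat alpha cells (no GLUT2) and has no
      effect,
    * arginine depolarizes directly and stimulates regardless of glucose —
      including under glucokinase knockdown, which otherwise pins the rate at
      ``r_kd``.

    Washout steps have no defined analysis rate and are rejected.
    """
    if step.treatment is Treatment.WASHOUT:
        raise ValueError("washout steps are excluded from rate analysis")
    if step.glucose_mM < 0:
        raise ValueError("glucose_mM must be >= 0")

    if step.treatment is Treatment.ARGININE_10MM:
        return model.r_stim
    if model.genotype == "gk_knockdown":
        return model.r_kd

    lo, hi = model.stim_range_mM
    g = float(step.glucose_mM)
    if step.treatment in GLYCOLYSIS_INHIBITORS:
        effective = min(g, hi) if g > 0 else 0.0
    elif step.treatment is Treatment.GKA:
        effective = g + GKA_GLUCOSE_SHIFT_MM
    elif step.treatment in (Treatment.NONE, Treatment.MANNOHEPTULOSE_10MM):
        effective = g
    else:  # pragma: no cover - enum is closed
        raise ValueError(f"unknown treatment {step.treatment!r}")

    if effective > hi:
        return model.r_inhib
    if effective >= lo:
        return model.r_stim
    # below the stimulatory range: suppressed by default (glucose-free buffer
    # lowers ATP/ADP further and re-activates KATP channels)
    return model.r_inhib if model.zero_glucose_suppressed else model.r_stim


def _step_rate(model: DoseResponseModel, step: ProtocolStep) -> float:
    # Washouts are rendered at the inhibited baseline but never analysed.
    if step.is_washout:
        return model.r_inhib
    return event_rate_at(model, step)


@dataclass(frozen=True)
class FlashParams:
    """Morphology of a single fusion flash.

    The flash rises within one frame, peaks at an amplitude drawn from a
    lognormal distribution with mean ``amplitude_mean`` and coefficient of
    variation ``amplitude_cv``, spreads as a 2-D Gaussian of sd
    ``psf_sigma_um``, and decays exponentially with ``decay_tau_s``.
    Defaults: tau = 0.27 s (three frames), amplitude_mean = 8x the default
    read-noise sd, psf sigma 0.4 um (~1.4 px) so that flashes near square
    borders bleed measurably into the neighboring grid squares.
    """

    amplitude_mean: float = 160.0
    amplitude_cv: float = 0.3
    decay_tau_s: float = 0.27
    psf_sigma_um: float = 0.4

    def __post_init__(self) -> None:
        for name in ("amplitude_mean", "amplitude_cv", "decay_tau_s", "psf_sigma_um"):
            if not getattr(self, name) > 0:
                raise ValueError(f"{name} must be > 0")


@dataclass(frozen=True)
class NoiseParams:
    """Camera noise model: constant background with slow linear bleaching,
    optional Poisson shot noise on the total signal, Gaussian read noise."""

    background_level: float = 50.0
    read_noise_sd: float = 20.0
    shot_noise: bool = True
    bleach_rate_per_s: float = 1e-4

    def __post_init__(self) -> None:
        if self.background_level < 0:
            raise ValueError("background_level must be >= 0")
        if self.read_noise_sd < 0:
            raise ValueError("read_noise_sd must be >= 0")
        if self.bleach_rate_per_s < 0:
            raise ValueError("bleach_rate_per_s must be >= 0")

    @classmethod
    def noiseless(cls) -> "NoiseParams":
        return cls(background_level=0.0, read_noise_sd=0.0, shot_noise=False,
                   bleach_rate_per_s=0.0)


@dataclass(frozen=True)
class GroundTruthEvent:
    """A simulated fusion event: onset time/frame, sub-pixel center, peak
    amplitude.  ``x_px`` is the column coordinate, ``y_px`` the row."""

    time_s: float
    frame: int
    x_px: float
    y_px: float
    amplitude: float


@dataclass
class MovieStack:
    """Frames x rows x cols fluorescence stack plus acquisition metadata.

    Intensities are kept in floating point internally; quantization to the
    camera bit depth happens only when writing to TIFF.
    """

    data: np.ndarray
    acquisition: AcquisitionParams = field(default_factory=AcquisitionParams)

    def __post_init__(self) -> None:
        data = np.asarray(self.data)
        if data.ndim != 3 or data.shape[0] < 1:
            raise ValueError("movie data must be (n_frames, n_rows, n_cols)")
        if np.min(data) < 0:
            raise ValueError("intensities must be >= 0")
        self.data = data

    @property
    def n_frames(self) -> int:
        return int(self.data.shape[0])

    @property
    def frame_shape(self) -> tuple[int, int]:
        return (int(self.data.shape[1]), int(self.data.shape[2]))


# ---------------------------------------------------------------------------
# Event sampling
# ---------------------------------------------------------------------------

def _lognormal_params(mean: float, cv: float) -> tuple[float, float]:
    sigma2 = math.log(1.0 + cv * cv)
    mu = math.log(mean) - sigma2 / 2.0
    return mu, math.sqrt(sigma2)


def sample_events(
    model: DoseResponseModel,
    protocol: Protocol,
    geometry: CellGeometry,
    acquisition: AcquisitionParams,
    seed,
    flash: FlashParams | None = None,
) -> list[GroundTruthEvent]:
    """Draw ground-truth fusion events for one recording.

    Per protocol step the event count is Poisson with mean
    ``rate * area_um2 / 100 * duration_s / 60``; onset times are uniform
    within the step, centers uniform over mask pixels with sub-pixel jitter,
    amplitudes i.i.d. lognormal from ``flash``.  Deterministic for a fixed
    seed.  Events are returned sorted by onset time.
    """
    if flash is None:
        flash = FlashParams()
    if geometry.area_um2 <= 0:
        raise ValueError("cell mask has zero area")
    rng = np.random.default_rng(seed)
    pixels = np.argwhere(geometry.mask)  # (n, 2) row, col
    mu, sigma = _lognormal_params(flash.amplitude_mean, flash.amplitude_cv)

    events: list[GroundTruthEvent] = []
    t0 = 0.0
    for step in protocol.steps:
        rate = _step_rate(model, step)
        lam = rate * (geometry.area_um2 / 100.0) * (step.duration_s / 60.0)
        n = int(rng.poisson(lam))
        times = np.sort(t0 + rng.uniform(0.0, step.duration_s, size=n))
        picks = rng.integers(0, len(pixels), size=n)
        jitter = rng.uniform(-0.5, 0.5, size=(n, 2))
        amps = rng.lognormal(mu, sigma, size=n)
        for t, p, (jy, jx), a in zip(times, picks, jitter, amps):
            row, col = pixels[p]
            events.append(
                GroundTruthEvent(
                    time_s=float(t),
                    frame=int(t / acquisition.frame_interval_s),
                    x_px=float(col + jx),
                    y_px=float(row + jy),
                    amplitude=float(a),
                )
            )
        t0 += step.duration_s
    return events


# ---------------------------------------------------------------------------
# Rendering
# ---------------------------------------------------------------------------

#: Frames are noised in blocks of this size; fixed so that the RNG stream —
#: and therefore the rendered movie — is independent of available memory.
_NOISE_CHUNK_FRAMES = 512


def render_movie(
    events: Sequence[GroundTruthEvent],
    geometry: CellGeometry,
    acquisition: AcquisitionParams,
    flash: FlashParams,
    noise: NoiseParams,
    n_frames: int,
    seed,
) -> MovieStack:
    """Render ground-truth events into a camera movie.

    Each event contributes, at every frame ``f >= onset frame f0``, a 2-D
    Gaussian of sd ``psf_sigma_um`` centered at its sub-pixel position with
    peak ``amplitude * exp(-(f - f0) * dt / decay_tau_s)``.  Contributions
    sum over events; background (with linear bleaching), shot noise and read
    noise are added on top and the result is clipped to the camera range.
    """
    if n_frames <= 0:
        raise ValueError("n_frames must be > 0")
    dt = acquisition.frame_interval_s
    t_max = n_frames * dt
    for e in events:
        if not (0.0 <= e.time_s < t_max):
            raise ValueError(
                f"event at t={e.time_s:.3f}s falls outside the movie [0, {t_max:.3f}s)"
            )

    h, w = geometry.mask.shape
    signal = np.zeros((n_frames, h, w), dtype=np.float32)
    sigma_px = flash.psf_sigma_um / acquisition.pixel_size_um
    patch_r = int(math.ceil(4.0 * sigma_px))
    # render the decay until it has fallen to 1e-4 of the peak
    horizon = int(math.ceil(flash.decay_tau_s / dt * math.log(1e4))) + 1
    decay = np.exp(-np.arange(horizon) * dt / flash.decay_tau_s)

    for e in events:
        f0 = e.frame
        nf = min(horizon, n_frames - f0)
        if nf <= 0:
            continue
        cy = int(math.floor(e.y_px + 0.5))
        cx = int(math.floor(e.x_px + 0.5))
        r0, r1 = max(0, cy - patch_r), min(h, cy + patch_r + 1)
        c0, c1 = max(0, cx - patch_r), min(w, cx + patch_r + 1)
        rr = np.arange(r0, r1, dtype=np.float64)
        cc = np.arange(c0, c1, dtype=np.float64)
        dist2 = ((rr - e.y_px) ** 2)[:, None] + ((cc - e.x_px) ** 2)[None, :]
        g = np.exp(-dist2 / (2.0 * sigma_px ** 2)).astype(np.float32)
        amp = (e.amplitude * decay[:nf]).astype(np.float32)
        signal[f0:f0 + nf, r0:r1, c0:c1] += amp[:, None, None] * g[None, :, :]

    rng = np.random.default_rng(seed)
    times = np.arange(n_frames) * dt
    background = noise.background_level * np.clip(
        1.0 - noise.bleach_rate_per_s * times, 0.0, None
    )
    ceiling = acquisition.intensity_ceiling

    out = np.empty_like(signal)
    for s in range(0, n_frames, _NOISE_CHUNK_FRAMES):
        e_ = min(s + _NOISE_CHUNK_FRAMES, n_frames)
        block = signal[s:e_].astype(np.float64)
        block += background[s:e_, None, None]
        if noise.shot_noise:
            block = rng.poisson(block).astype(np.float64)
        if noise.read_noise_sd > 0:
            block += rng.normal(0.0, noise.read_noise_sd, size=block.shape)
        out[s:e_] = np.clip(block, 0.0, ceiling)
    return MovieStack(data=out, acquisition=acquisition)


# ---------------------------------------------------------------------------
# Protocol builders for the standard experimental designs
# ---------------------------------------------------------------------------

def ramp_protocol(
    glucose_levels: Sequence[float] = (11, 5, 4, 3, 2, 1, 0),
    step_duration_s: float = 180.0,
) -> Protocol:
    """Descending glucose ramp: 11, 5, 4, 3, 2, 1, 0 mM for 3 min each."""
    steps = tuple(
        ProtocolStep(glucose_mM=float(g), duration_s=step_duration_s)
        for g in glucose_levels
    )
    return Protocol(steps=steps, label="glucose_ramp")


def inhibitor_protocol(
    treatment: Treatment,
    glucose_mM: float = 4.0,
    step_duration_s: float = 240.0,
) -> Protocol:
    """4 mM -> 4 mM + inhibitor -> washout -> 3 mM, 4 min each."""
    steps = (
        ProtocolStep(glucose_mM=glucose_mM, duration_s=step_duration_s),
        ProtocolStep(glucose_mM=glucose_mM, duration_s=step_duration_s,
                     treatment=treatment),
        ProtocolStep(glucose_mM=glucose_mM, duration_s=step_duration_s,
                     treatment=Treatment.WASHOUT, label="washout"),
        ProtocolStep(glucose_mM=3.0, duration_s=step_duration_s),
    )
    return Protocol(steps=steps, label=f"inhibitor_{Treatment(treatment).value}")


def gka_series_protocol(
    glucose_mM: float,
    concentrations_uM: Sequence[float] = (0.1, 1.0, 10.0),
    step_duration_s: float = 240.0,
) -> Protocol:
    """Untreated baseline followed by rising glucokinase-activator doses."""
    steps = [ProtocolStep(glucose_mM=glucose_mM, duration_s=step_duration_s)]
    for c in concentrations_uM:
        steps.append(
            ProtocolStep(
                glucose_mM=glucose_mM,
                duration_s=step_duration_s,
                treatment=Treatment.GKA,
                gka_conc_uM=float(c),
            )
        )
    return Protocol(steps=tuple(steps), label=f"gka_at_{glucose_mM:g}mM")


def single_step_protocol(
    glucose_mM: float,
    duration_s: float = 300.0,
    treatment: Treatment = Treatment.NONE,
    gka_conc_uM: float = 0.0,
) -> Protocol:
    """One condition held for the whole recording (5 min by default)."""
    step = ProtocolStep(
        glucose_mM=glucose_mM,
        duration_s=duration_s,
        treatment=treatment,
        gka_conc_uM=gka_conc_uM,
    )
    return Protocol(steps=(step,), label=f"hold_{glucose_mM:g}mM")
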