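"""Synthetic cue-response EEG sessions with known ground truth.

The generator emulates the statistical structure of a one-hour simulator
session: 14 scalp channels sampled at 128 Hz carrying 1/f background
activity plus band-limited oscillations in Theta/Alpha/Beta/Gamma;
visual cues spaced by truncated-normal intervals (mean 2.5 min, SD
1 min); event-locked band-power gains inside the 4.5-s activity window
of each cue; a linear-Gaussian link from standardized frontal Theta
log-power to reaction time; and optional slow amplitude drift across the
session.  Every stochastic choice flows from one seeded RNG stream, so a
given configuration and seed reproduce the session bit for bit.

Band components are synthesized as white Gaussian noise passed through
the package's own zero-phase band-pass filters, which guarantees their
energy sits inside the nominal band.  The per-source breakdown is kept
on the returned :class:`~ercpipe.containers.Recording` so drift can be
injected into a single band/lobe after the fact.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np

from .bands import BAND_NAMES, BANDS
from .containers import EventSchedule, Recording
from .filtering import (
    DEFAULT_KAISER_BETA,
    DEFAULT_N_TAPS,
    design_bandpass_filter,
    forward_backward_filter,
)
from .montage import CHANNEL_ORDER, ELECTRODE_LOBES, LOBES

#: Earliest admissible cue time: a full reference window must fit before it.
WARMUP_S = 2.5

#: Latest admissible cue: the 4.5-s activity window must fit before the end.
TAIL_S = 4.5


def _default_band_amplitudes() -> dict[str, float]:
    # uV RMS per channel; amplitudes fall with frequency as in scalp EEG.
    return {"Theta": 4.0, "Alpha": 6.0, "Beta": 3.0, "Gamma": 1.5}


def _default_activity_gain() -> dict[tuple[str, str], float]:
    # Frontal Theta synchronization after the cue: the generator's stand-in
    # for the cue-locked band-power change the analysis is meant to detect.
    return {("Theta", "Frontal"): 1.5}


@dataclass(frozen=True)
class SynthConfig:
    """Parameters of the synthetic session generator.

    Reaction times follow ``rt = max(rt_min, rt_base + rt_coupling * z +
    eps)`` with ``z`` the standardized latent frontal Theta log-power of
    the event and ``eps ~ N(0, rt_noise_sd**2)``; the default coupling
    and noise give a latent power-RT correlation of 0.5.
    ``drift_slope`` maps ``(band, lobe)`` to the fractional amplitude
    change over the full session.
    """

    duration: float = 3600.0
    fs: float = 128.0
    channel_labels: tuple[str, ...] = CHANNEL_ORDER
    mean_interval: float = 150.0
    sd_interval: float = 60.0
    min_interval: float = 30.0
    band_amplitudes: dict[str, float] = field(
        default_factory=_default_band_amplitudes
    )
    background_amplitude: float = 8.0
    activity_gain: dict[tuple[str, str], float] = field(
        default_factory=_default_activity_gain
    )
    rt_base: float = 1.5
    rt_coupling: float = 0.3
    rt_noise_sd: float = 0.52
    rt_min: float = 0.2
    drift_slope: dict[tuple[str, str], float] = field(default_factory=dict)
    n_taps: int = DEFAULT_N_TAPS
    kaiser_beta: float = DEFAULT_KAISER_BETA
    seed: int = 0

    def validate(self) -> None:
        scalars = {
            "duration": self.duration,
            "fs": self.fs,
            "mean_interval": self.mean_interval,
            "min_interval": self.min_interval,
            "rt_min": self.rt_min,
        }
        for name, value in scalars.items():
            if not math.isfinite(value) or value <= 0:
                raise ValueError(f"{name} must be finite and positive, got {value}")
        if not math.isfinite(self.sd_interval) or self.sd_interval < 0:
            raise ValueError("sd_interval must be finite and non-negative")
        for name in ("rt_base", "rt_coupling", "rt_noise_sd",
                     "background_amplitude"):
            if not math.isfinite(getattr(self, name)):
                raise ValueError(f"{name} must be finite")
        if self.rt_noise_sd < 0 or self.background_amplitude < 0:
            raise ValueError("rt_noise_sd and background_amplitude must be >= 0")
        for band, amp in self.band_amplitudes.items():
            if band not in BANDS:
                raise ValueError(f"unknown band {band!r} in band_amplitudes")
            if not math.isfinite(amp) or amp < 0:
                raise ValueError(f"band amplitude for {band} must be >= 0")
        for mapping, label in (
            (self.activity_gain, "activity_gain"),
            (self.drift_slope, "drift_slope"),
        ):
            for (band, lobe), value in mapping.items():
                if band not in BANDS:
                    raise ValueError(f"unknown band {band!r} in {label}")
                if lobe not in LOBES:
                    raise ValueError(f"unknown lobe {lobe!r} in {label}")
                if not math.isfinite(value):
                    raise ValueError(f"{label}[{band},{lobe}] must be finite")
                if label == "activity_gain" and value <= 0:
                    raise ValueError(f"activity gain for ({band},{lobe}) must be > 0")
        for ch in self.channel_labels:
            if ch not in ELECTRODE_LOBES:
                raise ValueError(f"unknown electrode label {ch!r}")


@dataclass(frozen=True)
class GroundTruth:
    """What the generator actually injected, for parameter-recovery tests."""

    activity_gain: dict[tuple[str, str], float]
    drift_slope: dict[tuple[str, str], float]
    rt_coupling: float
    latent_theta_logvar: np.ndarray
    latent_z: np.ndarray
    rt_noise: np.ndarray


def sample_intervals(
    n: int, config: SynthConfig, rng: np.random.Generator
) -> np.ndarray:
    """Draw ``n`` inter-cue intervals: Normal, truncated below.

    Draws from ``Normal(mean_interval, sd_interval)`` and clamps at
    ``min_interval``.  With the defaults the floor sits two standard
    deviations below the mean, so sample moments stay within a couple of
    percent of the nominal ones.
    """
    draws = rng.normal(config.mean_interval, config.sd_interval, size=n)
    return np.maximum(draws, config.min_interval)


def generate_cue_schedule(
    config: SynthConfig, rng: np.random.Generator | None = None
) -> EventSchedule:
    """Generate cue onsets for one session; reaction times left unset.

    Cues accumulate truncated-normal intervals from time zero; a cue
    must fall no earlier than 2.5 s (full reference window) and no
    closer than 4.5 s to the recording end (full activity window).
    """
    config.validate()
    if rng is None:
        rng = np.random.default_rng(config.seed)
    horizon = config.duration - TAIL_S
    if horizon <= WARMUP_S:
        raise ValueError(
            f"duration {config.duration} s leaves no room for a cue "
            f"(needs > {WARMUP_S + TAIL_S} s)"
        )
    cues: list[float] = []
    t = 0.0
    while True:
        t += float(sample_intervals(1, config, rng)[0])
        if t > horizon:
            break
        if t >= WARMUP_S:
            cues.append(t)
    if not cues:
        raise ValueError(
            f"duration {config.duration} s too short for any valid cue at "
            f"mean interval {config.mean_interval} s"
        )
    return EventSchedule(cue_times=np.array(cues))


def _one_over_f_background(
    n_samples: int, fs: float, rms: float, rng: np.random.Generator,
    corner_hz: float = 0.5,
) -> np.ndarray:
    """1/f-amplitude-shaped Gaussian noise, flattened below ``corner_hz``."""
    white = rng.standard_normal(n_samples)
    spectrum = np.fft.rfft(white)
    freqs = np.fft.rfftfreq(n_samples, d=1.0 / fs)
    shaping = 1.0 / np.sqrt(np.maximum(freqs, corner_hz))
    shaping[0] = 0.0  # no DC
    x = np.fft.irfft(spectrum * shaping, n=n_samples)
    sd = x.std()
    return x * (rms / sd) if sd > 0 else x


def _activity_slices(
    schedule: EventSchedule, fs: float, n_samples: int
) -> list[slice]:
    out = []
    for cue in schedule.cue_times:
        a0 = int(np.floor(cue * fs))
        a1 = int(np.floor((cue + TAIL_S) * fs))
        out.append(slice(max(a0, 0), min(a1, n_samples)))
    return out


def generate_session(
    config: SynthConfig,
) -> tuple[Recording, EventSchedule, GroundTruth]:
    """Generate one full session: recording, events, ground truth.

    See the module docstring for the generative model.  The returned
    recording retains its per-source components so
    :func:`inject_amplitude_drift` can rescale a single band/lobe.
    """
    config.validate()
    rng = np.random.default_rng(config.seed)
    schedule = generate_cue_schedule(config, rng)
    n_samples = int(round(config.duration * config.fs))
    n_channels = len(config.channel_labels)
    labels = list(config.channel_labels)

    components: dict[str, np.ndarray] = {}
    background = np.empty((n_channels, n_samples))
    for i in range(n_channels):
        background[i] = _one_over_f_background(
            n_samples, config.fs, config.background_amplitude, rng
        )
    components["background"] = background

    specs = {
        name: design_bandpass_filter(
            BANDS[name], config.fs, config.n_taps, config.kaiser_beta
        )
        for name in BAND_NAMES
    }
    act_slices = _activity_slices(schedule, config.fs, n_samples)

    for band in BAND_NAMES:
        rms = config.band_amplitudes.get(band, 0.0)
        comp = np.empty((n_channels, n_samples))
        for i in range(n_channels):
            raw = forward_backward_filter(
                rng.standard_normal(n_samples), specs[band]
            )
            sd = raw.std()
            comp[i] = raw * (rms / sd) if sd > 0 else raw
        # Event-locked gain inside each activity window.
        for (b, lobe), gain in config.activity_gain.items():
            if b != band or gain == 1.0:
                continue
            rows = [i for i, ch in enumerate(labels)
                    if ELECTRODE_LOBES[ch] == lobe]
            for sl in act_slices:
                comp[rows, sl] *= gain
        components[band] = comp

    # Session-long amplitude drift, same rescale as inject_amplitude_drift.
    for (band, lobe), slope in config.drift_slope.items():
        _apply_drift_inplace(
            components[band], labels, lobe, slope, config.duration, config.fs
        )

    # Latent frontal Theta log-power per event (after gains/drift) drives RT.
    frontal_rows = [i for i, ch in enumerate(labels)
                    if ELECTRODE_LOBES[ch] == "Frontal"]
    theta = components["Theta"]
    latent_lv = np.empty(len(schedule))
    for k, sl in enumerate(act_slices):
        seg = theta[frontal_rows, sl]
        latent_lv[k] = np.mean(np.log(seg.var(axis=1, ddof=1)))
    sd = latent_lv.std()
    z = (latent_lv - latent_lv.mean()) / sd if sd > 0 else np.zeros_like(latent_lv)

    eps = rng.normal(0.0, config.rt_noise_sd, size=len(schedule))
    rts = np.maximum(
        config.rt_min, config.rt_base + config.rt_coupling * z + eps
    )
    schedule = EventSchedule(
        cue_times=schedule.cue_times,
        reaction_times=rts,
        event_ids=schedule.event_ids,
    )

    data = background.copy()
    for band in BAND_NAMES:
        data += components[band]
    recording = Recording(
        data=data, fs=config.fs, channel_labels=labels, components=components
    )
    truth = GroundTruth(
        activity_gain=dict(config.activity_gain),
        drift_slope=dict(config.drift_slope),
        rt_coupling=config.rt_coupling,
        latent_theta_logvar=latent_lv,
        latent_z=z,
        rt_noise=eps,
    )
    return recording, schedule, truth


def _apply_drift_inplace(
    comp: np.ndarray,
    labels: list[str],
    lobe: str,
    slope: float,
    duration: float,
    fs: float,
) -> None:
    rows = [i for i, ch in enumerate(labels) if ELECTRODE_LOBES[ch] == lobe]
    if slope == 0.0 or not rows:
        return
    n = comp.shape[1]
    t = np.arange(n) / fs
    scale = 1.0 + slope * t / duration
    comp[rows, :] *= scale


def inject_amplitude_drift(
    recording: Recording, band: str, lobe: str, drift_slope: float
) -> Recording:
    """Rescale one band's component on one lobe by ``1 + slope*t/duration``.

    Requires a recording that still carries its synthesis components
    (i.e. one produced by :func:`generate_session`); other bands,
    channels and the background are untouched.
    """
    if band not in BANDS:
        raise ValueError(f"unknown band {band!r}; expected one of {list(BANDS)}")
    if lobe not in LOBES:
        raise ValueError(f"unknown lobe {lobe!r}; expected one of {list(LOBES)}")
    if not math.isfinite(drift_slope):
        raise ValueError("drift_slope must be finite")
    if recording.components is None:
        raise ValueError(
            "recording carries no synthesis components; drift can only be "
            "injected into generator output"
        )
    out = recording.copy()
    _apply_drift_inplace(
        out.components[band],
        out.channel_labels,
        lobe,
        drift_slope,
        out.duration,
        out.fs,
    )
    data = out.components["background"].copy()
    for b in BAND_NAMES:
        data += out.components[b]
    out.data = data
    return out


def simulate_rt_pairs(
    n_events: int, config: SynthConfig, rng: np.random.Generator
) -> tuple[np.ndarray, np.ndarray]:
    """Draw (latent log-power z, reaction time) pairs from the RT model only.

    Samples the reaction-time stage of the generative model without
    synthesizing any signal: ``z ~ N(0, 1)`` and ``rt = max(rt_min,
    rt_base + rt_coupling*z + eps)``.  Used for Monte Carlo studies of
    the correlation screen, where thousands of synthetic subjects are
    needed and the EEG synthesis itself is irrelevant.
    """
    z = rng.standard_normal(n_events)
    eps = rng.normal(0.0, config.rt_noise_sd, size=n_events)
    rt = np.maximum(config.rt_min, config.rt_base + config.rt_coupling * z + eps)
    return z, rt
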