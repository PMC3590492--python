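"""Synthetic continuous EEG realizing a conditioning trial schedule.

The generator renders a multichannel recording at 500 Hz in which every
scheduled sentence produces onset / last-word / end event markers, paired
trials add a US-evoked response, and every sentence end is followed by a
conditioned slow deflection whose shape and amplitude differ between CS
types. Background activity is a first-order autoregressive process (or,
optionally, 1/f-colored noise); ocular artifacts can be injected separately.

The conditioned response is deliberately non-peaked: a broad half-cosine bump
(default peak 700 ms after sentence end, width 1200 ms) with a centro-parietal
topography, subject to per-trial latency jitter. Its default amplitudes are
expressed as per-trial effect sizes of the downstream AUC statistic against
baseline noise and converted to microvolts analytically, so the simulated
"study conditions" are stated in the unit the analysis actually measures.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import signal as sps

from .paradigm import CSType, Schedule

__all__ = [
    "CLASSIFICATION_CHANNELS",
    "AUC_CHANNELS",
    "DEFAULT_EOG_CHANNELS",
    "AcquisitionConfig",
    "Component",
    "ERPModel",
    "NoiseModel",
    "Recording",
    "generate_recording",
    "inject_blinks",
    "auc_noise_sd",
    "amplitude_for_effect_size",
]

#: the 10-channel subset used for single-trial classification
CLASSIFICATION_CHANNELS = ("Fz", "Cz", "CPz", "P3", "Pz", "P4", "PO7", "POz", "PO8", "Oz")
#: electrode pair used for the AUC statistics
AUC_CHANNELS = ("Cz", "Pz")
DEFAULT_EOG_CHANNELS = ("VEOG", "HEOG")

EVENT_KINDS = ("sentence_onset", "last_word_onset", "sentence_end", "us_onset")


@dataclass(frozen=True)
class AcquisitionConfig:
    fs: float = 500.0
    channels: tuple[str, ...] = CLASSIFICATION_CHANNELS + DEFAULT_EOG_CHANNELS
    eog_channels: tuple[str, ...] = DEFAULT_EOG_CHANNELS
    notch_freq: float = 50.0
    pad_s: float = 60.0  # quiet signal before/after the paradigm (filter transients)

    def __post_init__(self) -> None:
        if len(set(self.channels)) != len(self.channels):
            raise ValueError("channel labels must be unique")
        if self.fs <= 60.0:
            raise ValueError("sampling rate must exceed twice the 30 Hz analysis band")
        missing = [c for c in self.eog_channels if c not in self.channels]
        if missing:
            raise ValueError(f"EOG channels not in montage: {missing}")

    @property
    def scalp_channels(self) -> tuple[str, ...]:
        return tuple(c for c in self.channels if c not in self.eog_channels)

    def require_channels(self, needed: Sequence[str]) -> None:
        missing = [c for c in needed if c not in self.channels]
        if missing:
            raise ValueError(f"montage is missing required channels: {missing}")


#: centro-parietal topography of the conditioned response (unit weight at Cz)
TOPO_CENTROPARIETAL: Mapping[str, float] = {
    "Fz": 0.6, "Cz": 1.0, "CPz": 0.95, "P3": 0.8, "Pz": 0.9, "P4": 0.8,
    "PO7": 0.5, "POz": 0.7, "PO8": 0.5, "Oz": 0.4,
}
#: fronto-central topography of the auditory US-evoked response
TOPO_FRONTOCENTRAL: Mapping[str, float] = {
    "Fz": 1.0, "Cz": 0.95, "CPz": 0.8, "P3": 0.6, "Pz": 0.6, "P4": 0.6,
    "PO7": 0.3, "POz": 0.4, "PO8": 0.3, "Oz": 0.2,
}


@dataclass(frozen=True)
class Component:
    """One half-cosine bump: ``amp * cos^2(pi (t-peak)/width)`` on its support."""

    amplitude_uv: float
    peak_ms: float
    width_ms: float
    weights: Mapping[str, float] | float = 1.0

    def waveform(self, t_ms: np.ndarray) -> np.ndarray:
        u = (t_ms - self.peak_ms) / self.width_ms
        w = np.where(np.abs(u) < 0.5, np.cos(np.pi * u) ** 2, 0.0)
        return self.amplitude_uv * w

    def weight_for(self, channel: str) -> float:
        if isinstance(self.weights, Mapping):
            return float(self.weights.get(channel, 0.0))
        return float(self.weights)

    @property
    def end_ms(self) -> float:
        return self.peak_ms + self.width_ms / 2


def _render(components: Sequence[Component], channels: Sequence[str], fs: float) -> np.ndarray:
    """Sample a component list on a (channels, samples) grid starting at t=0."""
    if not components:
        return np.zeros((len(channels), 1))
    n = int(round(max(c.end_ms for c in components) / 1000.0 * fs)) + 1
    t_ms = np.arange(n) / fs * 1000.0
    out = np.zeros((len(channels), n))
    for comp in components:
        wave = comp.waveform(t_ms)
        for i, ch in enumerate(channels):
            w = comp.weight_for(ch)
            if w:
                out[i] += w * wave
    return out


_DEFAULT_US_COMPONENTS = (
    Component(-8.0, 100.0, 120.0, TOPO_FRONTOCENTRAL),   # N1-like
    Component(12.0, 220.0, 180.0, TOPO_FRONTOCENTRAL),   # P2-like
)


@dataclass(frozen=True)
class NoiseModel:
    """Background EEG + ocular-artifact parameters.

    The AR(1) background with coefficient 0.95 and innovation SD 3.12 uV gives
    a stationary RMS near 10 uV, a realistic magnitude for band-limited
    resting EEG.
    """

    ar_coef: float = 0.95
    innovation_sd_uv: float = 3.12
    one_over_f_exponent: float | None = None
    blink_rate_per_min: float = 10.0
    blink_amplitude_uv: float = 150.0
    blink_width_ms: float = 300.0
    blink_coupling: Mapping[str, float] = field(
        default_factory=lambda: {
            "Fz": 0.30, "Cz": 0.15, "CPz": 0.10, "P3": 0.06, "Pz": 0.05,
            "P4": 0.06, "PO7": 0.03, "POz": 0.03, "PO8": 0.03, "Oz": 0.02,
        }
    )

    def __post_init__(self) -> None:
        if not -1.0 < self.ar_coef < 1.0:
            raise ValueError("AR coefficient must lie in (-1, 1)")
        if self.blink_rate_per_min < 0:
            raise ValueError("blink rate must be nonnegative")

    @property
    def stationary_sd_uv(self) -> float:
        return self.innovation_sd_uv / math.sqrt(1.0 - self.ar_coef**2)


def auc_noise_sd(noise: NoiseModel, n_samples: int = 1000, dt: float = 0.002) -> float:
    """Analytic SD of the AUC-increase statistic of pure AR(1) noise.

    The statistic is a fixed linear functional c'x of the window (trapezoid
    weights minus the window duration on the first sample), so its variance is
    c' Sigma c with the AR(1) covariance Sigma_ij = sigma^2 rho^|i-j|.
    """
    w = np.full(n_samples, dt)
    w[0] = w[-1] = dt / 2.0
    c = w.copy()
    c[0] -= (n_samples - 1) * dt
    # autocovariance-weighted quadratic form via the autocorrelation of c
    acf_c = np.correlate(c, c, mode="full")[n_samples - 1 :]
    rho = noise.ar_coef ** np.arange(n_samples)
    var = noise.stationary_sd_uv**2 * (acf_c[0] + 2.0 * np.dot(acf_c[1:], rho[1:]))
    return math.sqrt(var)


def _unit_cr_components(weights: Mapping[str, float] = TOPO_CENTROPARIETAL) -> tuple[Component, ...]:
    return (Component(1.0, 700.0, 1200.0, weights),)


def amplitude_for_effect_size(
    d: float,
    noise: NoiseModel,
    components: Sequence[Component] | None = None,
    channel: str = "Cz",
    fs: float = 500.0,
    window_ms: float = 2000.0,
) -> float:
    """Microvolt amplitude giving a per-trial AUC effect size ``d`` vs baseline.

    ``d`` is (mean template AUC) / (noise AUC SD) at the given channel;
    the template AUC scales linearly with amplitude.
    """
    comps = tuple(components) if components else _unit_cr_components()
    n = int(round(window_ms / 1000.0 * fs))
    t_ms = np.arange(n) / fs * 1000.0
    unit = np.zeros(n)
    for c in comps:
        unit += c.weight_for(channel) * c.waveform(t_ms) / c.amplitude_uv if c.amplitude_uv else 0.0
    unit_auc = np.trapezoid(unit - unit[0], dx=1.0 / fs)
    if unit_auc <= 0:
        raise ValueError("unit template has nonpositive AUC; cannot calibrate")
    sd = auc_noise_sd(noise, n, 1.0 / fs)
    return d * sd / unit_auc


@dataclass(frozen=True)
class ERPModel:
    """Conditioned-response and US-evoked templates.

    Setting the CS1 and CS2 component lists equal defines the null model in
    which the two conditioned reactions are indistinguishable by construction.
    """

    cs1: tuple[Component, ...]
    cs2: tuple[Component, ...]
    us: Mapping[str, tuple[Component, ...]] = field(
        default_factory=lambda: {
            "pink-noise": _DEFAULT_US_COMPONENTS,
            "white-noise": tuple(
                replace(c, amplitude_uv=1.4 * c.amplitude_uv) for c in _DEFAULT_US_COMPONENTS
            ),
            "individual-noise": tuple(
                replace(c, amplitude_uv=1.5 * c.amplitude_uv) for c in _DEFAULT_US_COMPONENTS
            ),
        }
    )
    latency_jitter_sd_ms: float = 50.0

    def __post_init__(self) -> None:
        if self.latency_jitter_sd_ms < 0:
            raise ValueError("latency jitter SD must be nonnegative")

    @classmethod
    def conditioned(
        cls,
        cs1_effect_d: float = 0.5,
        cs2_effect_d: float = 0.8,
        noise: NoiseModel | None = None,
        latency_jitter_sd_ms: float = 50.0,
    ) -> "ERPModel":
        """Differential-conditioning model with AUC effect sizes vs baseline."""
        noise = noise or NoiseModel()
        a1 = amplitude_for_effect_size(cs1_effect_d, noise)
        a2 = amplitude_for_effect_size(cs2_effect_d, noise)
        (u,) = _unit_cr_components()
        return cls(
            cs1=(replace(u, amplitude_uv=a1),),
            cs2=(replace(u, amplitude_uv=a2),),
            latency_jitter_sd_ms=latency_jitter_sd_ms,
        )

    @classmethod
    def null(
        cls,
        effect_d: float = 0.5,
        noise: NoiseModel | None = None,
        latency_jitter_sd_ms: float = 50.0,
    ) -> "ERPModel":
        """Identical CS1/CS2 templates: no differential conditioning."""
        m = cls.conditioned(effect_d, effect_d, noise, latency_jitter_sd_ms)
        return replace(m, cs2=m.cs1)

    def cr_components(self, cs_type: CSType) -> tuple[Component, ...]:
        return self.cs1 if cs_type is CSType.CS1 else self.cs2

    def cr_template(self, cs_type: CSType, channels: Sequence[str], fs: float) -> np.ndarray:
        return _render(self.cr_components(cs_type), channels, fs)

    def us_template(self, us_kind: str, channels: Sequence[str], fs: float) -> np.ndarray:
        return _render(self.us.get(us_kind, ()), channels, fs)


@dataclass
class Recording:
    """Continuous multichannel signal plus sample-indexed event markers."""

    signal: np.ndarray  # (channels, samples), microvolts
    fs: float
    channels: tuple[str, ...]
    events: pd.DataFrame  # columns: sample, kind, trial_index
    eog_channels: tuple[str, ...] = DEFAULT_EOG_CHANNELS
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.signal.shape[0] != len(self.channels):
            raise ValueError("signal row count must match channel list")

    @property
    def n_samples(self) -> int:
        return self.signal.shape[1]

    @property
    def duration_s(self) -> float:
        return self.n_samples / self.fs

    def channel_index(self, label: str) -> int:
        try:
            return self.channels.index(label)
        except ValueError:
            raise KeyError(f"channel {label!r} not in recording") from None

    def events_of(self, kind: str) -> pd.DataFrame:
        return self.events[self.events["kind"] == kind].reset_index(drop=True)

    def copy(self) -> "Recording":
        return Recording(
            signal=self.signal.copy(),
            fs=self.fs,
            channels=self.channels,
            events=self.events.copy(),
            eog_channels=self.eog_channels,
            meta=dict(self.meta),
        )


def _timeline(
    schedule: Schedule, acq: AcquisitionConfig, rng: np.random.Generator
) -> pd.DataFrame:
    """Draw sentence timing and lay out events; returns the event table.

    Sentence durations are uniform on [2, 4] s with the decisive last word
    starting 300-600 ms before sentence end; the 5 s ITI runs from US end
    (or sentence end when unpaired) to the next sentence onset.
    """
    n = len(schedule)
    durations = rng.uniform(2.0, 4.0, size=n)
    last_word_lead = rng.uniform(0.3, 0.6, size=n)
    rows = []
    t = acq.pad_s
    us_dur = schedule.arm.us_duration_ms / 1000.0
    for i, tr in enumerate(schedule.trials):
        onset, end = t, t + durations[i]
        rows.append((onset, "sentence_onset", tr.trial_index))
        rows.append((end - last_word_lead[i], "last_word_onset", tr.trial_index))
        rows.append((end, "sentence_end", tr.trial_index))
        if tr.paired:
            rows.append((end, "us_onset", tr.trial_index))
            end += us_dur
        t = end + tr.iti_s
    df = pd.DataFrame(rows, columns=["time_s", "kind", "trial_index"])
    df["sample"] = np.round(df["time_s"] * acq.fs).astype(int)
    return df[["sample", "kind", "trial_index", "time_s"]]


def _background(
    noise: NoiseModel, n_channels: int, n_samples: int, rng: np.random.Generator
) -> np.ndarray:
    innov = rng.standard_normal((n_channels, n_samples)) * noise.innovation_sd_uv
    if noise.one_over_f_exponent is not None:
        # color white innovations to f^(-beta/2), normalized back to the
        # stationary RMS of the AR alternative
        spec = np.fft.rfft(innov, axis=1)
        freqs = np.fft.rfftfreq(n_samples)
        gain = np.ones_like(freqs)
        gain[1:] = freqs[1:] ** (-noise.one_over_f_exponent / 2.0)
        gain[0] = 0.0
        colored = np.fft.irfft(spec * gain, n=n_samples, axis=1)
        colored *= noise.stationary_sd_uv / colored.std(axis=1, keepdims=True)
        return colored
    return sps.lfilter([1.0], [1.0, -noise.ar_coef], innov, axis=1)


def generate_recording(
    schedule: Schedule,
    acq: AcquisitionConfig | None = None,
    erp: ERPModel | None = None,
    noise: NoiseModel | None = None,
    seed: int = 0,
) -> Recording:
    """Render a schedule into a continuous synthetic recording.

    Deterministic per seed; all stochastic draws derive from one generator in
    fixed order (timing, jitter, then background noise), so changing template
    amplitudes leaves the noise realization untouched and the generated signal
    decomposes exactly into noise plus inserted templates.
    """
    acq = acq or AcquisitionConfig()
    noise = noise if noise is not None else NoiseModel()
    erp = erp or ERPModel.conditioned(noise=noise)
    acq.require_channels(AUC_CHANNELS)

    rng = np.random.default_rng(seed)
    events = _timeline(schedule, acq, rng)
    jitter_ms = rng.standard_normal(len(schedule)) * erp.latency_jitter_sd_ms
    if erp.latency_jitter_sd_ms > 0:
        lim = 3.0 * erp.latency_jitter_sd_ms
        jitter_ms = np.clip(jitter_ms, -lim, lim)

    n_samples = int(events["sample"].max()) + int(round(acq.pad_s * acq.fs))
    sig = _background(noise, len(acq.channels), n_samples, rng)

    templates = {cs: erp.cr_template(cs, acq.channels, acq.fs) for cs in CSType}
    us_templates = {
        kind: erp.us_template(kind, acq.channels, acq.fs)
        for kind in {t.us_kind for t in schedule.trials if t.us_kind}
    }

    ends = events.set_index(["kind", "trial_index"])["sample"]
    for i, tr in enumerate(schedule.trials):
        tpl = templates[tr.cs_type]
        start = int(ends.loc[("sentence_end", tr.trial_index)]) + int(
            round(jitter_ms[i] / 1000.0 * acq.fs)
        )
        sig[:, start : start + tpl.shape[1]] += tpl[:, : max(0, n_samples - start)]
        if tr.paired:
            utpl = us_templates[tr.us_kind]
            ustart = int(ends.loc[("us_onset", tr.trial_index)])
            sig[:, ustart : ustart + utpl.shape[1]] += utpl[:, : max(0, n_samples - ustart)]

    return Recording(
        signal=sig,
        fs=acq.fs,
        channels=acq.channels,
        events=events[["sample", "kind", "trial_index"]].copy(),
        eog_channels=acq.eog_channels,
        meta={
            "arm": schedule.arm.arm_id.value,
            "schedule_seed": schedule.seed,
            "signal_seed": seed,
        },
    )


def inject_blinks(
    recording: Recording, noise: NoiseModel, seed: int = 0
) -> Recording:
    """Add Poisson-timed blink transients to EOG and, via coupling, to scalp.

    Blink count over the recording is Poisson with mean rate x duration;
    blinks land on every EOG channel at full amplitude and on scalp channels
    scaled by the coupling weights.
    """
    if not recording.eog_channels:
        raise ValueError("recording has no EOG channels")
    if noise.blink_rate_per_min < 0:
        raise ValueError("blink rate must be nonnegative")
    out = recording.copy()
    if noise.blink_rate_per_min == 0:
        return out
    rng = np.random.default_rng(seed)
    duration_min = recording.duration_s / 60.0
    n_blinks = rng.poisson(noise.blink_rate_per_min * duration_min)
    times = np.sort(rng.uniform(0, recording.duration_s, size=n_blinks))
    width_n = int(round(noise.blink_width_ms / 1000.0 * recording.fs))
    t = np.arange(width_n) / recording.fs * 1000.0
    shape = noise.blink_amplitude_uv * np.sin(np.pi * t / noise.blink_width_ms) ** 2
    gains = np.array(
        [
            1.0 if ch in recording.eog_channels else noise.blink_coupling.get(ch, 0.0)
            for ch in recording.channels
        ]
    )
    for bt in times:
        start = int(round(bt * recording.fs))
        seg = min(width_n, recording.n_samples - start)
        if seg <= 0:
            continue
        out.signal[:, start : start + seg] += gains[:, None] * shape[:seg]
    out.meta["n_blinks"] = int(n_blinks)
    return out
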