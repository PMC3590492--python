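"""Filtering, ocular-artifact attenuation, and epoch extraction.

The analysis band is 0.009-30 Hz, applied as a zero-phase forward-backward
Butterworth filter (order 4 per pass) so event alignment is preserved. The
0.009 Hz high-pass has an extremely long impulse response; recordings are
generated with quiet padding at both ends so its edge transients never touch
analyzed epochs.

Epochs come in two roles: 2000 ms post-sentence windows anchored at sentence
end (where the conditioned reaction is expected) and 2000 ms baseline windows
ending at sentence onset. Each epoch is offset-corrected by subtracting the
per-channel mean of the 100 ms immediately preceding its start.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from enum import Enum
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import signal as sps

from .synthgen import Recording

__all__ = [
    "FilterSpec",
    "EpochRole",
    "EpochSet",
    "bandpass_filter",
    "remove_ocular",
    "extract_epochs",
]

REFERENCE_MS = 100.0  # offset-correction interval preceding each epoch


@dataclass(frozen=True)
class FilterSpec:
    highpass_hz: float = 0.009
    lowpass_hz: float = 30.0
    notch_hz: float | None = None
    order: int = 4
    zero_phase: bool = True

    def validate(self, fs: float) -> list[str]:
        issues = []
        if not 0 < self.highpass_hz < self.lowpass_hz:
            issues.append("require 0 < highpass < lowpass")
        if self.lowpass_hz >= fs / 2:
            issues.append(f"lowpass {self.lowpass_hz} Hz >= Nyquist {fs / 2} Hz")
        if self.notch_hz is not None and self.notch_hz >= fs / 2:
            issues.append(f"notch {self.notch_hz} Hz >= Nyquist {fs / 2} Hz")
        return issues


class EpochRole(str, Enum):
    POST_SENTENCE = "POST_SENTENCE"
    BASELINE = "BASELINE"


#: anchor event and window start (ms relative to anchor) per role
_ROLE_ANCHORS = {
    EpochRole.POST_SENTENCE: ("sentence_end", 0.0),
    EpochRole.BASELINE: ("sentence_onset", -2000.0),
}


def bandpass_filter(recording: Recording, spec: FilterSpec | None = None) -> Recording:
    """Zero-phase band-pass (and optional notch); length and events unchanged."""
    spec = spec or FilterSpec()
    issues = spec.validate(recording.fs)
    if issues:
        raise ValueError("; ".join(issues))
    nyq = recording.fs / 2.0
    out = recording.copy()
    sos_hp = sps.butter(spec.order, spec.highpass_hz / nyq, "highpass", output="sos")
    sos_lp = sps.butter(spec.order, spec.lowpass_hz / nyq, "lowpass", output="sos")
    apply = sps.sosfiltfilt if spec.zero_phase else sps.sosfilt
    x = apply(sos_hp, out.signal, axis=1)
    x = apply(sos_lp, x, axis=1)
    if spec.notch_hz is not None:
        b, a = sps.iirnotch(spec.notch_hz, Q=30.0, fs=recording.fs)
        x = sps.filtfilt(b, a, x, axis=1) if spec.zero_phase else sps.lfilter(b, a, x, axis=1)
    out.signal = np.ascontiguousarray(x)
    out.meta["filter"] = spec
    return out


def remove_ocular(recording: Recording) -> Recording:
    """Least-squares EOG regression: scalp channels become regression residuals.

    Each scalp channel is projected onto the span of the EOG channels over the
    whole recording and replaced by its residual; EOG channels pass through
    unchanged. Idempotent up to numerical precision.
    """
    if not recording.eog_channels:
        raise ValueError("no EOG channel present; cannot remove ocular artifacts")
    eog_idx = [recording.channel_index(c) for c in recording.eog_channels]
    scalp_idx = [i for i in range(len(recording.channels)) if i not in eog_idx]
    out = recording.copy()
    eog = recording.signal[eog_idx]  # (n_eog, T)
    scalp = recording.signal[scalp_idx]  # (n_scalp, T)
    # demean both so the regression captures coupling, not offsets
    eog_c = eog - eog.mean(axis=1, keepdims=True)
    scalp_mean = scalp.mean(axis=1, keepdims=True)
    coef, *_ = np.linalg.lstsq(eog_c.T, (scalp - scalp_mean).T, rcond=None)
    out.signal[scalp_idx] = scalp - coef.T @ eog_c
    out.meta["ocular"] = {"method": "eog-regression", "coef": coef.T}
    return out


@dataclass
class EpochSet:
    """Fixed-length epochs: (trials, channels, samples) plus trial metadata."""

    data: np.ndarray
    meta: pd.DataFrame  # columns: trial_index, cs_type, phase, role
    channels: tuple[str, ...]
    fs: float
    window_ms: tuple[float, float]  # (start relative to anchor, length)
    reference_mean: np.ndarray  # (trials, channels) subtracted offsets
    provenance: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.data.shape[0] != len(self.meta):
            raise ValueError("metadata rows must match epoch count")
        if self.data.shape[1] != len(self.channels):
            raise ValueError("channel list must match epoch data")

    def __len__(self) -> int:
        return self.data.shape[0]

    @property
    def n_samples(self) -> int:
        return self.data.shape[2]

    def channel_index(self, label: str) -> int:
        try:
            return self.channels.index(label)
        except ValueError:
            raise KeyError(f"channel {label!r} not in epoch set") from None

    def select(self, mask: np.ndarray | pd.Series) -> "EpochSet":
        mask = np.asarray(mask)
        return EpochSet(
            data=self.data[mask],
            meta=self.meta.loc[mask].reset_index(drop=True),
            channels=self.channels,
            fs=self.fs,
            window_ms=self.window_ms,
            reference_mean=self.reference_mean[mask],
            provenance=dict(self.provenance),
        )

    def select_phases(self, phases) -> "EpochSet":
        wanted = {getattr(p, "value", p) for p in phases}
        return self.select(self.meta["phase"].isin(wanted).to_numpy())

    def save(self, directory: str | Path) -> None:
        """Directory layout: ``meta.tsv`` + ``data.npy`` (trials x ch x samples,
        float64, C-order) + ``reference_mean.npy`` + ``attrs.tsv``."""
        d = Path(directory)
        d.mkdir(parents=True, exist_ok=True)
        self.meta.to_csv(d / "meta.tsv", sep="\t", index=False)
        np.save(d / "data.npy", self.data)
        np.save(d / "reference_mean.npy", self.reference_mean)
        attrs = pd.DataFrame(
            {
                "key": ["channels", "fs", "window_start_ms", "window_len_ms"],
                "value": [
                    ",".join(self.channels),
                    self.fs,
                    self.window_ms[0],
                    self.window_ms[1],
                ],
            }
        )
        attrs.to_csv(d / "attrs.tsv", sep="\t", index=False)

    @classmethod
    def load(cls, directory: str | Path) -> "EpochSet":
        d = Path(directory)
        meta = pd.read_csv(d / "meta.tsv", sep="\t")
        attrs = pd.read_csv(d / "attrs.tsv", sep="\t").set_index("key")["value"]
        return cls(
            data=np.load(d / "data.npy"),
            meta=meta,
            channels=tuple(str(attrs["channels"]).split(",")),
            fs=float(attrs["fs"]),
            window_ms=(float(attrs["window_start_ms"]), float(attrs["window_len_ms"])),
            reference_mean=np.load(d / "reference_mean.npy"),
        )


def extract_epochs(
    recording: Recording,
    schedule,
    role: EpochRole | str = EpochRole.POST_SENTENCE,
    window_len_ms: float = 2000.0,
) -> EpochSet:
    """Cut fixed-length, offset-corrected epochs of one role.

    POST_SENTENCE epochs start at sentence end; BASELINE epochs end at
    sentence onset. The per-channel mean of the 100 ms immediately preceding
    the epoch start is subtracted and stored. Epochs are half-open sample
    ranges [start, start+n) with anchors mapped via round(t * fs).
    """
    role = EpochRole(role)
    anchor_kind, start_ms = _ROLE_ANCHORS[role]
    if role is EpochRole.BASELINE:
        start_ms = -window_len_ms
    fs = recording.fs
    n = int(round(window_len_ms / 1000.0 * fs))
    n_ref = int(round(REFERENCE_MS / 1000.0 * fs))
    offset = int(round(start_ms / 1000.0 * fs))

    anchors = recording.events_of(anchor_kind).set_index("trial_index")["sample"]
    trials = {t.trial_index: t for t in schedule.trials}

    starts, rows, bad = [], [], []
    for trial_index, anchor in anchors.items():
        start = int(anchor) + offset
        if start - n_ref < 0 or start + n > recording.n_samples:
            bad.append(trial_index)
            continue
        tr = trials[trial_index]
        starts.append(start)
        rows.append(
            {
                "trial_index": trial_index,
                "cs_type": tr.cs_type.value,
                "phase": tr.phase.value,
                "role": role.value,
            }
        )
    if bad:
        raise ValueError(
            f"{len(bad)} {role.value} epoch(s) fall outside the recording; "
            f"trial_index: {bad}"
        )

    n_trials = len(starts)
    data = np.empty((n_trials, len(recording.channels), n))
    ref = np.empty((n_trials, len(recording.channels)))
    for i, start in enumerate(starts):
        ref[i] = recording.signal[:, start - n_ref : start].mean(axis=1)
        data[i] = recording.signal[:, start : start + n] - ref[i][:, None]

    return EpochSet(
        data=data,
        meta=pd.DataFrame(rows),
        channels=recording.channels,
        fs=fs,
        window_ms=(start_ms, window_len_ms),
        reference_mean=ref,
        provenance={
            "role": role.value,
            "filter": recording.meta.get("filter"),
            "ocular": "eog-regression" if "ocular" in recording.meta else None,
        },
    )
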