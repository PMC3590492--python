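"""European Data Format (EDF) export/import and event tables.

The writer emits plain 16-bit EDF (one-second data records, per-channel
symmetric physical scaling chosen from the data so nothing clips); no EDF
writing library is available in the supported environment, so the format is
implemented here directly and the reader side goes through MNE, which also
serves as the independent check of the writer in the test suite. Event
markers travel in a companion tab-separated table (sample, kind,
trial_index) rather than EDF+ annotations.
"""

from __future__ import annotations

import math
from pathlib import Path

import numpy as np
import pandas as pd

from .synthgen import DEFAULT_EOG_CHANNELS, Recording

__all__ = ["write_edf", "read_edf", "write_events_tsv", "read_events_tsv"]

_DIG_MAX = 32767
_DIG_MIN = -32768


def _ascii(value, width: int) -> bytes:
    s = str(value)
    if len(s) > width:
        raise ValueError(f"EDF header field too long: {s!r} > {width}")
    return s.ljust(width).encode("ascii")


def write_edf(recording: Recording, path: str | Path) -> None:
    """Write the recording as 16-bit EDF with one-second data records.

    The last record is zero-padded when the signal length is not a multiple
    of the sampling rate; per-channel physical bounds are the smallest
    symmetric integer range covering the data (at least +/-1 uV).
    """
    fs = recording.fs
    if abs(fs - round(fs)) > 1e-9:
        raise ValueError("EDF writer requires an integer sampling rate")
    spr = int(round(fs))  # samples per record (1 s records)
    n_ch, n_samp = recording.signal.shape
    n_rec = math.ceil(n_samp / spr)

    phys_max = np.maximum(1.0, np.ceil(np.abs(recording.signal).max(axis=1)))
    header = bytearray()
    header += _ascii("0", 8)
    header += _ascii("X X X X", 80)
    header += _ascii("Startdate X X X X semcond", 80)
    header += _ascii("01.01.00", 8)
    header += _ascii("00.00.00", 8)
    header += _ascii(256 * (1 + n_ch), 8)
    header += _ascii("", 44)
    header += _ascii(n_rec, 8)
    header += _ascii(1, 8)
    header += _ascii(n_ch, 4)
    for field_values in (
        [f"EEG {c}" if c not in recording.eog_channels else f"EOG {c}"
         for c in recording.channels],  # labels
    ):
        for v in field_values:
            header += _ascii(v, 16)
    for width, values in (
        (80, ["AgAgCl electrode"] * n_ch),
        (8, ["uV"] * n_ch),
        (8, [f"{-int(p)}" for p in phys_max]),
        (8, [f"{int(p)}" for p in phys_max]),
        (8, [str(_DIG_MIN)] * n_ch),
        (8, [str(_DIG_MAX)] * n_ch),
        (80, [""] * n_ch),
        (8, [str(spr)] * n_ch),
        (32, [""] * n_ch),
    ):
        for v in values:
            header += _ascii(v, width)

    scale = _DIG_MAX / phys_max  # digital units per microvolt, per channel
    padded = np.zeros((n_ch, n_rec * spr))
    padded[:, :n_samp] = recording.signal
    digital = np.clip(
        np.round(padded * scale[:, None]), _DIG_MIN, _DIG_MAX
    ).astype("<i2")

    with open(path, "wb") as fh:
        fh.write(bytes(header))
        for r in range(n_rec):
            fh.write(digital[:, r * spr : (r + 1) * spr].tobytes())


def read_edf(
    path: str | Path,
    events_path: str | Path | None = None,
    eog_channels: tuple[str, ...] = DEFAULT_EOG_CHANNELS,
) -> Recording:
    """Load an EDF recording (via MNE) back into microvolt units."""
    import mne

    raw = mne.io.read_raw_edf(path, preload=True, verbose="error")
    channels = tuple(name.split(" ", 1)[-1] for name in raw.ch_names)
    events = (
        read_events_tsv(events_path)
        if events_path is not None
        else pd.DataFrame(columns=["sample", "kind", "trial_index"])
    )
    return Recording(
        signal=raw.get_data() * 1e6,
        fs=float(raw.info["sfreq"]),
        channels=channels,
        events=events,
        eog_channels=tuple(c for c in eog_channels if c in channels),
        meta={"source": str(path)},
    )


def write_events_tsv(recording: Recording, path: str | Path) -> None:
    recording.events.to_csv(path, sep="\t", index=False)


def read_events_tsv(path: str | Path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t")
    expected = {"sample", "kind", "trial_index"}
    if not expected.issubset(df.columns):
        raise ValueError(f"event table must have columns {sorted(expected)}")
    return df[["sample", "kind", "trial_index"]]
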