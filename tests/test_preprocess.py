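"""Filtering, EOG regression, and epoch extraction."""

import numpy as np
import pandas as pd
import pytest
from scipy import signal as sps

from semcond.preprocess import (
    EpochRole,
    EpochSet,
    FilterSpec,
    bandpass_filter,
    extract_epochs,
    remove_ocular,
)
from semcond.synthgen import NoiseModel, Recording, inject_blinks

from conftest import flat_recording


def sine_recording(freq_hz, duration_s=900.0, fs=500.0):
    t = np.arange(int(duration_s * fs)) / fs
    return flat_recording(0.0, duration_s, fs).copy(), np.sin(2 * np.pi * freq_hz * t)


class TestFilter:
    MID = slice(int(300 * 500), int(600 * 500))  # steady-state section

    def test_dc_removed(self):
        rec = flat_recording(10.0, duration_s=120.0)
        out = bandpass_filter(rec)
        mid = slice(int(40 * 500), int(80 * 500))
        assert np.abs(out.signal[:, mid]).max() < 0.1  # < 1% of the 10 uV input

    def test_notch_attenuates_50hz(self):
        rec, s = sine_recording(50.0)
        rec.signal[:] = s
        out = bandpass_filter(rec, FilterSpec(notch_hz=50.0))
        atten_db = -20 * np.log10(np.abs(out.signal[0, self.MID]).max())
        assert atten_db >= 20.0
        # and the designed notch itself is deep at 50 Hz
        b, a = sps.iirnotch(50.0, Q=30.0, fs=500.0)
        _, h = sps.freqz(b, a, worN=[50.0], fs=500.0)
        assert -20 * np.log10(np.abs(h[0])) >= 20.0

    def test_passband_gain_near_unity(self):
        rec, s = sine_recording(10.0)
        rec.signal[:] = s
        out = bandpass_filter(rec)
        assert 0.9 <= np.abs(out.signal[0, self.MID]).max() <= 1.1

    def test_zero_phase_preserves_alignment(self):
        """A slow pulse keeps its peak sample position under zero-phase filtering."""
        rec = flat_recording(0.0, duration_s=300.0)
        center = rec.n_samples // 2
        t = np.arange(rec.n_samples) / rec.fs
        rec.signal[:] = np.exp(-0.5 * ((t - t[center]) / 0.5) ** 2)
        out = bandpass_filter(rec)
        assert abs(int(np.argmax(out.signal[0])) - center) <= 2

    def test_length_and_events_unchanged(self):
        rec = flat_recording(1.0, duration_s=30.0)
        out = bandpass_filter(rec)
        assert out.signal.shape == rec.signal.shape

    def test_bad_cutoff_rejected(self):
        rec = flat_recording(0.0, duration_s=10.0)
        with pytest.raises(ValueError, match="Nyquist"):
            bandpass_filter(rec, FilterSpec(lowpass_hz=300.0))


class TestOcularRegression:
    @staticmethod
    def blinky_recording(coupling):
        nm = NoiseModel(
            blink_rate_per_min=12.0,
            blink_coupling=coupling,
        )
        rec = flat_recording(0.0, duration_s=300.0)
        return inject_blinks(rec, nm, seed=7)

    def test_known_coupling_removed(self):
        """With purely linear EOG coupling the scalp blink energy all but vanishes."""
        coupling = {"Cz": 0.25, "Pz": 0.12}
        rec = self.blinky_recording(coupling)
        out = remove_ocular(rec)
        for ch, w in coupling.items():
            i = rec.channel_index(ch)
            # channel means are kept by the regression; compare AC energy
            before = float(np.sum((rec.signal[i] - rec.signal[i].mean()) ** 2))
            after = float(np.sum((out.signal[i] - out.signal[i].mean()) ** 2))
            assert after < 0.01 * before

    def test_blink_free_recording_unchanged(self):
        rec = self.blinky_recording({})  # blinks on EOG only
        out = remove_ocular(rec)
        for ch in ("Cz", "Pz"):
            i = rec.channel_index(ch)
            np.testing.assert_allclose(out.signal[i], rec.signal[i], atol=1e-9)
        # EOG passes through untouched
        e = rec.channel_index("VEOG")
        np.testing.assert_array_equal(out.signal[e], rec.signal[e])

    def test_idempotent(self):
        rec = self.blinky_recording({"Cz": 0.25, "Pz": 0.12})
        once = remove_ocular(rec)
        twice = remove_ocular(once)
        np.testing.assert_allclose(twice.signal, once.signal, atol=1e-8)

    def test_requires_eog(self):
        rec = flat_recording(0.0, duration_s=5.0, channels=("Cz", "Pz"), eog=())
        with pytest.raises(ValueError, match="EOG"):
            remove_ocular(rec)


class TestEpochs:
    def test_window_sample_count(self, exp1_participant):
        _, post, baseline = exp1_participant
        assert post.n_samples == 1000  # 2000 ms at 500 Hz
        assert baseline.n_samples == 1000

    def test_epoch_counts_match_schedule(self, exp1_participant):
        schedule, post, baseline = exp1_participant
        assert len(post) == 640
        assert len(baseline) == 640
        unpaired = post.meta["phase"].isin(["UNPAIRED", "EXT"]).sum()
        assert unpaired == 140  # 2 x (50 + 20)

    def test_constant_recording_epochs_are_zero(self):
        from semcond.paradigm import build_schedule, Schedule
        from semcond.synthgen import AcquisitionConfig, ERPModel, generate_recording

        full = build_schedule("EXP1", 0)
        sched = Schedule(full.arm, full.trials[:5], 0)
        quiet = NoiseModel(innovation_sd_uv=0.0)
        erp = ERPModel(cs1=(), cs2=(), us={}, latency_jitter_sd_ms=0.0)
        rec = generate_recording(sched, AcquisitionConfig(pad_s=5.0), erp, quiet, seed=0)
        rec.signal += 7.5  # constant offset everywhere
        post = extract_epochs(rec, sched, EpochRole.POST_SENTENCE)
        np.testing.assert_allclose(post.data, 0.0, atol=1e-12)
        np.testing.assert_allclose(post.reference_mean, 7.5)

    def test_offset_correction_bookkeeping(self):
        """Adding back the stored reference mean reproduces the raw slice."""
        from semcond.paradigm import build_schedule, Schedule
        from semcond.synthgen import AcquisitionConfig, generate_recording

        full = build_schedule("EXP1", 3)
        sched = Schedule(full.arm, full.trials[:6], 3)
        rec = generate_recording(sched, AcquisitionConfig(pad_s=5.0), seed=4)
        post = extract_epochs(rec, sched, EpochRole.POST_SENTENCE)
        ends = rec.events_of("sentence_end").set_index("trial_index")["sample"]
        for i, row in post.meta.iterrows():
            start = int(ends.loc[row.trial_index])
            raw = rec.signal[:, start : start + 1000]
            np.testing.assert_allclose(
                post.data[i] + post.reference_mean[i][:, None], raw, atol=1e-12
            )

    def test_baseline_window_precedes_onset(self):
        from semcond.paradigm import build_schedule, Schedule
        from semcond.synthgen import AcquisitionConfig, generate_recording

        full = build_schedule("EXP1", 3)
        sched = Schedule(full.arm, full.trials[:6], 3)
        rec = generate_recording(sched, AcquisitionConfig(pad_s=5.0), seed=4)
        base = extract_epochs(rec, sched, EpochRole.BASELINE)
        onsets = rec.events_of("sentence_onset").set_index("trial_index")["sample"]
        for i, row in base.meta.iterrows():
            start = int(onsets.loc[row.trial_index]) - 1000
            raw = rec.signal[:, start : start + 1000]
            np.testing.assert_allclose(
                base.data[i] + base.reference_mean[i][:, None], raw, atol=1e-12
            )

    def test_out_of_bounds_reports_trials(self):
        from semcond.paradigm import build_schedule, Schedule
        from semcond.synthgen import AcquisitionConfig, generate_recording

        full = build_schedule("EXP1", 3)
        sched = Schedule(full.arm, full.trials[:4], 3)
        rec = generate_recording(sched, AcquisitionConfig(pad_s=5.0), seed=4)
        rec.signal = rec.signal[:, : int(rec.events["sample"].max()) - 200]
        with pytest.raises(ValueError, match="trial_index"):
            extract_epochs(rec, sched, EpochRole.POST_SENTENCE)

    def test_save_load_roundtrip(self, tmp_path, exp1_participant):
        _, post, _ = exp1_participant
        sub = post.select(np.arange(len(post)) < 8)
        sub.save(tmp_path / "epochs")
        back = EpochSet.load(tmp_path / "epochs")
        np.testing.assert_array_equal(back.data, sub.data)
        assert back.channels == sub.channels
        assert back.fs == sub.fs
        pd.testing.assert_frame_equal(
            back.meta, sub.meta.reset_index(drop=True), check_dtype=False
        )
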