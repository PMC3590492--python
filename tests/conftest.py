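"""Shared fixtures. Heavy synthetic cohorts are session-scoped and reused."""

from __future__ import annotations

from dataclasses import replace

import numpy as np
import pandas as pd
import pytest

from semcond.decode import ClassifierConfig, FeatureConfig
from semcond.paradigm import build_schedule
from semcond.pipeline import ERPSettings, RunConfig, run_cohort, simulate_participant
from semcond.preprocess import EpochSet
from semcond.synthgen import AcquisitionConfig, Recording

#: montage restricted to the AUC electrodes (cheap generation for ANOVA-only runs)
AUC_ONLY_ACQ = AcquisitionConfig(channels=("Cz", "Pz", "VEOG", "HEOG"))
AUC_ONLY_FEATURES = FeatureConfig(channels=("Cz", "Pz"))

FAST_CLF = ClassifierConfig(search=False)


def auc_only_config(**kwargs) -> RunConfig:
    return RunConfig(
        acquisition=AUC_ONLY_ACQ, features=AUC_ONLY_FEATURES, schemes=(), **kwargs
    )


@pytest.fixture(scope="session")
def exp1_schedule():
    return build_schedule("EXP1", 1)


@pytest.fixture(scope="session")
def exp1_participant():
    """One fully preprocessed conditioning-arm participant (default effect model)."""
    schedule, post, baseline = simulate_participant(RunConfig())
    return schedule, post, baseline


@pytest.fixture(scope="session")
def g3_participant():
    """One no-US control participant (300 unpaired trials per CS type)."""
    cfg = RunConfig(arm="EXP2_G3", schedule_seed=11, signal_seed=12)
    schedule, post, baseline = simulate_participant(cfg)
    return schedule, post, baseline


@pytest.fixture(scope="session")
def null_cohort():
    """10 participants under the null model (identical CS templates), Scheme I + AUC."""
    cfg = RunConfig(erp=ERPSettings(kind="null"))
    return run_cohort(cfg, n_participants=10, master_seed=101, schemes=("I",))


@pytest.fixture(scope="session")
def null_auc_batches():
    """Nine further 6-participant null batches, AUC electrodes only (no decoding)."""
    out = []
    for b in range(9):
        cfg = auc_only_config(erp=ERPSettings(kind="null"))
        res = run_cohort(cfg, n_participants=6, master_seed=211 + b, classify=False)
        out.append(res["auc"])
    return out


@pytest.fixture(scope="session")
def effect_cohort():
    """6 participants with the differential-conditioning effect model, all schemes."""
    cfg = RunConfig()  # defaults: CS1 d=0.5, CS2 d=0.8 vs baseline
    return run_cohort(cfg, n_participants=6, master_seed=301)


def synthetic_epochset(
    n_per_cell: int,
    channels=("Cz", "Pz"),
    phases=("ACQ", "UNPAIRED", "EXT"),
    cs_types=("CS1", "CS2"),
    fs: float = 500.0,
    n_samples: int = 1000,
    amplitudes: dict | None = None,
    noise_sd: float = 0.0,
    seed: int = 0,
    role: str = "POST_SENTENCE",
) -> EpochSet:
    """Hand-built epoch set: optional per-CS half-cosine bump + white noise."""
    rng = np.random.default_rng(seed)
    t = np.arange(n_samples) / fs * 1000.0
    u = (t - 700.0) / 1200.0
    bump = np.where(np.abs(u) < 0.5, np.cos(np.pi * u) ** 2, 0.0)
    rows, data = [], []
    idx = 0
    for phase in phases:
        for cs in cs_types:
            amp = (amplitudes or {}).get(cs, 0.0)
            for _ in range(n_per_cell):
                ep = amp * bump[None, :] + noise_sd * rng.standard_normal(
                    (len(channels), n_samples)
                )
                data.append(ep)
                rows.append(
                    {"trial_index": idx, "cs_type": cs, "phase": phase, "role": role}
                )
                idx += 1
    data = np.stack(data)
    return EpochSet(
        data=data,
        meta=pd.DataFrame(rows),
        channels=tuple(channels),
        fs=fs,
        window_ms=(0.0, n_samples / fs * 1000.0),
        reference_mean=np.zeros((len(rows), len(channels))),
    )


def flat_recording(
    value: float | np.ndarray,
    duration_s: float = 60.0,
    fs: float = 500.0,
    channels=("Cz", "Pz", "VEOG"),
    eog=("VEOG",),
) -> Recording:
    n = int(duration_s * fs)
    sig = np.broadcast_to(np.asarray(value, dtype=float), (len(channels), n)).copy()
    return Recording(
        signal=sig,
        fs=fs,
        channels=tuple(channels),
        events=pd.DataFrame(columns=["sample", "kind", "trial_index"]),
        eog_channels=tuple(eog),
    )
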