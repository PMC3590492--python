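"""Configuration, orchestration, and provenance for the full analysis.

One participant's pipeline runs: trial schedule -> synthetic recording ->
band-pass filter -> EOG regression -> post-sentence and baseline epochs ->
AUC table -> classification schemes. Cohort helpers repeat this over
participants with seeds derived from one master seed and feed the
repeated-measures ANOVA and the group accuracy report.

All stochastic stages take explicit seeds; a fixed configuration reproduces
byte-identical numeric outputs.
"""

from __future__ import annotations

import hashlib
import logging
from dataclasses import asdict, dataclass, field, replace
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .aucstats import build_auc_table, pairwise_contrasts, rm_anova
from .decode import (
    ClassifierConfig,
    ClassificationResult,
    FeatureConfig,
    SchemeSpec,
    assemble_scheme,
    crossval_classify,
)
from .paradigm import ARM_CONFIGS, Arm, Schedule, build_schedule, write_schedule_tsv
from .preprocess import EpochRole, EpochSet, FilterSpec, bandpass_filter, extract_epochs, remove_ocular
from .synthgen import (
    AUC_CHANNELS,
    AcquisitionConfig,
    CLASSIFICATION_CHANNELS,
    ERPModel,
    NoiseModel,
    generate_recording,
    inject_blinks,
)

__all__ = [
    "RunConfig",
    "validate_config",
    "derive_seeds",
    "simulate_participant",
    "run_pipeline",
    "run_cohort",
]

log = logging.getLogger("semcond")


def derive_seeds(master: int, n: int) -> list[int]:
    """n reproducible child seeds (< 2^31) from one master seed."""
    return [int(s) for s in np.random.SeedSequence(master).generate_state(n) % (2**31)]


@dataclass(frozen=True)
class ERPSettings:
    kind: str = "conditioned"  # "conditioned" or "null"
    cs1_effect_d: float = 0.5
    cs2_effect_d: float = 0.8
    latency_jitter_sd_ms: float = 50.0

    def build(self, noise: NoiseModel) -> ERPModel:
        if self.kind == "null":
            return ERPModel.null(self.cs1_effect_d, noise, self.latency_jitter_sd_ms)
        if self.kind == "conditioned":
            return ERPModel.conditioned(
                self.cs1_effect_d, self.cs2_effect_d, noise, self.latency_jitter_sd_ms
            )
        raise ValueError(f"unknown ERP model kind {self.kind!r}")


@dataclass(frozen=True)
class RunConfig:
    arm: str = "EXP1"
    schedule_seed: int = 1
    signal_seed: int = 2
    subsample_seed: int = 3
    fold_seed: int = 4
    erp: ERPSettings = field(default_factory=ERPSettings)
    noise: NoiseModel = field(default_factory=NoiseModel)
    acquisition: AcquisitionConfig = field(default_factory=AcquisitionConfig)
    filter: FilterSpec = field(default_factory=FilterSpec)
    features: FeatureConfig = field(default_factory=FeatureConfig)
    classifier: ClassifierConfig = field(default_factory=ClassifierConfig)
    schemes: tuple[str, ...] = ("I", "II", "III")
    k_folds: int = 10
    trials_per_class: int = 70
    auc_electrodes: tuple[str, ...] = AUC_CHANNELS
    auc_last_k: int = 20
    with_blinks: bool = False

    # -- serialization -----------------------------------------------------
    def to_dict(self) -> dict:
        d = asdict(self)
        d["noise"]["blink_coupling"] = dict(self.noise.blink_coupling)
        return d

    def to_yaml(self, path: str | Path | None = None) -> str:
        text = yaml.safe_dump(self.to_dict(), sort_keys=True)
        if path is not None:
            Path(path).write_text(text)
        return text

    @classmethod
    def from_dict(cls, d: dict) -> "RunConfig":
        d = dict(d)
        for key, typ in (
            ("erp", ERPSettings),
            ("noise", NoiseModel),
            ("filter", FilterSpec),
        ):
            if key in d and isinstance(d[key], dict):
                d[key] = typ(**d[key])
        if "acquisition" in d and isinstance(d["acquisition"], dict):
            a = dict(d["acquisition"])
            for f in ("channels", "eog_channels"):
                if f in a:
                    a[f] = tuple(a[f])
            d["acquisition"] = AcquisitionConfig(**a)
        if "features" in d and isinstance(d["features"], dict):
            f = dict(d["features"])
            if "channels" in f:
                f["channels"] = tuple(f["channels"])
            d["features"] = FeatureConfig(**f)
        if "classifier" in d and isinstance(d["classifier"], dict):
            c = dict(d["classifier"])
            for f in ("c_grid", "gamma_grid"):
                if f in c:
                    c[f] = tuple(c[f])
            d["classifier"] = ClassifierConfig(**c)
        for f in ("schemes", "auc_electrodes"):
            if f in d:
                d[f] = tuple(d[f])
        return cls(**d)

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        return cls.from_dict(yaml.safe_load(Path(path).read_text()))

    def config_hash(self) -> str:
        return hashlib.sha256(self.to_yaml().encode()).hexdigest()[:16]


def validate_config(config: RunConfig) -> list[str]:
    """All detectable configuration problems, without executing anything."""
    issues: list[str] = []
    try:
        Arm(config.arm)
    except ValueError:
        issues.append(f"unknown arm {config.arm!r}")
    issues.extend(config.filter.validate(config.acquisition.fs))
    for ch in config.features.channels:
        if ch not in config.acquisition.channels:
            issues.append(f"classification channel {ch} missing from montage")
    for ch in config.auc_electrodes:
        if ch not in config.acquisition.channels:
            issues.append(f"AUC electrode {ch} missing from montage")
    if config.k_folds > config.trials_per_class:
        issues.append(
            f"k_folds={config.k_folds} exceeds trials per class {config.trials_per_class}"
        )
    if config.features.decimation and 2000.0 * config.acquisition.fs / 1000.0 % config.features.decimation:
        issues.append("decimation factor must divide the epoch sample count")
    for s in config.schemes:
        if s not in ("I", "II", "III"):
            issues.append(f"unknown scheme {s!r}")
    return issues


def _provenance_lines(config: RunConfig, stage: str) -> str:
    return (
        f"# semcond {__version__} stage={stage} config_sha={config.config_hash()} "
        f"arm={config.arm}\n"
    )


def simulate_participant(
    config: RunConfig,
) -> tuple[Schedule, EpochSet, EpochSet]:
    """Schedule -> recording -> preprocessing -> (post-sentence, baseline) epochs."""
    issues = validate_config(config)
    if issues:
        raise ValueError("invalid configuration: " + "; ".join(issues))
    log.info("stage=schedule arm=%s seed=%d", config.arm, config.schedule_seed)
    schedule = build_schedule(config.arm, config.schedule_seed)
    noise = config.noise
    erp = config.erp.build(noise)
    log.info("stage=simulate seed=%d", config.signal_seed)
    rec = generate_recording(schedule, config.acquisition, erp, noise, config.signal_seed)
    if config.with_blinks:
        rec = inject_blinks(rec, noise, seed=config.signal_seed + 1)
    log.info("stage=preprocess")
    rec = bandpass_filter(rec, config.filter)
    rec = remove_ocular(rec)
    post = extract_epochs(rec, schedule, EpochRole.POST_SENTENCE)
    baseline = extract_epochs(rec, schedule, EpochRole.BASELINE)
    return schedule, post, baseline


def classify_participant(
    config: RunConfig, post: EpochSet, baseline: EpochSet
) -> dict[str, ClassificationResult]:
    """Run the configured schemes for one participant's epochs."""
    results: dict[str, ClassificationResult] = {}
    for scheme in config.schemes:
        x, y, info = assemble_scheme(
            post,
            baseline,
            SchemeSpec(scheme, config.trials_per_class),
            seed=config.subsample_seed,
            cfg=config.features,
        )
        res = crossval_classify(
            x,
            y,
            k=config.k_folds,
            clf=config.classifier,
            seed=config.fold_seed,
            scheme=scheme,
        )
        res.provenance.update(info, config_sha=config.config_hash())
        results[scheme] = res
        log.info("stage=classify scheme=%s acc=%.2f%%", scheme, res.mean_accuracy)
    return results


def run_pipeline(config: RunConfig, out_dir: str | Path | None = None) -> dict:
    """Full single-participant pipeline; optionally writes TSV outputs.

    Returns schedule, AUC table, the CS Type x Electrode x Phase ANOVA is
    left to cohort level (a single participant cannot support it); the
    classification results carry their chance interval and provenance.
    """
    schedule, post, baseline = simulate_participant(config)
    auc = build_auc_table(
        post,
        baseline,
        electrodes=config.auc_electrodes,
        k=config.auc_last_k,
        participant=f"{config.arm}-s{config.schedule_seed}",
    )
    results = classify_participant(config, post, baseline)
    bundle = {"schedule": schedule, "auc": auc, "classification": results}
    if out_dir is not None:
        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        write_schedule_tsv(schedule, out / "schedule.tsv")
        _write_tsv(auc, out / "auc.tsv", config, "auc")
        rows = [
            {
                "scheme": s,
                "mean_accuracy": r.round2(),
                "chance_lo": round(r.chance[0], 2),
                "chance_hi": round(r.chance[1], 2),
                "n_trials": r.n_trials,
                **{f"fold{i + 1}": round(a, 2) for i, a in enumerate(r.fold_accuracies)},
            }
            for s, r in results.items()
        ]
        _write_tsv(pd.DataFrame(rows), out / "classification.tsv", config, "classify")
    return bundle


def _write_tsv(df: pd.DataFrame, path: Path, config: RunConfig, stage: str) -> None:
    with open(path, "w") as fh:
        fh.write(_provenance_lines(config, stage))
        df.to_csv(fh, sep="\t", index=False)


def run_cohort(
    base_config: RunConfig,
    n_participants: int,
    master_seed: int,
    schemes: Sequence[str] | None = None,
    classify: bool = True,
    auc: bool = True,
) -> dict:
    """Simulate a cohort of participants with derived per-participant seeds.

    Returns per-participant classification accuracies (long table), the
    pooled AUC long table, and the per-scheme group means.
    """
    seeds = derive_seeds(master_seed, 4 * n_participants)
    acc_rows, auc_tables = [], []
    schemes = tuple(schemes) if schemes is not None else base_config.schemes
    for p in range(n_participants):
        s = seeds[4 * p : 4 * p + 4]
        cfg = replace(
            base_config,
            schedule_seed=s[0],
            signal_seed=s[1],
            subsample_seed=s[2],
            fold_seed=s[3],
            schemes=schemes,
        )
        pid = f"P{p + 1:02d}"
        schedule, post, baseline = simulate_participant(cfg)
        if auc:
            auc_tables.append(
                build_auc_table(
                    post,
                    baseline,
                    electrodes=cfg.auc_electrodes,
                    k=cfg.auc_last_k,
                    participant=pid,
                )
            )
        if classify:
            for scheme, res in classify_participant(cfg, post, baseline).items():
                acc_rows.append(
                    {
                        "group": cfg.arm,
                        "participant": pid,
                        "scheme": scheme,
                        "accuracy": res.mean_accuracy,
                        "chance_lo": res.chance[0],
                        "chance_hi": res.chance[1],
                    }
                )
        del post, baseline
    out = {
        "accuracies": pd.DataFrame(acc_rows),
        "auc": pd.concat(auc_tables, ignore_index=True) if auc_tables else pd.DataFrame(),
    }
    if acc_rows:
        from .decode import aggregate_results

        out["group_means"] = aggregate_results(out["accuracies"])
    return out


def cohort_anova(auc_table: pd.DataFrame) -> pd.DataFrame:
    """The CS Type x Electrode x Phase within-subject ANOVA on cohort AUCs."""
    return rm_anova(
        auc_table,
        dv="auc",
        within=["cs_type", "electrode", "phase"],
        subject="participant",
    )


def cohort_cs_contrasts(auc_table: pd.DataFrame) -> pd.DataFrame:
    """Planned pairwise contrasts on the CS Type factor (uncorrected)."""
    return pairwise_contrasts(auc_table, dv="auc", factor="cs_type", subject="participant")
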