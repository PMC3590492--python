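"""Trial scheduling for the two-session semantic conditioning paradigm.

The paradigm pairs spoken true statements (CS1, "yes" thinking) and false
statements (CS2, "no" thinking) with two aversive noises (US1/US2). Each
session holds three 100-sentence blocks; block 1 pairs every sentence with a
US (acquisition), blocks 2 and 3 leave 20 and 30 sentences unpaired
(intermittent conditioning), and the second session ends with a 40-sentence
extinction block. Every unpaired trial is immediately followed by a paired
one so the conditioned reaction is not extinguished during acquisition.

Four experimental arms are modeled: the original paradigm (``EXP1``), a
longer-US variant (``EXP2_G1``), an individually-selected-US variant
(``EXP2_G2``), and a no-conditioning control (``EXP2_G3``) in which the same
sentences are presented over two sessions without any US (and without an
extinction block, leaving 300 unpaired trials per CS type).
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from enum import Enum
from pathlib import Path

import numpy as np
import pandas as pd

__all__ = [
    "Arm",
    "CSType",
    "Phase",
    "ArmConfig",
    "ARM_CONFIGS",
    "BlockSpec",
    "TrialEvent",
    "Schedule",
    "build_schedule",
    "schedule_summary",
    "phase_totals",
    "unpaired_successor_check",
    "schedule_to_table",
    "write_schedule_tsv",
    "read_schedule_tsv",
]

ITI_S = 5.0  #: intertrial interval between US end (or sentence end) and next onset

#: nominal sentence duration used only for *planned* onset times in exports;
#: actual durations are drawn by the signal generator.
NOMINAL_SENTENCE_S = 3.0


class Arm(str, Enum):
    EXP1 = "EXP1"
    EXP2_G1 = "EXP2_G1"
    EXP2_G2 = "EXP2_G2"
    EXP2_G3 = "EXP2_G3"


class CSType(str, Enum):
    CS1 = "CS1"  # true statement -> "yes" thinking
    CS2 = "CS2"  # false statement -> "no" thinking


class Phase(str, Enum):
    ACQ = "ACQ"          # paired trial (CS+)
    UNPAIRED = "UNPAIRED"  # unpaired trial during intermittent conditioning (CS-)
    EXT = "EXT"          # extinction-block trial (CS-ext)


@dataclass(frozen=True)
class ArmConfig:
    """US configuration of one experimental arm."""

    arm_id: Arm
    us1_kind: str | None
    us2_kind: str | None
    us_duration_ms: float
    us_present: bool

    def __post_init__(self) -> None:
        if self.arm_id is Arm.EXP1 and not (
            self.us_duration_ms == 500 and self.us_present
        ):
            raise ValueError("EXP1 uses 500 ms USs on paired trials")
        if self.arm_id is Arm.EXP2_G1 and self.us_duration_ms != 1000:
            raise ValueError("EXP2_G1 uses 1000 ms USs")
        if self.arm_id is Arm.EXP2_G3 and self.us_present:
            raise ValueError("EXP2_G3 is the no-US control arm")

    def us_kind_for(self, cs_type: CSType) -> str | None:
        if not self.us_present:
            return None
        return self.us1_kind if cs_type is CSType.CS1 else self.us2_kind


ARM_CONFIGS: dict[Arm, ArmConfig] = {
    Arm.EXP1: ArmConfig(Arm.EXP1, "pink-noise", "white-noise", 500, True),
    Arm.EXP2_G1: ArmConfig(Arm.EXP2_G1, "pink-noise", "white-noise", 1000, True),
    Arm.EXP2_G2: ArmConfig(Arm.EXP2_G2, "pink-noise", "individual-noise", 500, True),
    Arm.EXP2_G3: ArmConfig(Arm.EXP2_G3, None, None, 0, False),
}


@dataclass(frozen=True)
class BlockSpec:
    session: int
    block: int
    n_sentences: int
    n_unpaired: int
    is_extinction: bool = False

    def __post_init__(self) -> None:
        if self.n_sentences % 2:
            raise ValueError("blocks must balance true/false statements")
        if not 0 <= self.n_unpaired <= self.n_sentences:
            raise ValueError("invalid unpaired count")
        if self.n_unpaired % 2:
            raise ValueError("unpaired trials must split equally by CS type")
        if self.is_extinction and self.n_unpaired != self.n_sentences:
            raise ValueError("extinction blocks are entirely unpaired")


#: per-session block layout of the conditioning arms (sessions are identical
#: except for the extinction block closing session 2)
_CONDITIONING_BLOCKS = (
    BlockSpec(0, 1, 100, 0),
    BlockSpec(0, 2, 100, 20),
    BlockSpec(0, 3, 100, 30),
)
_EXTINCTION_BLOCK = BlockSpec(2, 4, 40, 40, is_extinction=True)


def blocks_for(arm: ArmConfig, session: int) -> tuple[BlockSpec, ...]:
    """Block layout of one session (1-based) for a given arm."""
    base = tuple(replace(b, session=session) for b in _CONDITIONING_BLOCKS)
    if arm.us_present and session == 2:
        return base + (_EXTINCTION_BLOCK,)
    return base


@dataclass(frozen=True)
class TrialEvent:
    trial_index: int
    session: int
    block: int
    cs_type: CSType
    paired: bool
    phase: Phase
    us_kind: str | None
    iti_s: float = ITI_S

    def __post_init__(self) -> None:
        if self.paired != (self.phase is Phase.ACQ):
            raise ValueError("paired trials are exactly the ACQ-phase trials")
        if (self.us_kind is None) != (not self.paired):
            raise ValueError("us_kind must be set iff the trial is paired")


@dataclass(frozen=True)
class Schedule:
    arm: ArmConfig
    trials: tuple[TrialEvent, ...]
    seed: int

    def __len__(self) -> int:
        return len(self.trials)

    def __iter__(self):
        return iter(self.trials)


def _nonadjacent_positions(n: int, k: int, rng: np.random.Generator) -> np.ndarray:
    """k positions in [0, n-2], pairwise non-adjacent, uniformly at random.

    Uses the standard bijection between k-subsets of {0..n-k-1} and
    non-adjacent k-subsets of {0..n-2}: add i to the i-th order statistic.
    The final block position is excluded so an unpaired trial always has a
    successor within the block.
    """
    if k == 0:
        return np.empty(0, dtype=int)
    if n - 1 < 2 * k - 1:
        raise ValueError(f"cannot place {k} non-adjacent trials in {n} slots")
    base = np.sort(rng.choice(n - k, size=k, replace=False))
    return base + np.arange(k)


def _build_block(
    arm: ArmConfig,
    spec: BlockSpec,
    rng: np.random.Generator,
    start_index: int,
) -> list[TrialEvent]:
    n = spec.n_sentences
    half = n // 2
    if spec.is_extinction or not arm.us_present:
        unpaired_mask = np.ones(n, dtype=bool)
    else:
        unpaired_mask = np.zeros(n, dtype=bool)
        unpaired_mask[_nonadjacent_positions(n, spec.n_unpaired, rng)] = True

    # CS types: equal split overall *and* within the unpaired subset, so the
    # two-session per-type totals land exactly on the design counts.
    def _shuffled_types(n_cs1: int, total: int) -> list[CSType]:
        types = [CSType.CS1] * n_cs1 + [CSType.CS2] * (total - n_cs1)
        return [types[i] for i in rng.permutation(total)]

    k_unp = int(unpaired_mask.sum())
    unp_iter = iter(_shuffled_types(k_unp // 2, k_unp))
    paired_iter = iter(_shuffled_types(half - k_unp // 2, n - k_unp))
    cs: list[CSType] = [
        next(unp_iter) if unpaired_mask[i] else next(paired_iter) for i in range(n)
    ]

    if spec.is_extinction:
        phase_unpaired = Phase.EXT
    else:
        phase_unpaired = Phase.UNPAIRED

    trials = []
    for i in range(n):
        paired = not unpaired_mask[i]
        cs_type = cs[i]
        trials.append(
            TrialEvent(
                trial_index=start_index + i,
                session=spec.session,
                block=spec.block,
                cs_type=cs_type,
                paired=paired,
                phase=Phase.ACQ if paired else phase_unpaired,
                us_kind=arm.us_kind_for(cs_type) if paired else None,
            )
        )
    return trials


def build_schedule(arm: ArmConfig | Arm | str, seed: int) -> Schedule:
    """Build the full two-session trial plan for one participant.

    Deterministic for a fixed ``(arm, seed)``. Conditioning arms yield 640
    trials (250 paired, 50 unpaired, 20 extinction per CS type); the control
    arm yields 600 all-unpaired trials (300 per CS type).
    """
    if not isinstance(arm, ArmConfig):
        arm = ARM_CONFIGS[Arm(arm)]
    rng = np.random.default_rng(seed)
    trials: list[TrialEvent] = []
    for session in (1, 2):
        for spec in blocks_for(arm, session):
            trials.extend(_build_block(arm, spec, rng, start_index=len(trials)))
    return Schedule(arm=arm, trials=tuple(trials), seed=seed)


def schedule_summary(s: Schedule) -> pd.DataFrame:
    """Trial counts per (cs_type, phase, session, block), long format."""
    if not s.trials:
        return pd.DataFrame(columns=["cs_type", "phase", "session", "block", "n"])
    df = schedule_to_table(s)
    out = (
        df.groupby(["cs_type", "phase", "session", "block"], observed=True)
        .size()
        .rename("n")
        .reset_index()
    )
    assert int(out["n"].sum()) == len(s)
    return out


def phase_totals(s: Schedule) -> dict[tuple[CSType, Phase], int]:
    """Two-session totals per (cs_type, phase) — the design-count margins."""
    totals: dict[tuple[CSType, Phase], int] = {}
    for t in s.trials:
        key = (t.cs_type, t.phase)
        totals[key] = totals.get(key, 0) + 1
    return totals


def unpaired_successor_check(s: Schedule) -> bool:
    """True iff every unpaired trial in a mixed block is followed by a paired one.

    The rule protects the conditioned reaction from extinction during blocks 2
    and 3; all-unpaired blocks (extinction block, control arm) are exempt.
    """
    from itertools import groupby

    for _, block_iter in groupby(s.trials, key=lambda t: (t.session, t.block)):
        block = list(block_iter)
        if not any(t.paired for t in block):
            continue  # all-unpaired block: rule not applicable
        for i, t in enumerate(block):
            if not t.paired:
                if i + 1 >= len(block) or not block[i + 1].paired:
                    return False
    return True


_TABLE_COLUMNS = [
    "trial_index",
    "session",
    "block",
    "cs_type",
    "paired",
    "phase",
    "us_kind",
    "planned_onset_s",
]


def schedule_to_table(s: Schedule) -> pd.DataFrame:
    """Flat table of the schedule with nominal planned onset times."""
    rows = []
    t = 0.0
    for tr in s.trials:
        rows.append(
            {
                "trial_index": tr.trial_index,
                "session": tr.session,
                "block": tr.block,
                "cs_type": tr.cs_type.value,
                "paired": tr.paired,
                "phase": tr.phase.value,
                "us_kind": tr.us_kind if tr.us_kind is not None else "none",
                "planned_onset_s": round(t, 3),
            }
        )
        t += NOMINAL_SENTENCE_S
        if tr.paired:
            t += s.arm.us_duration_ms / 1000.0
        t += tr.iti_s
    return pd.DataFrame(rows, columns=_TABLE_COLUMNS)


def write_schedule_tsv(s: Schedule, path: str | Path) -> None:
    df = schedule_to_table(s)
    with open(path, "w") as fh:
        fh.write(f"# semcond schedule arm={s.arm.arm_id.value} seed={s.seed}\n")
        df.to_csv(fh, sep="\t", index=False)


def read_schedule_tsv(path: str | Path) -> Schedule:
    """Re-hydrate a Schedule from its TSV export (round-trips losslessly)."""
    with open(path) as fh:
        header = fh.readline().strip()
        df = pd.read_csv(fh, sep="\t")
    meta = dict(
        item.split("=", 1) for item in header.lstrip("# ").split() if "=" in item
    )
    arm = ARM_CONFIGS[Arm(meta.get("arm", "EXP1"))]
    trials = tuple(
        TrialEvent(
            trial_index=int(r.trial_index),
            session=int(r.session),
            block=int(r.block),
            cs_type=CSType(r.cs_type),
            paired=bool(r.paired),
            phase=Phase(r.phase),
            us_kind=None if r.us_kind == "none" else r.us_kind,
        )
        for r in df.itertuples()
    )
    return Schedule(arm=arm, trials=trials, seed=int(meta.get("seed", -1)))
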