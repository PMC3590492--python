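#!/usr/bin/env python
"""Build and summarize the conditioning schedules for all four arms.

Verifies the design arithmetic (640 trials; 250 paired / 50 unpaired / 20
extinction per CS type in the conditioning arms; 600 all-unpaired trials in
the control arm) and the rule that every unpaired trial is immediately
followed by a paired one. Writes per-arm count tables and one example
schedule under results/.
"""

from pathlib import Path

import pandas as pd

from semcond.paradigm import (
    build_schedule,
    phase_totals,
    schedule_summary,
    unpaired_successor_check,
    write_schedule_tsv,
)

OUT = Path(__file__).resolve().parents[1] / "results"
OUT.mkdir(exist_ok=True)


def main() -> None:
    rows = []
    for arm in ("EXP1", "EXP2_G1", "EXP2_G2", "EXP2_G3"):
        s = build_schedule(arm, seed=1)
        ok = unpaired_successor_check(s)
        print(f"{arm}: {len(s)} trials, successor rule {'holds' if ok else 'VIOLATED'}")
        for (cs, phase), n in sorted(
            phase_totals(s).items(), key=lambda kv: (kv[0][0].value, kv[0][1].value)
        ):
            rows.append({"arm": arm, "cs_type": cs.value, "phase": phase.value, "n": n})
            print(f"  {cs.value} {phase.value:9s} {n}")
    pd.DataFrame(rows).to_csv(OUT / "schedule_counts.tsv", sep="\t", index=False)

    s = build_schedule("EXP1", seed=1)
    write_schedule_tsv(s, OUT / "schedule_exp1_seed1.tsv")
    schedule_summary(s).to_csv(OUT / "schedule_exp1_summary.tsv", sep="\t", index=False)
    print(f"\ntables -> {OUT}/schedule_counts.tsv, schedule_exp1_summary.tsv")


if __name__ == "__main__":
    main()
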