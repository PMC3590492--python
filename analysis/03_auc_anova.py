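#!/usr/bin/env python
"""AUC-increase statistics and the repeated-measures ANOVA on a cohort.

Simulates a 6-participant differential-conditioning cohort, computes the
per-participant AUC_ri tables (mean of the last 20 segments per CS Type x
Electrode x Phase cell), screens them for normality, and runs the
CS Type (CS1, CS2, baseline) x Electrode (Cz, Pz) x Phase (paired,
unpaired, extinction) within-subject ANOVA with Greenhouse-Geisser
correction plus planned CS Type contrasts.
"""

from pathlib import Path

from semcond.aucstats import normality_screen
from semcond.pipeline import RunConfig, cohort_anova, cohort_cs_contrasts, run_cohort

OUT = Path(__file__).resolve().parents[1] / "results"
OUT.mkdir(exist_ok=True)

N_PARTICIPANTS = 6
MASTER_SEED = 301


def main() -> None:
    cohort = run_cohort(
        RunConfig(), N_PARTICIPANTS, MASTER_SEED, classify=False
    )
    auc = cohort["auc"]
    auc.to_csv(OUT / "auc_table.tsv", sep="\t", index=False)

    screen = normality_screen(auc)
    excluded = screen[~screen["include"]]["participant"].tolist()
    print(f"normality screen: {len(excluded)} flagged participant(s) {excluded}")

    anova = cohort_anova(auc)
    anova.to_csv(OUT / "auc_anova.tsv", sep="\t", index=False)
    print("\nCS Type x Electrode x Phase rm-ANOVA (GG-corrected):")
    print(anova.to_string(index=False, float_format=lambda v: f"{v:.4f}"))

    contrasts = cohort_cs_contrasts(auc)
    contrasts.to_csv(OUT / "auc_contrasts.tsv", sep="\t", index=False)
    print("\nplanned CS Type contrasts:")
    print(contrasts.to_string(index=False, float_format=lambda v: f"{v:.4f}"))
    print(f"\ntables -> {OUT}/auc_table.tsv, auc_anova.tsv, auc_contrasts.tsv")


if __name__ == "__main__":
    main()
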