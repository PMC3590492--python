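#!/usr/bin/env python
"""Simulate one conditioning participant and run the preprocessing chain.

Generates a full two-session synthetic recording (500 Hz, 12 channels,
conditioned responses calibrated to AUC effect sizes d = 0.5 / 0.8 for
CS1 / CS2 vs baseline), band-pass filters it (0.009-30 Hz, zero phase),
regresses out the EOG, and cuts the 2000 ms post-sentence and baseline
epochs. Writes the epoch metadata summary and a short EDF excerpt with its
event table under results/.
"""

from pathlib import Path

from semcond.edf import write_edf, write_events_tsv
from semcond.pipeline import RunConfig, simulate_participant
from semcond.synthgen import generate_recording

OUT = Path(__file__).resolve().parents[1] / "results"
OUT.mkdir(exist_ok=True)


def main() -> None:
    cfg = RunConfig(schedule_seed=1, signal_seed=2)
    schedule, post, baseline = simulate_participant(cfg)
    print(f"schedule: {len(schedule)} trials")
    print(f"post-sentence epochs: {post.data.shape} (trials x channels x samples)")
    print(f"baseline epochs:      {baseline.data.shape}")
    counts = post.meta.groupby(["cs_type", "phase"]).size().rename("n").reset_index()
    print(counts.to_string(index=False))
    counts.to_csv(OUT / "epoch_counts.tsv", sep="\t", index=False)

    # small EDF excerpt for interchange (first 60 s of a fresh realization);
    # binary output goes under scratch/, not results/
    scratch = OUT.parent / "scratch"
    scratch.mkdir(exist_ok=True)
    rec = generate_recording(schedule, cfg.acquisition, cfg.erp.build(cfg.noise),
                             cfg.noise, cfg.signal_seed)
    excerpt = rec.copy()
    excerpt.signal = excerpt.signal[:, : int(60 * rec.fs)]
    excerpt.events = excerpt.events[excerpt.events["sample"] < excerpt.n_samples]
    write_edf(excerpt, scratch / "recording_excerpt.edf")
    write_events_tsv(excerpt, scratch / "recording_excerpt_events.tsv")
    print(f"excerpt -> {scratch}/recording_excerpt.edf")


if __name__ == "__main__":
    main()
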