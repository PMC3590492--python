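"""Published per-participant single-trial accuracies (percent).

The per-participant RBF-SVM accuracies reported for the original experiment
(14 participants) and the three six-participant variant groups are inputs to
the aggregation and chance-level analyses: group means are *recomputed* from
these values rather than copied. Scheme I is "yes" vs "no", Scheme II "yes"
vs baseline, Scheme III "no" vs baseline.
"""

from __future__ import annotations

import pandas as pd

from .decode import aggregate_results

__all__ = ["published_accuracies", "published_group_means"]

_ROWS: list[tuple[str, str, float, float, float]] = [
    # (group, participant, scheme I, scheme II, scheme III)
    ("EXP1", "E1.1", 62.90, 56.40, 60.70),
    ("EXP1", "E1.2", 50.00, 50.00, 66.40),
    ("EXP1", "E1.3", 48.60, 59.30, 63.60),
    ("EXP1", "E1.4", 44.30, 76.40, 80.00),
    ("EXP1", "E1.5", 59.30, 70.00, 70.00),
    ("EXP1", "E1.6", 46.40, 50.00, 60.70),
    ("EXP1", "E1.7", 50.00, 80.70, 73.60),
    ("EXP1", "E1.8", 54.30, 68.60, 74.30),
    ("EXP1", "E1.9", 45.70, 71.40, 82.90),
    ("EXP1", "E1.10", 43.60, 74.30, 75.70),
    ("EXP1", "E1.11", 49.30, 67.10, 64.30),
    ("EXP1", "E1.12", 52.10, 72.90, 77.90),
    ("EXP1", "E1.13", 45.00, 60.00, 64.30),
    ("EXP1", "E1.14", 55.70, 58.60, 49.30),
    ("EXP2_G1", "G1.1", 44.28, 77.14, 76.43),
    ("EXP2_G1", "G1.2", 51.42, 59.29, 61.43),
    ("EXP2_G1", "G1.3", 52.85, 67.14, 65.00),
    ("EXP2_G1", "G1.4", 54.28, 41.43, 45.71),
    ("EXP2_G1", "G1.5", 45.71, 47.14, 53.57),
    ("EXP2_G1", "G1.6", 51.42, 61.43, 65.71),
    ("EXP2_G2", "G2.1", 54.29, 55.71, 64.29),
    ("EXP2_G2", "G2.2", 51.43, 75.00, 75.00),
    ("EXP2_G2", "G2.3", 62.14, 52.86, 63.57),
    ("EXP2_G2", "G2.4", 51.43, 53.57, 57.86),
    ("EXP2_G2", "G2.5", 50.00, 54.29, 63.57),
    ("EXP2_G2", "G2.6", 47.86, 45.00, 52.14),
    ("EXP2_G3", "G3.1", 48.57, 66.43, 54.29),
    ("EXP2_G3", "G3.2", 46.43, 69.29, 67.14),
    ("EXP2_G3", "G3.3", 50.71, 47.86, 51.43),
    ("EXP2_G3", "G3.4", 50.71, 47.86, 55.71),
    ("EXP2_G3", "G3.5", 43.57, 61.43, 65.00),
    ("EXP2_G3", "G3.6", 51.43, 51.43, 55.00),
]


def published_accuracies() -> pd.DataFrame:
    """Long-format table: group, participant, scheme (I/II/III), accuracy (%)."""
    wide = pd.DataFrame(_ROWS, columns=["group", "participant", "I", "II", "III"])
    return wide.melt(
        id_vars=["group", "participant"],
        value_vars=["I", "II", "III"],
        var_name="scheme",
        value_name="accuracy",
    ).sort_values(["group", "scheme", "participant"], kind="stable").reset_index(drop=True)


def published_group_means() -> pd.DataFrame:
    """Recomputed per-group, per-scheme mean accuracies (2 dp)."""
    return aggregate_results(published_accuracies())
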