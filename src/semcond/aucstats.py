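"""AUC-increase statistics and repeated-measures ANOVA.

The conditioned EEG reactions show no clear peaked components, so amplitude
is quantified by the area under the curve with respect to increase (AUC_ri):
the trapezoidal integral of the signal minus its first value over the
analysis window. AUC_ri ignores each point's distance from zero and measures
change over time; it is invariant under adding a constant to the window and
linear in the signal.

Per trial type the AUC is averaged over the last 20 segments (the number of
extinction segments available per CS type), giving one cell per participant
in a CS Type (CS1, CS2, baseline) x Electrode (Cz, Pz) x Phase (paired,
unpaired, extinction) design, analyzed with a repeated-measures ANOVA with
Greenhouse-Geisser correction and planned (uncorrected) contrasts.
"""

from __future__ import annotations

import itertools
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .preprocess import EpochSet
from .synthgen import AUC_CHANNELS

__all__ = [
    "auc_ri",
    "last_k_mean",
    "build_auc_table",
    "rm_anova",
    "pairwise_contrasts",
    "normality_screen",
]

LAST_K_DEFAULT = 20


def auc_ri(samples: np.ndarray, dt: float) -> np.ndarray | float:
    """Area under the curve with respect to increase, trapezoid rule.

    ``auc_ri(x, dt) = trapezoid(x - x[0]) = trapezoid(x) - x[0] * (n-1) * dt``.
    Works on the last axis of any array shape; requires >= 2 uniformly
    spaced samples.
    """
    x = np.asarray(samples, dtype=float)
    if x.shape[-1] < 2:
        raise ValueError("auc_ri requires at least 2 samples")
    if dt <= 0:
        raise ValueError("dt must be positive")
    out = np.trapezoid(x - x[..., :1], dx=dt, axis=-1)
    return float(out) if out.ndim == 0 else out


def last_k_mean(values: Sequence[float], k: int = LAST_K_DEFAULT) -> float:
    """Mean of the final ``k`` values in presentation order; no silent fallback."""
    v = np.asarray(values, dtype=float)
    if v.ndim != 1:
        raise ValueError("expected a 1-D value sequence")
    if len(v) < k:
        raise ValueError(f"need at least k={k} values, got {len(v)}")
    return float(v[-k:].mean())


def build_auc_table(
    epochs: EpochSet,
    baseline: EpochSet,
    electrodes: Sequence[str] = AUC_CHANNELS,
    k: int = LAST_K_DEFAULT,
    participant: str | int | None = None,
) -> pd.DataFrame:
    """Mean last-``k`` AUC_ri per (cs_type, electrode, phase) cell.

    CS1/CS2 cells integrate the post-sentence epochs of that type and phase;
    BASELINE cells integrate the pre-sentence baseline epochs of the trials
    in that phase, pooled over CS types. Trials are ordered by presentation
    (trial index) before the last-``k`` averaging.
    """
    dt = 1.0 / epochs.fs
    phases = sorted(epochs.meta["phase"].unique())
    rows = []

    def cell_mean(eset: EpochSet, mask: np.ndarray, electrode: str, cell: str) -> float:
        idx = np.flatnonzero(mask)
        if idx.size == 0:
            raise ValueError(f"AUC table cell {cell} has no epochs")
        order = idx[np.argsort(eset.meta.loc[idx, "trial_index"].to_numpy())]
        vals = auc_ri(eset.data[order, eset.channel_index(electrode), :], dt)
        try:
            return last_k_mean(vals, k)
        except ValueError as err:
            raise ValueError(f"AUC table cell {cell}: {err}") from None

    for phase in phases:
        for electrode in electrodes:
            for cs in ("CS1", "CS2"):
                mask = (
                    (epochs.meta["cs_type"] == cs) & (epochs.meta["phase"] == phase)
                ).to_numpy()
                rows.append(
                    {
                        "participant": participant,
                        "cs_type": cs,
                        "electrode": electrode,
                        "phase": phase,
                        "auc": cell_mean(epochs, mask, electrode, f"({cs},{electrode},{phase})"),
                    }
                )
            bmask = (baseline.meta["phase"] == phase).to_numpy()
            rows.append(
                {
                    "participant": participant,
                    "cs_type": "BASELINE",
                    "electrode": electrode,
                    "phase": phase,
                    "auc": cell_mean(
                        baseline, bmask, electrode, f"(BASELINE,{electrode},{phase})"
                    ),
                }
            )
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# repeated-measures ANOVA (univariate approach with Greenhouse-Geisser)
# ---------------------------------------------------------------------------


def _orthonormal_contrasts(k: int) -> np.ndarray:
    """(k, k-1) orthonormal basis of the contrast space (orthogonal to 1)."""
    h = np.eye(k) - np.ones((k, k)) / k
    u, s, _ = np.linalg.svd(h)
    return u[:, : k - 1]


def _gg_epsilon(s_pooled: np.ndarray) -> float:
    """Greenhouse-Geisser epsilon from the covariance of the transformed data."""
    q = s_pooled.shape[0]
    if q == 1:
        return 1.0
    denom = q * np.sum(s_pooled * s_pooled.T)
    if denom <= 0:
        return 1.0  # degenerate (zero-variance) projection
    eps = np.trace(s_pooled) ** 2 / denom
    return float(np.clip(eps, 1.0 / q, 1.0))


def _pivot_wide(
    data: pd.DataFrame, dv: str, within: Sequence[str], subject: str
) -> tuple[np.ndarray, list[tuple], pd.Index]:
    counts = data.groupby([subject, *within], observed=True)[dv].count()
    if (counts != 1).any():
        raise ValueError(
            "design must be balanced and complete: exactly one observation "
            "per subject per within-cell (aggregate replicates first)"
        )
    wide = data.pivot_table(index=subject, columns=list(within), values=dv, observed=True)
    if wide.isna().any().any():
        raise ValueError("design has missing subject x cell combinations")
    wide = wide.sort_index(axis=1)
    cells = list(wide.columns) if len(within) > 1 else [(c,) for c in wide.columns]
    return wide.to_numpy(), cells, wide.index


def rm_anova(
    data: pd.DataFrame,
    dv: str,
    within: Sequence[str] | str,
    subject: str,
    between: str | None = None,
) -> pd.DataFrame:
    """Repeated-measures / split-plot ANOVA with Greenhouse-Geisser correction.

    Handles any number of within-subject factors and at most one
    between-subjects factor. Each within effect is tested by projecting the
    subject x cell matrix onto an orthonormal contrast basis (a Kronecker
    product of per-factor contrasts and averaging vectors); the
    Greenhouse-Geisser epsilon is estimated from the covariance of the
    projected scores. Returns one row per effect with ``F``, uncorrected and
    GG-corrected ``p``, ``eps``, and partial eta squared.
    """
    within = [within] if isinstance(within, str) else list(within)
    if not within:
        raise ValueError("at least one within factor is required")
    y, cells, subjects = _pivot_wide(data, dv, within, subject)
    n, p = y.shape
    if n < 2:
        raise ValueError("need at least 2 subjects")

    levels = [sorted(set(c[i] for c in cells)) for i in range(len(within))]
    # cells are sorted lexicographically, consistent with kron ordering
    contrasts = [_orthonormal_contrasts(len(lv)) for lv in levels]
    means = [np.full((len(lv), 1), 1.0 / len(lv)) for lv in levels]

    groups = None
    if between is not None:
        glab = (
            data.drop_duplicates(subject)
            .set_index(subject)[between]
            .reindex(subjects)
        )
        if glab.isna().any():
            raise ValueError("every subject needs a between-group label")
        groups = glab.to_numpy()
        glevels, gcounts = np.unique(groups, return_counts=True)
        if len(glevels) < 2:
            raise ValueError("between factor needs >= 2 groups")
        if (gcounts < 2).any():
            raise ValueError("need >= 2 subjects per group")

    rows = []

    if between is not None:
        # between-subjects main effect on the subject means across cells
        m = y.mean(axis=1)
        grand = m.mean()
        ss_b = sum(
            (m[groups == g].size) * (m[groups == g].mean() - grand) ** 2
            for g in glevels
        )
        ss_w = sum(((m[groups == g] - m[groups == g].mean()) ** 2).sum() for g in glevels)
        df1, df2 = len(glevels) - 1, n - len(glevels)
        f = (ss_b / df1) / (ss_w / df2) if ss_w > 0 else np.inf
        p_unc = float(stats.f.sf(f, df1, df2))
        rows.append(
            {
                "effect": between,
                "df1": df1,
                "df2": df2,
                "F": float(f),
                "eps": 1.0,
                "p_unc": p_unc,
                "p_gg": p_unc,
                "partial_eta_sq": float(ss_b / (ss_b + ss_w)) if ss_b + ss_w > 0 else 0.0,
            }
        )

    for r in range(1, len(within) + 1):
        for combo in itertools.combinations(range(len(within)), r):
            mats = [contrasts[i] if i in combo else means[i] for i in range(len(within))]
            m_eff = mats[0]
            for mat in mats[1:]:
                m_eff = np.kron(m_eff, mat)
            z = y @ m_eff  # (n, q)
            q = z.shape[1]
            zbar = z.mean(axis=0)
            name = ":".join(within[i] for i in combo)
            # numerically-exact-zero guard (constant data projects to ~0)
            tiny = 1e-12 * max(1.0, float((y**2).sum()))

            if between is None:
                ss_eff = n * float(zbar @ zbar)
                resid = z - zbar
                ss_err = float((resid**2).sum())
                if ss_eff < tiny:
                    ss_eff = 0.0
                if ss_err < tiny:
                    ss_err = 0.0
                df1, df2 = q, q * (n - 1)
                s_pooled = np.atleast_2d(np.cov(z, rowvar=False, ddof=1))
                _append_within_row(rows, name, ss_eff, ss_err, df1, df2, s_pooled)
            else:
                gmeans = {g: z[groups == g].mean(axis=0) for g in glevels}
                ss_eff = n * float(zbar @ zbar)
                ss_int = sum(
                    (groups == g).sum() * float(gmeans[g] @ gmeans[g]) for g in glevels
                ) - ss_eff
                resid = z - np.stack([gmeans[g] for g in groups])
                ss_err = float((resid**2).sum())
                ss_eff, ss_int, ss_err = (
                    0.0 if v < tiny else v for v in (ss_eff, ss_int, ss_err)
                )
                ngrp = len(glevels)
                s_pooled = sum(
                    ((groups == g).sum() - 1)
                    * np.atleast_2d(np.cov(z[groups == g], rowvar=False, ddof=1))
                    for g in glevels
                ) / (n - ngrp)
                _append_within_row(rows, name, ss_eff, ss_err, q, q * (n - ngrp), s_pooled)
                _append_within_row(
                    rows,
                    f"{name}:{between}",
                    ss_int,
                    ss_err,
                    q * (ngrp - 1),
                    q * (n - ngrp),
                    s_pooled,
                )
    return pd.DataFrame(rows)


def _append_within_row(
    rows: list,
    name: str,
    ss_eff: float,
    ss_err: float,
    df1: int,
    df2: int,
    s_pooled: np.ndarray,
) -> None:
    eps = _gg_epsilon(s_pooled)
    ms_err = ss_err / df2 if df2 > 0 else np.nan
    f = (ss_eff / df1) / ms_err if ms_err > 0 else (np.inf if ss_eff > 0 else 0.0)
    p_unc = float(stats.f.sf(f, df1, df2))
    p_gg = float(stats.f.sf(f, df1 * eps, df2 * eps))
    rows.append(
        {
            "effect": name,
            "df1": df1,
            "df2": df2,
            "F": float(f),
            "eps": eps,
            "p_unc": p_unc,
            "p_gg": p_gg,
            "partial_eta_sq": float(ss_eff / (ss_eff + ss_err))
            if ss_eff + ss_err > 0
            else 0.0,
        }
    )


def pairwise_contrasts(
    data: pd.DataFrame,
    dv: str,
    factor: str,
    subject: str,
    levels: Sequence | None = None,
) -> pd.DataFrame:
    """Planned pairwise contrasts on one within factor (paired t, uncorrected).

    Collapses all other factors by per-subject averaging, then runs a paired
    t-test for every level pair (or the given ordered subset).
    """
    cellmeans = data.groupby([subject, factor], observed=True)[dv].mean().unstack(factor)
    if cellmeans.isna().any().any():
        raise ValueError("every subject needs data at every factor level")
    levels = list(levels) if levels is not None else list(cellmeans.columns)
    rows = []
    for a, b in itertools.combinations(levels, 2):
        diff = cellmeans[a] - cellmeans[b]
        t, p = stats.ttest_rel(cellmeans[a], cellmeans[b])
        rows.append(
            {
                "level_a": a,
                "level_b": b,
                "mean_diff": float(diff.mean()),
                "t": float(t),
                "df": len(diff) - 1,
                "p": float(p),
            }
        )
    return pd.DataFrame(rows)


def normality_screen(
    values: Mapping[str | int, Sequence[float]] | pd.DataFrame,
    alpha: float = 0.05,
    dv: str = "auc",
    participant: str = "participant",
) -> pd.DataFrame:
    """Shapiro-Wilk screening of per-participant value distributions.

    Returns one row per participant with the test statistic, p value, a
    ``testable`` flag (False for degenerate/constant input) and an
    ``include`` flag (False when normality is rejected at ``alpha``).
    Exclusion is advisory: callers decide whether to act on the flags.
    """
    if isinstance(values, pd.DataFrame):
        values = {k: g[dv].to_numpy() for k, g in values.groupby(participant)}
    rows = []
    for pid, v in values.items():
        v = np.asarray(v, dtype=float)
        if len(v) < 3:
            raise ValueError(f"participant {pid}: need >= 3 values for Shapiro-Wilk")
        if np.ptp(v) == 0:
            rows.append(
                {"participant": pid, "n": len(v), "W": np.nan, "p": np.nan,
                 "testable": False, "include": True}
            )
            continue
        w, p = stats.shapiro(v)
        rows.append(
            {"participant": pid, "n": len(v), "W": float(w), "p": float(p),
             "testable": True, "include": bool(p >= alpha)}
        )
    return pd.DataFrame(rows)
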