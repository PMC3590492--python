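"""AUC-increase statistic, cell aggregation, and the rm-ANOVA engine."""

import numpy as np
import pandas as pd
import pingouin as pg
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy import stats

from semcond.aucstats import (
    auc_ri,
    build_auc_table,
    last_k_mean,
    normality_screen,
    pairwise_contrasts,
    rm_anova,
)

from conftest import synthetic_epochset


def brute_force_auc_ri(x, dt):
    """Sum of per-interval trapezoids of (x - x[0]); the independent oracle."""
    y = [v - x[0] for v in x]
    return sum((y[i] + y[i + 1]) / 2.0 * dt for i in range(len(y) - 1))


class TestAucRi:
    def test_constant_is_zero(self):
        assert auc_ri(np.full(50, 3.7), 0.002) == pytest.approx(0.0, abs=1e-12)

    def test_linear_ramp_triangle_area(self):
        n, a = 501, 4.0
        t_total = (n - 1) * 0.002
        x = np.linspace(0, a, n)
        assert auc_ri(x, 0.002) == pytest.approx(a * t_total / 2.0, rel=1e-12)

    def test_matches_brute_force_oracle(self):
        rng = np.random.default_rng(0)
        for _ in range(100):
            x = rng.normal(size=10)
            assert auc_ri(x, 0.002) == pytest.approx(
                brute_force_auc_ri(x, 0.002), rel=1e-10, abs=1e-14
            )

    def test_shift_invariance_and_linearity(self):
        rng = np.random.default_rng(1)
        x, y = rng.normal(size=200), rng.normal(size=200)
        assert auc_ri(x + 5.0, 0.002) == pytest.approx(auc_ri(x, 0.002), abs=1e-10)
        assert auc_ri(x + y, 0.002) == pytest.approx(
            auc_ri(x, 0.002) + auc_ri(y, 0.002), abs=1e-10
        )

    def test_too_short_rejected(self):
        with pytest.raises(ValueError):
            auc_ri(np.array([1.0]), 0.002)


class TestLastKMean:
    def test_identical_values(self):
        assert last_k_mean([2.5] * 20, 20) == 2.5

    def test_final_window(self):
        assert last_k_mean(np.arange(1, 26), 20) == pytest.approx(15.5)

    def test_insufficient_values_rejected(self):
        with pytest.raises(ValueError, match="k=20"):
            last_k_mean(np.arange(19), 20)


class TestAucTable:
    def test_amplitude_ordering_without_noise(self):
        post = synthetic_epochset(25, amplitudes={"CS1": 3.0, "CS2": 5.0})
        base = synthetic_epochset(25, amplitudes={}, role="BASELINE")
        table = build_auc_table(post, base, k=20, participant="p")
        wide = table.pivot_table(index="phase", columns="cs_type", values="auc")
        for phase in wide.index:
            assert wide.loc[phase, "CS2"] > wide.loc[phase, "CS1"] > wide.loc[phase, "BASELINE"]

    def test_null_symmetry(self):
        post = synthetic_epochset(
            40, amplitudes={"CS1": 2.0, "CS2": 2.0}, noise_sd=1.0, seed=3
        )
        base = synthetic_epochset(40, noise_sd=1.0, seed=4, role="BASELINE")
        table = build_auc_table(post, base, k=20)
        cells = table.groupby("cs_type")["auc"].mean()
        # identical templates: CS1 and CS2 agree within Monte-Carlo error
        mc_sd = 3.0  # generous bound for 20-trial cell means of unit noise
        assert abs(cells["CS1"] - cells["CS2"]) < mc_sd

    def test_uses_exactly_last_k(self):
        post = synthetic_epochset(25, amplitudes={"CS1": 1.0, "CS2": 1.0})
        # overwrite Cz of the first 5 CS1/ACQ epochs; they must not matter for k=20
        mask = ((post.meta.cs_type == "CS1") & (post.meta.phase == "ACQ")).to_numpy()
        idx = np.flatnonzero(mask)[:5]
        bumped = post.data.copy()
        bumped[idx] += 1e6
        post2 = synthetic_epochset(25, amplitudes={"CS1": 1.0, "CS2": 1.0})
        post2.data = bumped
        base = synthetic_epochset(25, role="BASELINE")
        t1 = build_auc_table(post, base, k=20)
        t2 = build_auc_table(post2, base, k=20)
        pd.testing.assert_frame_equal(t1, t2)

    def test_short_cell_reported_by_name(self):
        base = synthetic_epochset(25, phases=("ACQ",), role="BASELINE")
        small = synthetic_epochset(5, phases=("ACQ",))
        with pytest.raises(ValueError, match="CS1"):
            build_auc_table(small, base, k=20)


def _textbook_oneway_rm(wide):
    """Classic sums-of-squares one-way repeated-measures ANOVA + GG epsilon."""
    n, k = wide.shape
    grand = wide.values.mean()
    ss_cond = n * ((wide.mean(axis=0) - grand) ** 2).sum()
    ss_subj = k * ((wide.mean(axis=1) - grand) ** 2).sum()
    ss_tot = ((wide.values - grand) ** 2).sum()
    ss_err = ss_tot - ss_cond - ss_subj
    f = (ss_cond / (k - 1)) / (ss_err / ((k - 1) * (n - 1)))
    # GG epsilon from the double-centered covariance matrix
    s = np.cov(wide.values, rowvar=False, ddof=1)
    sc = s - s.mean(axis=0) - s.mean(axis=1)[:, None] + s.mean()
    eps = np.trace(sc) ** 2 / ((k - 1) * np.sum(sc * sc))
    return f, eps


class TestRmAnova:
    def test_two_level_equals_squared_paired_t(self):
        rng = np.random.default_rng(2)
        rows = [
            {"s": i, "a": lv, "y": rng.normal(0.4 * j, 1)}
            for i in range(12)
            for j, lv in enumerate(["l0", "l1"])
        ]
        df = pd.DataFrame(rows)
        res = rm_anova(df, "y", "a", "s")
        wide = df.pivot(index="s", columns="a", values="y")
        t, p = stats.ttest_rel(wide["l0"], wide["l1"])
        assert res.F[0] == pytest.approx(t**2, rel=1e-10)
        assert res.eps[0] == 1.0
        assert res.p_unc[0] == pytest.approx(p, rel=1e-10)

    def test_all_equal_gives_zero_f(self):
        rows = [{"s": i, "a": f"l{j}", "y": float(i)} for i in range(6) for j in range(3)]
        res = rm_anova(pd.DataFrame(rows), "y", "a", "s")
        assert res.F[0] == 0.0

    def test_textbook_five_by_three(self):
        rng = np.random.default_rng(7)
        rows = [
            {"s": i, "a": f"l{j}", "y": rng.normal(0.5 * j, 1.0)}
            for i in range(5)
            for j in range(3)
        ]
        df = pd.DataFrame(rows)
        res = rm_anova(df, "y", "a", "s")
        f, eps = _textbook_oneway_rm(df.pivot(index="s", columns="a", values="y"))
        assert res.F[0] == pytest.approx(f, rel=1e-10)
        assert res.eps[0] == pytest.approx(eps, rel=1e-10)

    def test_matches_pingouin_oneway(self):
        rng = np.random.default_rng(11)
        rows = [
            {"s": i, "a": f"l{j}", "y": rng.normal(0.3 * j, 1.0)}
            for i in range(14)
            for j in range(3)
        ]
        df = pd.DataFrame(rows)
        mine = rm_anova(df, "y", "a", "s")
        ref = pg.rm_anova(
            data=df, dv="y", within="a", subject="s", correction=True, detailed=True
        )
        assert mine.F[0] == pytest.approx(float(ref["F"][0]), rel=1e-8)
        assert mine.eps[0] == pytest.approx(float(ref["eps"][0]), rel=1e-8)
        assert mine.p_gg[0] == pytest.approx(float(ref["p_GG_corr"][0]), rel=1e-6)

    def test_matches_pingouin_mixed(self):
        rng = np.random.default_rng(13)
        rows = []
        for g in range(2):
            for i in range(8):
                for j in range(3):
                    rows.append(
                        {
                            "s": f"g{g}i{i}",
                            "grp": f"G{g}",
                            "a": f"l{j}",
                            "y": rng.normal(0.4 * g + 0.2 * j + 0.1 * g * j, 1.0),
                        }
                    )
        df = pd.DataFrame(rows)
        mine = rm_anova(df, "y", "a", "s", between="grp").set_index("effect")
        ref = pg.mixed_anova(
            data=df, dv="y", within="a", subject="s", between="grp"
        ).set_index("Source")
        for ours, theirs in (("grp", "grp"), ("a", "a"), ("a:grp", "Interaction")):
            assert mine.loc[ours, "F"] == pytest.approx(float(ref.loc[theirs, "F"]), rel=1e-8)
            assert mine.loc[ours, "p_unc"] == pytest.approx(
                float(ref.loc[theirs, "p_unc"]), rel=1e-6
            )

    def test_three_way_within_runs_and_epsilon_bounded(self):
        rng = np.random.default_rng(17)
        rows = []
        for i in range(10):
            for cs in ("CS1", "CS2", "BASELINE"):
                for el in ("Cz", "Pz"):
                    for ph in ("ACQ", "UNPAIRED", "EXT"):
                        rows.append(
                            {"s": i, "cs": cs, "el": el, "ph": ph, "y": rng.normal()}
                        )
        res = rm_anova(pd.DataFrame(rows), "y", ["cs", "el", "ph"], "s")
        assert set(res.effect) == {
            "cs", "el", "ph", "cs:el", "cs:ph", "el:ph", "cs:el:ph",
        }
        for _, row in res.iterrows():
            q = row.df1
            assert 1.0 / q <= row.eps <= 1.0 + 1e-12
            assert row.F >= 0.0
            assert 0.0 <= row.partial_eta_sq <= 1.0

    def test_unbalanced_rejected(self):
        rows = [{"s": i, "a": f"l{j}", "y": 0.0} for i in range(4) for j in range(3)]
        df = pd.DataFrame(rows).drop(index=0)
        with pytest.raises(ValueError, match="balanced|missing"):
            rm_anova(df, "y", "a", "s")

    def test_type_one_error_calibrated_on_null(self):
        """Uncorrected p rejects at about the nominal rate on spherical null data."""
        rng = np.random.default_rng(23)
        rejections = 0
        reps = 200
        for _ in range(reps):
            y = rng.standard_normal((10, 3))
            df = pd.DataFrame(
                [
                    {"s": i, "a": f"l{j}", "y": y[i, j]}
                    for i in range(10)
                    for j in range(3)
                ]
            )
            res = rm_anova(df, "y", "a", "s")
            rejections += res.p_unc[0] < 0.05
        assert 3 <= rejections <= 19  # central 99% band of Binomial(200, 0.05)


class TestContrasts:
    def test_pairwise_matches_paired_t(self):
        rng = np.random.default_rng(3)
        rows = [
            {"s": i, "a": lv, "y": rng.normal(j * 0.5, 1)}
            for i in range(10)
            for j, lv in enumerate(["x", "y", "z"])
        ]
        df = pd.DataFrame(rows)
        res = pairwise_contrasts(df, "y", "a", "s").set_index(["level_a", "level_b"])
        wide = df.pivot(index="s", columns="a", values="y")
        t, p = stats.ttest_rel(wide["x"], wide["z"])
        assert res.loc[("x", "z"), "t"] == pytest.approx(t, rel=1e-10)
        assert res.loc[("x", "z"), "p"] == pytest.approx(p, rel=1e-10)


class TestNormalityScreen:
    def test_gaussian_included(self):
        rng = np.random.default_rng(5)
        out = normality_screen({"p1": rng.standard_normal(50)})
        assert out.loc[0, "testable"] and out.loc[0, "include"]

    def test_skewed_usually_excluded(self):
        rng = np.random.default_rng(6)
        excluded = 0
        for _ in range(20):
            out = normality_screen({"p": rng.exponential(size=50)})
            excluded += not out.loc[0, "include"]
        assert excluded >= 15  # Shapiro-Wilk has high power against exp(1) at n=50

    def test_constant_flagged_nontestable(self):
        out = normality_screen({"p": np.full(10, 1.0)})
        assert not out.loc[0, "testable"]

    def test_too_few_values_rejected(self):
        with pytest.raises(ValueError):
            normality_screen({"p": [1.0, 2.0]})
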