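"""RM-ANOVA decomposition, adjusted RT, and load-RT partial correlations."""

import numpy as np
import pandas as pd
import pytest

import lexload as ll


def _load_table(n_subjects, seed=0, effects=True):
    rng = np.random.default_rng(seed)
    conds = list(ll.CONDITIONS)
    comps = list(ll.COMPONENTS)
    rows = []
    for i in range(n_subjects):
        subj_eff = rng.normal(0, 1)
        for ci, c in enumerate(conds):
            for ki, k in enumerate(comps):
                val = subj_eff + rng.normal(0, 0.5)
                if effects:
                    val += 0.8 * ci + 0.5 * ki + 0.3 * ci * ki
                rows.append({"subject": f"s{i:02d}", "condition": c,
                             "component": k, "load": val})
    return pd.DataFrame(rows)


def anova_ss_oracle(df):
    """Direct sums-of-squares decomposition by explicit cell means."""
    piv = df.pivot_table(index="subject", columns=["condition", "component"],
                         values="load")
    conds = sorted(df["condition"].unique())
    comps = sorted(df["component"].unique())
    Y = piv.to_numpy().reshape(len(piv), len(conds), len(comps))
    s, a, b = Y.shape
    g = Y.mean()
    ss = {}
    ss["condition"] = sum(
        s * b * (Y[:, i, :].mean() - g) ** 2 for i in range(a))
    ss["component"] = sum(
        s * a * (Y[:, :, j].mean() - g) ** 2 for j in range(b))
    ss["interaction"] = sum(
        s * (Y[:, i, j].mean() - Y[:, i, :].mean() - Y[:, :, j].mean() + g) ** 2
        for i in range(a) for j in range(b))
    ss["subject"] = sum(a * b * (Y[i].mean() - g) ** 2 for i in range(s))
    ss["subj_x_cond"] = sum(
        b * (Y[i, j, :].mean() - Y[i].mean() - Y[:, j, :].mean() + g) ** 2
        for i in range(s) for j in range(a))
    ss["subj_x_comp"] = sum(
        a * (Y[i, :, j].mean() - Y[i].mean() - Y[:, :, j].mean() + g) ** 2
        for i in range(s) for j in range(b))
    ss["total"] = ((Y - g) ** 2).sum()
    return ss, Y


class TestRmAnova:
    def test_identical_cells_give_zero_f(self):
        df = _load_table(6, effects=False)
        df["load"] = 2.0
        res = ll.rm_anova_two_way(df)
        assert np.allclose(res.table["F"], 0.0)
        assert np.allclose(res.table["p"], 1.0)

    def test_matches_ss_oracle(self):
        df = _load_table(10, seed=1)
        res = ll.rm_anova_two_way(df)
        ss, Y = anova_ss_oracle(df)
        s, a, b = Y.shape
        tab = res.table.set_index("effect")
        f_cond = (ss["condition"] / (a - 1)) / (ss["subj_x_cond"] / ((s - 1) * (a - 1)))
        f_comp = (ss["component"] / (b - 1)) / (ss["subj_x_comp"] / ((s - 1) * (b - 1)))
        ss_res = (ss["total"] - ss["subject"] - ss["condition"] - ss["component"]
                  - ss["interaction"] - ss["subj_x_cond"] - ss["subj_x_comp"])
        f_int = (ss["interaction"] / ((a - 1) * (b - 1))) / (
            ss_res / ((s - 1) * (a - 1) * (b - 1)))
        assert tab.loc["condition", "F"] == pytest.approx(f_cond, abs=1e-8)
        assert tab.loc["component", "F"] == pytest.approx(f_comp, abs=1e-8)
        assert tab.loc["condition:component", "F"] == pytest.approx(f_int, abs=1e-8)

    def test_matches_pingouin(self):
        pingouin = pytest.importorskip("pingouin")
        df = _load_table(12, seed=2)
        res = ll.rm_anova_two_way(df)
        pg = pingouin.rm_anova(data=df, dv="load", within=["condition", "component"],
                               subject="subject", detailed=True)
        tab = res.table.set_index("effect")
        pg = pg.set_index("Source")
        assert tab.loc["condition", "F"] == pytest.approx(
            pg.loc["condition", "F"], rel=1e-6)
        assert tab.loc["component", "F"] == pytest.approx(
            pg.loc["component", "F"], rel=1e-6)
        assert tab.loc["condition:component", "F"] == pytest.approx(
            pg.loc["condition * component", "F"], rel=1e-6)

    def test_subject_relabeling_leaves_f_unchanged(self):
        df = _load_table(8, seed=3)
        res1 = ll.rm_anova_two_way(df)
        relabel = {f"s{i:02d}": f"x{(i * 7) % 8:02d}" for i in range(8)}
        df2 = df.assign(subject=df["subject"].map(relabel))
        res2 = ll.rm_anova_two_way(df2)
        np.testing.assert_allclose(res1.table["F"], res2.table["F"], atol=1e-10)

    def test_ss_conservation(self):
        df = _load_table(9, seed=4)
        res = ll.rm_anova_two_way(df)
        ss, Y = anova_ss_oracle(df)
        parts = res.table["ss"].sum() + res.table["ss_error"].sum() + ss["subject"]
        assert parts == pytest.approx(ss["total"], abs=1e-8)

    def test_missing_cells_rejected(self):
        df = _load_table(5).iloc[:-1]
        with pytest.raises(ValueError, match="s04"):
            ll.rm_anova_two_way(df)

    def test_posthoc_bonferroni_monotone_and_bounded(self):
        df = _load_table(10, seed=5)
        res = ll.rm_anova_two_way(df)
        ph = res.posthoc
        assert np.all(ph["p_bonferroni"] >= ph["p_raw"] - 1e-15)
        assert np.all(ph["p_bonferroni"] <= 1.0)
        order = np.argsort(ph["p_raw"].to_numpy())
        assert np.all(np.diff(ph["p_bonferroni"].to_numpy()[order]) >= -1e-15)


def _behavior(n_subjects=10, seed=0):
    rng = np.random.default_rng(seed)
    rows = []
    for i in range(n_subjects):
        off = rng.normal(0, 100)
        for c in ll.CONDITIONS:
            rows.append({"subject": f"s{i:02d}", "condition": c,
                         "rt_ms": 1000 + off + 100 * ll.CONDITION_LABELS[c]
                         + rng.normal(0, 30)})
    return pd.DataFrame(rows)


class TestAdjustedRt:
    def test_identical_subjects_unchanged(self):
        df = _behavior(6, seed=1)
        # make all subjects identical
        base = df[df["subject"] == "s00"].set_index("condition")["rt_ms"]
        df["rt_ms"] = df["condition"].map(base)
        out = ll.adjusted_rt(df)
        np.testing.assert_allclose(out["adjusted_rt"], df["rt_ms"], atol=1e-8)

    def test_constant_shift_removed(self):
        df = _behavior(8, seed=2)
        out1 = ll.adjusted_rt(df)
        df2 = df.copy()
        df2.loc[df2["subject"] == "s03", "rt_ms"] += 500.0
        out2 = ll.adjusted_rt(df2)
        a = out1[out1["subject"] == "s03"]["adjusted_rt"].to_numpy()
        b = out2[out2["subject"] == "s03"]["adjusted_rt"].to_numpy()
        # the shift is absorbed into the subject offset; only the grand mean
        # (shared by everyone) moves, so the subject's profile is unchanged
        np.testing.assert_allclose(a - a.mean(), b - b.mean(), atol=1e-6)
        assert b.mean() - a.mean() == pytest.approx(500.0 / 8, abs=1e-6)

    def test_balanced_equals_centering_plus_grand_mean(self):
        df = _behavior(10, seed=3)
        out = ll.adjusted_rt(df).merge(df, on=["subject", "condition"])
        grand = df["rt_ms"].mean()
        subj_mean = df.groupby("subject")["rt_ms"].mean()
        expect = out["rt_ms"] - out["subject"].map(subj_mean) + grand
        np.testing.assert_allclose(out["adjusted_rt"], expect, atol=1e-8)

    def test_single_condition_subject_dropped(self):
        df = _behavior(5)
        df = pd.concat([df, pd.DataFrame([{"subject": "lone", "condition":
                                           "chinese_word", "rt_ms": 900.0}])])
        with pytest.warns(UserWarning, match="lone"):
            out = ll.adjusted_rt(df)
        assert "lone" not in set(out["subject"])


class TestPartialPearson:
    def test_empty_controls_equal_plain_pearson(self):
        rng = np.random.default_rng(0)
        x, y = rng.normal(size=30), rng.normal(size=30)
        r, _ = ll.partial_pearson(y, x, None)
        assert r == pytest.approx(np.corrcoef(x, y)[0, 1], abs=1e-12)

    def test_matches_pingouin(self):
        pingouin = pytest.importorskip("pingouin")
        rng = np.random.default_rng(1)
        df = pd.DataFrame(rng.normal(size=(40, 4)), columns=["y", "x", "c1", "c2"])
        r, p = ll.partial_pearson(df["y"].to_numpy(), df["x"].to_numpy(),
                                  df[["c1", "c2"]].to_numpy())
        pg = pingouin.partial_corr(df, x="x", y="y", covar=["c1", "c2"])
        assert r == pytest.approx(float(pg["r"].iloc[0]), abs=1e-10)
        assert p == pytest.approx(float(pg["p_val"].iloc[0]), abs=1e-10)

    def test_too_few_observations_rejected(self):
        with pytest.raises(ValueError):
            ll.partial_pearson(np.ones(4), np.ones(4), np.ones((4, 2)))


class TestLoadRtAssociation:
    def _tables(self, n=50, seed=0, plant=0.6):
        rng = np.random.default_rng(seed)
        rows, brows = [], []
        for i in range(n):
            s = f"s{i:02d}"
            loads = {}
            for c in ll.CONDITIONS:
                for k in ll.COMPONENTS:
                    loads[(c, k)] = rng.normal(5, 1)
                    rows.append({"subject": s, "condition": c, "component": k,
                                 "load": loads[(c, k)]})
            for c in ll.CONDITIONS:
                rt = 1000 + 50 * plant * (loads[(c, "logo")] - 5) + rng.normal(0, 50 * np.sqrt(1 - plant**2))
                brows.append({"subject": s, "condition": c, "rt_ms": rt})
        return pd.DataFrame(rows), pd.DataFrame(brows)

    def test_duplicated_control_kills_correlation(self):
        loads, beh = self._tables(30, seed=1)
        adj = ll.adjusted_rt(beh)
        # duplicate the target component as one of the controls
        dup = loads.copy()
        dup.loc[dup["component"] == "phonology", "load"] = (
            loads.loc[loads["component"] == "logo", "load"].to_numpy())
        res = ll.load_rt_partial_correlation(dup, adj)
        row = res.table[(res.table["condition"] == "chinese_word")
                        & (res.table["component"] == "logo")].iloc[0]
        assert abs(row["partial_r"]) < 1e-6

    def test_planted_partial_structure_recovered(self):
        loads, beh = self._tables(50, seed=2, plant=0.6)
        adj = ll.adjusted_rt(beh)
        res = ll.load_rt_partial_correlation(loads, adj)
        for cond in ll.CONDITIONS:
            row = res.table[(res.table["condition"] == cond)
                            & (res.table["component"] == "logo")].iloc[0]
            assert row["partial_r"] == pytest.approx(0.6, abs=0.25)

    def test_family_one_means_no_correction(self):
        loads, beh = self._tables(20, seed=3)
        adj = ll.adjusted_rt(beh)
        res = ll.load_rt_partial_correlation(loads, adj, family=1)
        np.testing.assert_allclose(res.table["p_bonferroni"], res.table["p_raw"])

    def test_family_recorded(self):
        loads, beh = self._tables(20, seed=4)
        res = ll.load_rt_partial_correlation(loads, ll.adjusted_rt(beh), family=9)
        assert res.family_size == 9
        assert np.all(res.table["p_bonferroni"] <= 1.0)
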