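"""Group statistics: Mann-Whitney with effect size, FDR, mixed ANOVA,
paired t, partial Spearman, drinking measures."""

import itertools

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from oddconn.stats import (
    drinking_measures,
    fdr_adjust,
    mann_whitney_effect,
    paired_t_by_channel,
    partial_spearman,
    rm_anova,
)
from oddconn.synth import simulate_drinking


def _brute_force_u(a, b):
    return sum(
        1.0 if x > y else (0.5 if x == y else 0.0)
        for x, y in itertools.product(a, b)
    )


class TestMannWhitney:
    def test_complete_separation(self):
        u, p, r = mann_whitney_effect([1, 2, 3], [4, 5, 6])
        assert u == _brute_force_u([1, 2, 3], [4, 5, 6]) == 0.0
        assert r == 1.0

    def test_identical_groups_zero_effect(self):
        u, p, r = mann_whitney_effect([1, 2, 3], [1, 2, 3])
        assert r == 0.0
        assert p == pytest.approx(1.0)

    def test_interleaved_enumeration(self):
        u, p, r = mann_whitney_effect([1, 3], [2, 4])
        assert u == _brute_force_u([1, 3], [2, 4]) == 1.0

    @pytest.mark.parametrize("seed", range(5))
    def test_u_matches_brute_force(self, seed):
        rng = np.random.default_rng(seed)
        a, b = rng.normal(size=6), rng.normal(1, 1, size=7)
        u, _, r = mann_whitney_effect(a, b)
        bf = _brute_force_u(a, b)
        assert u == bf
        assert r == pytest.approx(1 - 2 * bf / 42)

    def test_small_groups_rejected(self):
        with pytest.raises(ValueError):
            mann_whitney_effect([1.0], [2.0, 3.0])


class TestFdr:
    def test_hand_computed_example(self):
        adj = fdr_adjust([0.01, 0.02, 0.03])
        assert np.allclose(adj, [0.03, 0.03, 0.03])

    def test_single_value_unchanged(self):
        assert fdr_adjust([0.2])[0] == pytest.approx(0.2)

    def test_equal_values_fixed_point(self):
        assert np.allclose(fdr_adjust([0.04] * 5), 0.04)

    def test_adjusted_at_least_raw(self):
        rng = np.random.default_rng(0)
        p = rng.random(50)
        adj = fdr_adjust(p)
        assert np.all(adj >= p - 1e-12)
        assert np.all(adj <= 1.0)

    def test_monotone_in_rank(self):
        rng = np.random.default_rng(1)
        p = np.sort(rng.random(30))
        adj = fdr_adjust(p)
        assert np.all(np.diff(adj) >= -1e-12)

    def test_out_of_range_rejected(self):
        with pytest.raises(ValueError):
            fdr_adjust([0.1, 1.5])

    @settings(derandomize=True, max_examples=50, deadline=None)
    @given(
        st.lists(
            st.floats(min_value=0.0, max_value=1.0, allow_nan=False),
            min_size=1, max_size=40,
        )
    )
    def test_step_up_properties_hold_for_any_input(self, p):
        # adjusted values dominate raw ones, stay in [0, 1], and respect
        # the raw ordering (step-up monotonicity)
        p = np.asarray(p)
        adj = fdr_adjust(p)
        assert np.all(adj >= p - 1e-12)
        assert np.all((adj >= 0) & (adj <= 1))
        order = np.argsort(p, kind="stable")
        assert np.all(np.diff(adj[order]) >= -1e-12)

    @settings(derandomize=True, max_examples=50, deadline=None)
    @given(
        st.lists(st.floats(-1e3, 1e3), min_size=2, max_size=10, unique=True),
        st.lists(st.floats(-1e3, 1e3), min_size=2, max_size=10, unique=True),
    )
    def test_rank_biserial_bounded_and_antisymmetric(self, a, b):
        _, _, r_ab = mann_whitney_effect(a, b)
        _, _, r_ba = mann_whitney_effect(b, a)
        assert -1.0 - 1e-12 <= r_ab <= 1.0 + 1e-12
        assert r_ab == pytest.approx(-r_ba, abs=1e-9)


def _tidy(Y, groups, treats, chans):
    rows = []
    for si in range(Y.shape[0]):
        for bi, tr in enumerate(treats):
            for ci, ch in enumerate(chans):
                rows.append((f"s{si}", groups[si], tr, ch, Y[si, bi, ci]))
    return pd.DataFrame(
        rows, columns=["subject", "group", "treatment", "channel", "value"]
    )


class TestRmAnova:
    def test_all_equal_values_give_zero_f(self):
        Y = np.full((6, 2, 3), 4.2)
        tab = rm_anova(_tidy(Y, ["a"] * 3 + ["b"] * 3, ["pre", "post"],
                             ["c1", "c2", "c3"]))
        assert np.allclose(tab["F"], 0.0)

    def test_within_effects_match_anovarm_oracle(self):
        # one-group design: treatment/channel/interaction F must equal the
        # two-way repeated-measures ANOVA from an independent implementation
        from statsmodels.stats.anova import AnovaRM

        rng = np.random.default_rng(0)
        Y = rng.normal(size=(8, 2, 3))
        df = _tidy(Y, ["a"] * 8, ["pre", "post"], ["c1", "c2", "c3"])
        ours = rm_anova(df).set_index("effect")
        ref = AnovaRM(
            df, depvar="value", subject="subject",
            within=["treatment", "channel"],
        ).fit().anova_table
        assert ours.loc["treatment", "F"] == pytest.approx(
            ref.loc["treatment", "F Value"]
        )
        assert ours.loc["channel", "F"] == pytest.approx(
            ref.loc["channel", "F Value"]
        )
        assert ours.loc["treatment:channel", "F"] == pytest.approx(
            ref.loc["treatment:channel", "F Value"]
        )

    def test_collapses_to_paired_t(self):
        # 2 within-levels, 1 channel, 1 group: F(treatment) == t^2
        from scipy.stats import ttest_rel

        rng = np.random.default_rng(1)
        Y = rng.normal(size=(10, 2, 1))
        df = _tidy(Y, ["a"] * 10, ["pre", "post"], ["c1"])
        tab = rm_anova(df).set_index("effect")
        t = ttest_rel(Y[:, 1, 0], Y[:, 0, 0]).statistic
        assert tab.loc["treatment", "F"] == pytest.approx(t**2)

    def test_injected_group_shift_detected_and_null_calibrated(self):
        rng = np.random.default_rng(2)
        Y = rng.normal(size=(12, 2, 3))
        Y[:6] += 3.0  # pure group shift for the first 6 subjects
        df = _tidy(Y, ["a"] * 6 + ["b"] * 6, ["pre", "post"], list("xyz"))
        tab = rm_anova(df).set_index("effect")
        assert tab.loc["group", "p"] < 0.01
        # treatment p uniform under its null: check over repeated simulations
        ps = []
        for s in range(200):
            r2 = np.random.default_rng(100 + s)
            Yn = r2.normal(size=(6, 2, 2))
            dfn = _tidy(Yn, ["a"] * 3 + ["b"] * 3, ["pre", "post"], ["u", "v"])
            ps.append(rm_anova(dfn).set_index("effect").loc["treatment", "p"])
        assert 0.01 < np.mean(np.array(ps) < 0.05) < 0.12

    def test_unbalanced_design_instructs_imputation(self):
        Y = np.random.default_rng(3).normal(size=(4, 2, 2))
        df = _tidy(Y, ["a"] * 2 + ["b"] * 2, ["pre", "post"], ["c1", "c2"])
        with pytest.raises(ValueError, match="[Ii]mpute"):
            rm_anova(df.drop(index=0))


class TestPairedT:
    def test_no_change_gives_t_zero_p_one(self):
        x = np.random.default_rng(0).normal(size=(6, 3))
        out = paired_t_by_channel(x, x)
        assert np.allclose(out["t"], 0.0)
        assert np.allclose(out["p"], 1.0)
        assert out["zero_variance"].all()

    def test_constant_shift_flagged_with_p_zero(self):
        x = np.random.default_rng(1).normal(size=(5, 2))
        out = paired_t_by_channel(x, x + 1.0)
        assert np.all(np.isinf(out["t"]))
        assert np.allclose(out["p"], 0.0)
        assert out["zero_variance"].all()

    def test_type_one_error_calibrated(self):
        # 2,000 null simulations, alpha = 0.05
        rng = np.random.default_rng(2)
        pre = rng.normal(size=(2000, 10, 1))
        post = rng.normal(size=(2000, 10, 1))
        hits = 0
        for i in range(2000):
            out = paired_t_by_channel(pre[i], post[i])
            hits += out["p"].iloc[0] < 0.05
        rate = hits / 2000
        assert abs(rate - 0.05) < 2.2 * np.sqrt(0.05 * 0.95 / 2000) + 1e-9

    def test_length_mismatch_rejected(self):
        with pytest.raises(ValueError):
            paired_t_by_channel(np.zeros((4, 2)), np.zeros((5, 2)))


class TestPartialSpearman:
    def test_monotone_identity(self):
        rng = np.random.default_rng(0)
        x = rng.normal(size=50)
        z = rng.normal(size=50)
        rho, p = partial_spearman(x, x.copy(), z)
        assert rho > 0.99
        assert p < 1e-6

    def test_partialling_out_nulls_shared_covariate(self):
        rhos = []
        for s in range(50):
            rng = np.random.default_rng(s)
            z = rng.normal(size=60)
            x = rng.normal(size=60)
            rho, _ = partial_spearman(x, z + 0.001 * rng.normal(size=60), z)
            rhos.append(rho)
        assert abs(np.mean(rhos)) < 0.05

    def test_known_partial_correlation_recovered(self):
        # trivariate normal with partial corr(x, y | z) = 0.5; the Monte
        # Carlo mean over replicates must recover it (rank-based estimate
        # of a Pearson 0.5 sits slightly below, ~0.48 for normal data)
        vals = []
        for s in range(10):
            rng = np.random.default_rng(s)
            n = 200
            z = rng.normal(size=n)
            e1, e2 = rng.normal(size=n), rng.normal(size=n)
            x = z + e1
            y = z + (0.5 * e1 + np.sqrt(1 - 0.25) * e2)
            vals.append(partial_spearman(x, y, z)[0])
        assert np.mean(vals) == pytest.approx(0.5, abs=0.1)

    def test_agrees_with_pingouin(self):
        pingouin = pytest.importorskip("pingouin")
        rng = np.random.default_rng(2)
        df = pd.DataFrame(rng.normal(size=(40, 3)), columns=["x", "y", "z"])
        df["y"] += 0.5 * df["x"]
        rho, p = partial_spearman(df["x"], df["y"], df["z"])
        ref = pingouin.partial_corr(df, x="x", y="y", covar="z",
                                    method="spearman")
        assert rho == pytest.approx(float(ref["r"].iloc[0]), abs=1e-6)
        assert p == pytest.approx(float(ref["p_val"].iloc[0]), rel=1e-3)

    def test_constant_input_rejected(self):
        with pytest.raises(ValueError):
            partial_spearman(np.ones(10), np.arange(10), np.arange(10))


class TestDrinkingMeasures:
    def test_constant_intake_trivials(self):
        rows = []
        schedule = [("drinking_0", 10), ("deprivation_0", 5), ("drinking_1", 10)]
        for rat in ("r1", "r2", "r3"):
            day = 0
            for ph, nd in schedule:
                for _ in range(nd):
                    for c in (5, 10, 20):
                        intake = 0.0 if ph.startswith("depriv") else 2.0
                        rows.append((rat, day, ph, c, intake))
                    day += 1
        table = pd.DataFrame(
            rows, columns=["rat", "day", "phase", "concentration", "intake"]
        )
        res = drinking_measures(table)
        per = res.per_rat[res.per_rat["concentration"] != "total"]
        assert np.allclose(per["BL"], 2.0)
        assert np.allclose(per["ADE"], 2.0)
        assert np.allclose(per["relapse"], 0.0)

    def test_null_phase_effect_not_significant(self):
        # equal BL and ADE means: the drinking-phase effect is null
        bl = {5: 1.0, 10: 1.2, 20: 1.1}
        table = simulate_drinking(n_rats=8, bl_means=bl, ade_means=bl, seed=9)
        res = drinking_measures(table)
        p = res.anova.set_index("effect").loc["drinking_phase", "Pr > F"]
        assert p > 0.05

    def test_configured_ade_increment_recovered(self):
        bl = {5: 1.02, 10: 1.25, 20: 1.16}
        ade = {5: 1.60, 10: 1.56, 20: 1.59}  # increment 1.32 total
        table = simulate_drinking(n_rats=10, bl_means=bl, ade_means=ade, seed=4)
        res = drinking_measures(table)
        tot = res.per_rat[res.per_rat["concentration"] == "total"]
        sem = tot["relapse"].std(ddof=1) / np.sqrt(len(tot))
        assert abs(tot["relapse"].mean() - 1.32) < 2 * sem + 0.1
        t_tot = res.relapse_tests.set_index("concentration").loc["total"]
        assert t_tot["p"] < 0.01

    def test_totals_are_sums_over_concentrations(self):
        table = simulate_drinking(n_rats=4, seed=5)
        res = drinking_measures(table)
        for rat, df_r in res.per_rat.groupby("rat"):
            parts = df_r[df_r["concentration"] != "total"]
            tot = df_r[df_r["concentration"] == "total"].iloc[0]
            for col in ("BL", "ADE", "relapse"):
                assert tot[col] == pytest.approx(parts[col].sum())

    def test_no_deprivation_rejected(self):
        table = pd.DataFrame(
            {"rat": ["r1"] * 3, "day": range(3), "phase": ["drinking_0"] * 3,
             "concentration": [5] * 3, "intake": [1.0] * 3}
        )
        with pytest.raises(ValueError, match="deprivation"):
            drinking_measures(table)
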