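"""Candidate-prioritization operations against hand and oracle computations."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats as sps

from radsense import synthio, transcriptome as tx
from radsense.datatypes import ExpressionMatrix
from radsense.stats import bh_adjust, logrank_two_group


def _em(values, groups=None, units="counts"):
    df = pd.DataFrame(values)
    df.index = [f"G{i}" for i in range(len(df))]
    df.columns = [f"S{i}" for i in range(df.shape[1])]
    return ExpressionMatrix(df, groups or {c: "all" for c in df.columns}, units=units)


class TestFilterLowExpression:
    def test_all_zero_gene_removed(self):
        em = _em([[0, 0], [5, 5]])
        out = tx.filter_low_expression(em)
        assert list(out.values.index) == ["G1"]

    def test_exactly_half_low_is_kept(self):
        """'More than 50%' is a strict cut: a gene low in exactly half stays."""
        # G0 has CPM >= 1 in exactly 1 of 2 samples (library sizes ~2e6)
        em = _em([[5, 0], [2_000_000, 2_000_000]])
        out = tx.filter_low_expression(em)
        assert "G0" in out.values.index

    def test_hand_cpm_arithmetic(self):
        # library sizes ~1e6; counts (0,0) removed as unexpressed,
        # (2,0): CPM<1 in >50%? low in 1 of 2 -> kept; (2,2): kept
        base = np.full((1, 2), 1_000_000 - 2)
        em = _em(np.vstack([[0, 0], [2, 0], [2, 2], base]))
        out = tx.filter_low_expression(em)
        assert list(out.values.index) == ["G1", "G2", "G3"]

    def test_gene_order_preserved(self, small_counts):
        em, _ = small_counts
        out = tx.filter_low_expression(em)
        kept = [g for g in em.values.index if g in set(out.values.index)]
        assert list(out.values.index) == kept


class TestNormalization:
    def test_cpm_columns_sum_to_million(self, small_counts):
        em, _ = small_counts
        c = tx.cpm(em)
        assert np.allclose(c.sum(axis=0), 1e6, rtol=1e-6)

    def test_constant_offset_removed(self):
        """A planted constant log2 offset between two samples vanishes."""
        rng = np.random.default_rng(1)
        base = rng.integers(50, 5000, 300).astype(float)
        counts = np.column_stack([base, base * 2.0]).astype(int)
        em = _em(counts)
        out = tx.normalize_log2cpm_cyclicloess(em)
        offset = (out.values["S0"] - out.values["S1"]).abs().mean()
        assert offset < 0.01

    def test_intensity_dependent_distortion_removed(self):
        """A smooth expression-dependent distortion (which per-sample scaling
        cannot fix) is flattened by the pairwise loess."""
        rng = np.random.default_rng(4)
        base = np.exp(rng.normal(6, 1.5, 400))
        z = (np.log2(base) - np.log2(base).mean()) / np.log2(base).std()
        distorted = base * 2 ** (0.5 * z)  # +/-0.5 log2 units across intensity
        counts = np.column_stack([base, distorted]).astype(int) + 1
        em = _em(counts)

        def residual_trend(matrix):
            x = matrix.values.to_numpy()
            fit = tx._pair_trend(0.5 * (x[:, 0] + x[:, 1]), x[:, 0] - x[:, 1], 0.7)
            return np.abs(fit).mean()

        before = residual_trend(tx.normalize_log2cpm_cyclicloess(em, iterations=0))
        after = residual_trend(tx.normalize_log2cpm_cyclicloess(em, iterations=3))
        assert before > 0.2
        assert after < 0.05

    def test_idempotent_after_removing_pure_offset(self):
        """A constant M-vs-A offset is a loess fixed point: removed exactly
        in one pass, and a second pass changes nothing."""
        rng = np.random.default_rng(2)
        a = rng.normal(8, 2, 300)
        m = np.full(300, 0.8)
        fit = tx._pair_trend(a, m, 0.7)
        assert np.allclose(fit, 0.8, atol=1e-9)
        refit = tx._pair_trend(a, m - fit, 0.7)
        assert np.abs(refit).max() < 1e-9

    def test_cycles_contract_the_pair_trend(self):
        """On noisy data each cycle shrinks the remaining M-vs-A trend."""
        rng = np.random.default_rng(3)
        counts = rng.integers(100, 10000, (300, 4))
        em = _em(counts)

        def trend_size(em_norm):
            x = em_norm.values.to_numpy()
            worst = 0.0
            for i in range(x.shape[1] - 1):
                for j in range(i + 1, x.shape[1]):
                    fit = tx._pair_trend(0.5 * (x[:, i] + x[:, j]), x[:, i] - x[:, j], 0.7)
                    worst = max(worst, np.abs(fit).max())
            return worst

        raw = trend_size(tx.normalize_log2cpm_cyclicloess(em, iterations=0))
        one = trend_size(tx.normalize_log2cpm_cyclicloess(em, iterations=1))
        three = trend_size(tx.normalize_log2cpm_cyclicloess(em, iterations=3))
        assert one < raw
        assert three < one

    def test_equal_counts_give_plain_log2cpm(self):
        counts = np.tile(np.arange(1, 101)[:, None] * 50, (1, 3))
        em = _em(counts)
        out = tx.normalize_log2cpm_cyclicloess(em)
        lib = counts.sum(axis=0)[0]
        expected = np.log2(counts[:, 0] / lib * 1e6 + 0.5)
        assert np.allclose(out.values.to_numpy()[:, 0], expected, atol=1e-8)

    def test_single_sample_rejected(self):
        em = _em(np.ones((20, 1), dtype=int))
        with pytest.raises(ValueError):
            tx.normalize_log2cpm_cyclicloess(em)


class TestDifferentialExpression:
    def test_identical_means_not_reported(self, log2cpm_pair):
        tumor, normal = log2cpm_pair
        normal = ExpressionMatrix(tumor.values.copy().rename(columns=dict(
            zip(tumor.values.columns, normal.values.columns))),
            dict(normal.sample_groups), units="log2cpm")
        out = tx.differential_expression(tumor, normal)
        assert len(out) == 0

    def test_f_equals_t_squared(self, log2cpm_pair):
        tumor, normal = log2cpm_pair
        out = tx.differential_expression(tumor, normal, return_all=True)
        for g in out.index[:10]:
            f_oracle = sps.f_oneway(
                tumor.values.loc[g], normal.values.loc[g]
            ).statistic
            assert out.loc[g, "F"] == pytest.approx(f_oracle, rel=1e-10)
            assert out.loc[g, "F"] == pytest.approx(out.loc[g, "t"] ** 2, rel=1e-12)

    def test_power_on_planted_shift(self):
        """log2fc=1 at n=20 vs 20, sd=0.5 is detected with power > 0.99."""
        rng = np.random.default_rng(3)
        detected = 0
        reps = 200
        for _ in range(reps):
            a = rng.normal(6.0, 0.5, 20)
            b = rng.normal(5.0, 0.5, 20)
            t, p = sps.ttest_ind(a, b, equal_var=True)
            detected += (p < 0.05) and (a.mean() - b.mean() > 0.3)
        assert detected / reps > 0.99

    def test_small_group_rejected(self, log2cpm_pair):
        tumor, _ = log2cpm_pair
        single = ExpressionMatrix(
            tumor.values.iloc[:, :1], {tumor.values.columns[0]: "tumor"}, units="log2cpm"
        )
        with pytest.raises(ValueError):
            tx.differential_expression(tumor, single)


class TestHighExpressionTest:
    def test_reference_t_and_p(self):
        """Values (0.5, 1.0, 1.5): t = 3.4641, one-sided p ~ 0.0371."""
        df = pd.DataFrame([[0.5, 1.0, 1.5]], index=["G0"],
                          columns=["m1", "m2", "m3"])
        em = ExpressionMatrix(df, {c: c for c in df.columns}, units="log2cpm")
        out = tx.high_expression_test(em, per_model_mean=False)
        assert out.loc["G0", "t_stat"] == pytest.approx(np.sqrt(12), rel=1e-4)
        assert out.loc["G0", "t_stat"] == pytest.approx(3.4641, abs=1e-4)
        assert out.loc["G0", "p_one_sided"] == pytest.approx(0.0371, abs=1e-3)

    def test_negative_means_give_large_p(self):
        df = pd.DataFrame([[-0.5, -1.0, -1.5]], index=["G0"],
                          columns=["m1", "m2", "m3"])
        em = ExpressionMatrix(df, {c: c for c in df.columns}, units="log2cpm")
        out = tx.high_expression_test(em, per_model_mean=False)
        assert out.loc["G0", "p_one_sided"] > 0.5

    def test_zero_variance_flagged(self):
        df = pd.DataFrame([[1.0, 1.0, 1.0], [-2.0, -2.0, -2.0]],
                          index=["G0", "G1"], columns=["m1", "m2", "m3"])
        em = ExpressionMatrix(df, {c: c for c in df.columns}, units="log2cpm")
        out = tx.high_expression_test(em, per_model_mean=False)
        assert out.loc["G0", "degenerate"] and out.loc["G0", "p_one_sided"] == 0.0
        assert out.loc["G1", "degenerate"] and out.loc["G1", "p_one_sided"] == 1.0

    def test_bh_hand_example(self):
        """BH step-up on (0.01, 0.02, 0.03, 0.04) gives q = 0.04 everywhere."""
        q = bh_adjust([0.01, 0.02, 0.03, 0.04])
        assert np.allclose(q, 0.04)

    def test_bh_invariants(self, rng):
        p = rng.uniform(size=50)
        q = bh_adjust(p)
        assert (q >= p - 1e-12).all()
        order = np.argsort(p)
        assert (np.diff(q[order]) >= -1e-12).all()


class TestRankCandidates:
    def _tables(self, n=300):
        genes = [f"G{i:03d}" for i in range(n)]
        deg = pd.DataFrame({"direction": ["up"] * n, "log2fc": 1.0, "p": 0.01},
                           index=genes)
        rng = np.random.default_rng(0)
        heg = pd.DataFrame({
            "mean_log2cpm": rng.normal(5, 1, n),
            "p_one_sided": rng.uniform(1e-8, 0.1, n),
        }, index=genes)
        heg["q_fdr"] = bh_adjust(heg["p_one_sided"])
        return deg, heg

    def test_gene_missing_from_heg_excluded(self):
        deg, heg = self._tables(10)
        ranked = tx.rank_candidates(deg, heg.drop(index="G003"), top_n=10)
        assert "G003" not in ranked

    def test_truncates_to_top_n(self):
        deg, heg = self._tables(300)
        assert len(tx.rank_candidates(deg, heg, top_n=200)) == 200

    def test_matches_brute_force_sort(self):
        deg, heg = self._tables(50)
        ranked = tx.rank_candidates(deg, heg, top_n=50)
        oracle = heg.assign(nlp=-np.log10(heg["p_one_sided"])).sort_values(
            "nlp", ascending=False
        ).index.tolist()
        assert ranked == oracle

    def test_down_regulated_excluded(self):
        deg, heg = self._tables(10)
        deg.loc["G000", "direction"] = "down"
        assert "G000" not in tx.rank_candidates(deg, heg, top_n=10)


class TestLogrankMedianSplit:
    def test_identical_survival_gives_null(self):
        surv = pd.DataFrame({
            "patient": [f"P{i}" for i in range(8)],
            "time_months": [5, 5, 9, 9, 5, 5, 9, 9],
            "event": [1] * 8,
        })
        expr = pd.Series([1, 1, 1, 1, 2, 2, 2, 2.0],
                         index=[f"P{i}" for i in range(8)])
        res = tx.logrank_median_split(expr, surv)
        assert res.statistic == pytest.approx(0.0, abs=1e-12)
        assert res.p == pytest.approx(1.0)

    def test_hand_computed_toy(self):
        """4 distinct event times, 2 per arm: O-E and V from the hypergeometric sums."""
        surv = pd.DataFrame({
            "patient": ["P1", "P2", "P3", "P4"],
            "time_months": [1.0, 2.0, 3.0, 4.0],
            "event": [1, 1, 1, 1],
        })
        expr = pd.Series([0.0, 0.0, 1.0, 1.0], index=["P1", "P2", "P3", "P4"])
        res = tx.logrank_median_split(expr, surv)
        # risk sets: t=1 n=4,nH=2,d=1(L); t=2 n=3,nH=2,d=1(L); t=3 n=2,nH=2,d=1(H); t=4 n=1,nH=1,d=1(H)
        # O_high = 2; E_high = 2/4 + 2/3 + 1 + 1 = 19/6
        # V = 1*(1/2)(1/2)(3/3) + 1*(2/3)(1/3)(2/2) + 0 + 0 = 1/4 + 2/9
        assert res.o_high == pytest.approx(2.0)
        assert res.e_high == pytest.approx(19 / 6, rel=1e-12)
        expected_v = 1 / 4 + 2 / 9
        expected_stat = (2 - 19 / 6) ** 2 / expected_v
        assert res.statistic == pytest.approx(expected_stat, rel=1e-12)
        assert not res.high_is_worse

    def test_agrees_with_lifelines(self):
        lifelines = pytest.importorskip("lifelines")
        rng = np.random.default_rng(4)
        time = rng.exponential(10, 40)
        event = rng.random(40) < 0.8
        group = rng.random(40) < 0.5
        res = logrank_two_group(time, event.astype(int), group)
        ll = lifelines.statistics.logrank_test(
            time[group], time[~group], event[group], event[~group]
        )
        assert res.statistic == pytest.approx(ll.test_statistic, rel=1e-8)
        assert res.p == pytest.approx(ll.p_value, rel=1e-8)

    def test_agrees_with_permutation_null(self):
        """Chi-square p within Monte-Carlo error of a 5000-shuffle permutation p."""
        rng = np.random.default_rng(5)
        n = 30
        time = rng.exponential(12, n)
        event = (rng.random(n) < 0.8).astype(int)
        group = np.zeros(n, bool)
        group[:15] = True
        obs = logrank_two_group(time, event, group)
        stats = np.empty(5000)
        for k in range(5000):
            stats[k] = logrank_two_group(time, event, rng.permutation(group)).statistic
        perm_p = (stats >= obs.statistic - 1e-12).mean()
        se = np.sqrt(perm_p * (1 - perm_p) / 5000)
        assert abs(obs.p - perm_p) < max(4 * se, 0.02)

    def test_no_events_flagged(self):
        surv = pd.DataFrame({
            "patient": [f"P{i}" for i in range(6)],
            "time_months": [1.0] * 6,
            "event": [0] * 6,
        })
        expr = pd.Series(np.arange(6.0), index=[f"P{i}" for i in range(6)])
        res = tx.logrank_median_split(expr, surv)
        assert res.p == 1.0 and res.degenerate


class TestSelectPrognostic:
    def test_planted_prognostic_gene_recovered(self):
        """HR=2.5, n=150, 30% censoring: recovered in >=95% of simulations."""
        hits = 0
        reps = 100
        for rep in range(reps):
            expr, risk = synthio.gen_patient_expression(
                150, ["G0", "G1"], prognostic_genes=["G0"], seed=rep
            )
            surv, _ = synthio.gen_survival(
                expression=expr, prognostic_genes=["G0"], hazard_ratio=2.5,
                censor_rate=0.3, seed=rep + 500, risk=risk,
            )
            out = tx.select_prognostic(["G0"], expr, surv)
            hits += bool(out.loc["G0", "selected"])
        assert hits >= 95

    def test_protective_gene_excluded_despite_significance(self):
        expr, risk = synthio.gen_patient_expression(
            120, ["G0"], prognostic_genes=["G0"], seed=1
        )
        surv, _ = synthio.gen_survival(
            expression=expr, prognostic_genes=["G0"], hazard_ratio=0.3,
            censor_rate=0.1, seed=2, risk=risk,
        )
        out = tx.select_prognostic(["G0"], expr, surv)
        assert out.loc["G0", "p"] < 0.05
        assert not out.loc["G0", "selected"]

    def test_alpha_one_keeps_all_harmful(self):
        expr, risk = synthio.gen_patient_expression(
            60, ["G0", "G1"], prognostic_genes=["G0", "G1"], seed=3
        )
        surv, _ = synthio.gen_survival(
            expression=expr, prognostic_genes=["G0", "G1"], hazard_ratio=3.0,
            censor_rate=0.0, seed=4, risk=risk,
        )
        out = tx.select_prognostic(["G0", "G1"], expr, surv, alpha=1.0)
        assert out["selected"].all()


class TestORA:
    def test_hand_combinatorial_example(self):
        """2 candidates, set of exactly those 2, universe 10: p = 1/C(10,2)."""
        universe = [f"G{i}" for i in range(10)]
        out = tx.ora_gene_sets(["G0", "G1"], {"S": ["G0", "G1"]}, universe)
        assert out.loc["S", "p_hyper"] == pytest.approx(1 / 45, rel=1e-10)

    def test_candidates_equal_universe(self):
        universe = [f"G{i}" for i in range(8)]
        out = tx.ora_gene_sets(universe, {"S": universe[:4]}, universe)
        assert out.loc["S", "p_hyper"] == pytest.approx(1.0)

    def test_zero_overlap_gives_p_one(self):
        universe = [f"G{i}" for i in range(10)]
        out = tx.ora_gene_sets(["G0"], {"S": ["G5", "G6"]}, universe)
        assert out.loc["S", "p_hyper"] == pytest.approx(1.0)

    def test_candidates_outside_universe_rejected(self):
        with pytest.raises(ValueError):
            tx.ora_gene_sets(["X"], {"S": ["G0"]}, ["G0", "G1"])


class TestClusterSamples:
    def _em_from(self, arr):
        df = pd.DataFrame(arr, columns=[f"S{i}" for i in range(arr.shape[1])])
        df.index = [f"G{i}" for i in range(len(df))]
        return ExpressionMatrix(df, {c: "x" for c in df.columns}, units="log2cpm")

    def test_duplicated_samples_merge_first_at_zero(self, rng):
        base = rng.normal(5, 1, 30)
        arr = np.column_stack([base, base, rng.normal(5, 1, 30)])
        z, leaves, heights = tx.cluster_samples(self._em_from(arr))
        assert heights[0] == pytest.approx(0.0, abs=1e-9)
        first = {int(z[0, 0]), int(z[0, 1])}
        assert first == {0, 1}

    def test_three_sample_merge_order_matches_brute_force(self, rng):
        arr = rng.normal(0, 1, (40, 3))
        em = self._em_from(arr)
        z, leaves, _ = tx.cluster_samples(em)
        d = 1 - pd.DataFrame(arr).corr().to_numpy()
        pair = np.unravel_index(np.argmin(d + np.eye(3) * 9), d.shape)
        assert {int(z[0, 0]), int(z[0, 1])} == set(pair)

    def test_heights_non_decreasing(self, rng):
        arr = rng.normal(0, 1, (50, 8))
        _, _, heights = tx.cluster_samples(self._em_from(arr))
        assert (np.diff(heights) >= -1e-12).all()

    def test_zero_variance_sample_rejected(self):
        arr = np.column_stack([np.ones(20), np.arange(20.0), np.arange(20.0) ** 2])
        with pytest.raises(ValueError):
            tx.cluster_samples(self._em_from(arr))
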