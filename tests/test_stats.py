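import itertools
from math import comb

import numpy as np
import pandas as pd
import pytest

from tnbcstrat.stats import (
    alteration_tests,
    fisher_exact_rx2,
    group_anova_fdr,
    hrd_compare,
    posthoc_pairwise_t,
    signature_scores,
)


def make_scores(rng, n_signatures=5, groups=("LAR", "LP", "LI", "LD"), per_group=10):
    samples = []
    labels = []
    for g in groups:
        for i in range(per_group):
            samples.append(f"{g}{i}")
            labels.append(g)
    scores = pd.DataFrame(
        rng.normal(size=(n_signatures, len(samples))),
        index=[f"sig{k}" for k in range(n_signatures)],
        columns=samples,
    )
    return scores, pd.Series(labels, index=samples)


class TestSignatureScores:
    def test_mean_z_all_genes_zero_on_average(self, rng):
        # per-gene z-scores sum to zero across samples, so the all-genes
        # score averages to zero over the cohort (not per sample)
        expr = pd.DataFrame(
            rng.normal(size=(20, 6)),
            index=[f"g{i}" for i in range(20)],
            columns=[f"s{j}" for j in range(6)],
        )
        scores = signature_scores(expr, {"all": list(expr.index)}, method="mean_z")
        assert scores.loc["all"].sum() == pytest.approx(0.0, abs=1e-10)

    def test_mean_z_hand_computed(self):
        expr = pd.DataFrame(
            {
                "s1": [1.0, 2.0, 3.0, 4.0, 5.0],
                "s2": [5.0, 4.0, 3.0, 2.0, 1.0],
            },
            index=[f"g{i}" for i in range(5)],
        )
        # per-gene z over two samples is +-1 (or 0 for g2); set {g0, g1}
        scores = signature_scores(expr, {"set": ["g0", "g1"]}, method="mean_z")
        assert scores.loc["set", "s1"] == pytest.approx(-1.0)
        assert scores.loc["set", "s2"] == pytest.approx(1.0)

    def test_ssgsea_ranks_top_genes_higher(self, rng):
        expr = pd.DataFrame(
            rng.normal(size=(50, 1)),
            index=[f"g{i}" for i in range(50)],
            columns=["s"],
        )
        top = expr["s"].nlargest(5).index.tolist()
        bottom = expr["s"].nsmallest(5).index.tolist()
        scores = signature_scores(expr, {"top": top, "bottom": bottom})
        assert scores.loc["top", "s"] > scores.loc["bottom", "s"]

    def test_ssgsea_rank_invariance(self, rng):
        expr = pd.DataFrame(
            rng.normal(size=(30, 4)),
            index=[f"g{i}" for i in range(30)],
            columns=list("abcd"),
        )
        genesets = {"set": [f"g{i}" for i in range(0, 10)]}
        base = signature_scores(expr, genesets)
        monotone = signature_scores(np.exp(expr), genesets)
        pd.testing.assert_frame_equal(base, monotone)

    def test_empty_overlap_is_na(self, rng):
        expr = pd.DataFrame(
            rng.normal(size=(10, 3)), index=[f"g{i}" for i in range(10)]
        )
        scores = signature_scores(expr, {"none": ["zz"], "ok": ["g1", "g2"]})
        assert scores.loc["none"].isna().all()
        assert scores.loc["ok"].notna().all()

    def test_unknown_method(self, rng):
        expr = pd.DataFrame(rng.normal(size=(10, 3)), index=[f"g{i}" for i in range(10)])
        with pytest.raises(ValueError):
            signature_scores(expr, {"s": ["g1"]}, method="gsva")


class TestGroupAnovaFdr:
    def test_shifted_signature_detected(self, rng):
        scores, groups = make_scores(rng, n_signatures=8, per_group=30)
        scores.loc["sig0", groups == "LD"] += 3.0
        result = group_anova_fdr(scores, groups)
        assert result.loc["sig0", "p_adjusted"] < 0.05

    def test_null_rejection_rate_near_alpha(self):
        rng = np.random.default_rng(5)
        scores, groups = make_scores(rng, n_signatures=400, per_group=25)
        result = group_anova_fdr(scores, groups)
        # raw p uniform under the null; BH keeps FDR <= alpha
        raw_rate = (result["p_raw"] < 0.05).mean()
        assert 0.02 <= raw_rate <= 0.08
        assert (result["p_adjusted"] < 0.05).mean() <= 0.02

    def test_single_signature_bh_identity(self, rng):
        scores, groups = make_scores(rng, n_signatures=1)
        result = group_anova_fdr(scores, groups)
        assert result["p_adjusted"].iloc[0] == pytest.approx(result["p_raw"].iloc[0])

    def test_constant_scores_na(self, rng):
        scores, groups = make_scores(rng, n_signatures=2)
        scores.loc["sig0"] = 1.0
        result = group_anova_fdr(scores, groups)
        assert np.isnan(result.loc["sig0", "p_raw"])

    def test_bh_monotonicity(self, rng):
        scores, groups = make_scores(rng, n_signatures=50)
        result = group_anova_fdr(scores, groups).dropna()
        assert (result["p_adjusted"] >= result["p_raw"] - 1e-12).all()
        ordered = result.sort_values("p_raw")
        assert (np.diff(ordered["p_adjusted"]) >= -1e-12).all()

    def test_too_few_groups_rejected(self, rng):
        scores, _ = make_scores(rng)
        with pytest.raises(ValueError):
            group_anova_fdr(scores, pd.Series("LAR", index=scores.columns))


class TestPosthocPairwiseT:
    def test_all_six_pairs(self, rng):
        scores, groups = make_scores(rng, n_signatures=2)
        result = posthoc_pairwise_t(scores, groups)
        assert len(result) == 2 * 6

    def test_label_swap_symmetry(self, rng):
        scores, groups = make_scores(rng, n_signatures=1)
        result = posthoc_pairwise_t(scores, groups)
        swapped = groups.map(
            {"LAR": "LP", "LP": "LAR", "LI": "LD", "LD": "LI"}
        )
        result_sw = posthoc_pairwise_t(scores, swapped)
        pairs = lambda df: {
            frozenset((r.group_a, r.group_b)): r.p for r in df.itertuples()
        }
        orig = pairs(result)
        for pair, p in pairs(result_sw).items():
            mapped = frozenset(
                {"LAR": "LP", "LP": "LAR", "LI": "LD", "LD": "LI"}[x] for x in pair
            )
            assert p == pytest.approx(orig[mapped])

    def test_hand_three_vs_three(self):
        xa = np.array([1.0, 2.0, 3.0])
        xb = np.array([2.0, 4.0, 6.0])
        scores = pd.DataFrame(
            [np.concatenate([xa, xb])],
            index=["sig"],
            columns=list("abcdef"),
        )
        groups = pd.Series(["g1"] * 3 + ["g2"] * 3, index=scores.columns)
        result = posthoc_pairwise_t(scores, groups)
        # pooled-variance t statistic by hand
        sp2 = (xa.var(ddof=1) + xb.var(ddof=1)) / 2
        tstat = (xa.mean() - xb.mean()) / np.sqrt(sp2 * (2 / 3))
        from scipy import stats as ss

        expected_p = 2 * ss.t.sf(abs(tstat), df=4)
        assert result["p"].iloc[0] == pytest.approx(expected_p)

    def test_small_group_skipped(self, rng, caplog):
        scores, groups = make_scores(rng, n_signatures=1, per_group=5)
        groups.iloc[:4] = "tiny"
        groups.iloc[4] = "LAR"
        result = posthoc_pairwise_t(scores, groups)
        assert not any(
            {"LAR"} <= {r.group_a, r.group_b} for r in result.itertuples()
        )


class TestFisherExact:
    def test_balanced_equal_frequencies_p_one(self):
        # 2/4 vs 2/4: every table is at least as extreme
        assert fisher_exact_rx2([2, 2], [4, 4]) == pytest.approx(1.0)

    def test_hand_hypergeometric_tail(self):
        # 5/5 vs 0/15: only the observed table has probability <= observed;
        # P = C(5,5) C(15,0) / C(20,5) = 1/15504
        p = fisher_exact_rx2([5, 0], [5, 15])
        assert p == pytest.approx(1 / comb(20, 5))

    def test_matches_scipy_two_by_two(self, rng):
        from scipy.stats import fisher_exact

        for _ in range(20):
            totals = rng.integers(3, 15, 2)
            altered = np.array([rng.integers(0, t + 1) for t in totals])
            table = [
                [altered[0], totals[0] - altered[0]],
                [altered[1], totals[1] - altered[1]],
            ]
            _, expected = fisher_exact(table)
            assert fisher_exact_rx2(altered, totals) == pytest.approx(expected)

    def test_four_group_matches_exhaustive_oracle(self):
        # independent brute-force enumeration with plain combinatorics
        altered = np.array([3, 0, 1, 2])
        totals = np.array([4, 4, 4, 4])
        c1 = altered.sum()
        n = totals.sum()

        def prob(cells):
            num = 1
            for t, a in zip(totals, cells):
                num *= comb(t, a)
            return num / comb(n, c1)

        p_obs = prob(altered)
        p_total = 0.0
        for cells in itertools.product(*(range(t + 1) for t in totals)):
            if sum(cells) == c1 and prob(cells) <= p_obs + 1e-12:
                p_total += prob(cells)
        assert fisher_exact_rx2(altered, totals) == pytest.approx(p_total)

    def test_monte_carlo_agrees_with_exact(self):
        altered = np.array([8, 2, 4, 6])
        totals = np.array([20, 20, 20, 20])
        exact = fisher_exact_rx2(altered, totals)
        mc = fisher_exact_rx2(altered, totals, max_tables=1, mc_draws=200_000, seed=1)
        assert mc == pytest.approx(exact, abs=0.01)

    def test_invariant_bounds(self, rng):
        for _ in range(20):
            totals = rng.integers(2, 10, 3)
            altered = np.array([rng.integers(0, t + 1) for t in totals])
            p = fisher_exact_rx2(altered, totals)
            assert 0.0 <= p <= 1.0

    def test_invalid_counts_rejected(self):
        with pytest.raises(ValueError):
            fisher_exact_rx2([5], [4])


class TestAlterationTests:
    def make_alterations(self, rng, groups, freqs):
        samples = groups.index.tolist()
        data = {}
        for event, by_group in freqs.items():
            probs = groups.map(by_group).to_numpy(dtype=float)
            data[event] = (rng.random(len(samples)) < probs).astype(int)
        return pd.DataFrame(data, index=samples).T

    def test_differential_event_detected(self, rng):
        groups = pd.Series(
            np.repeat(["LAR", "LP", "LI", "LD"], 40),
            index=[f"s{i}" for i in range(160)],
        )
        alts = self.make_alterations(
            rng,
            groups,
            {
                "PIK3CA:mutation": {"LAR": 0.7, "LP": 0.1, "LI": 0.1, "LD": 0.1},
                "TP53:mutation": {"LAR": 0.5, "LP": 0.5, "LI": 0.5, "LD": 0.5},
            },
        )
        result = alteration_tests(alts, groups)
        assert result.loc["PIK3CA:mutation", "p_adjusted"] < 0.05
        assert result.loc["PIK3CA:mutation", "freq_LAR"] > 0.4

    def test_all_zero_matrix_empty_result(self, rng):
        groups = pd.Series(["LAR", "LP"] * 5, index=[f"s{i}" for i in range(10)])
        alts = pd.DataFrame(
            np.zeros((3, 10), dtype=int),
            index=["a:mutation", "b:deletion", "c:amplification"],
            columns=groups.index,
        )
        result = alteration_tests(alts, groups)
        assert len(result) == 0

    def test_sample_order_invariance(self, rng):
        groups = pd.Series(
            np.repeat(["LAR", "LP"], 15), index=[f"s{i}" for i in range(30)]
        )
        alts = self.make_alterations(
            rng, groups, {"g:mutation": {"LAR": 0.8, "LP": 0.2}}
        )
        perm = rng.permutation(30)
        result = alteration_tests(alts, groups)
        result_perm = alteration_tests(
            alts.iloc[:, perm], groups.iloc[perm]
        )
        assert result.loc["g:mutation", "p_raw"] == pytest.approx(
            result_perm.loc["g:mutation", "p_raw"]
        )


class TestHrdCompare:
    def test_shifted_group_detected(self, rng):
        groups = pd.Series(
            np.repeat(["LAR", "LP", "LI", "LD"], 30),
            index=[f"s{i}" for i in range(120)],
        )
        scores = pd.Series(rng.normal(size=120), index=groups.index)
        scores[groups == "LD"] += 2.0
        kw_stat, kw_p, pairwise = hrd_compare(scores, groups)
        assert kw_p < 0.05
        row = pairwise[
            (pairwise[["group_a", "group_b"]].isin(["LD", "LAR"]).all(axis=1))
        ]
        assert row["p_adjusted"].item() < 0.05

    def test_null_rejection_rate(self):
        rng = np.random.default_rng(9)
        rejections = 0
        reps = 200
        for _ in range(reps):
            groups = pd.Series(
                np.repeat(["LAR", "LP", "LI", "LD"], 50),
                index=range(200),
            )
            scores = pd.Series(rng.normal(size=200), index=groups.index)
            _, kw_p, _ = hrd_compare(scores, groups)
            rejections += kw_p < 0.05
        assert 0.02 <= rejections / reps <= 0.09

    def test_two_groups_kw_close_to_ranksum(self, rng):
        groups = pd.Series(np.repeat(["a", "b"], 150), index=range(300))
        scores = pd.Series(rng.normal(size=300), index=groups.index)
        scores[groups == "b"] += 0.3
        _, kw_p, pairwise = hrd_compare(scores, groups)
        assert kw_p == pytest.approx(pairwise["p_raw"].iloc[0], rel=0.05)

    def test_all_tied_na(self):
        groups = pd.Series(["a", "a", "b", "b"], index=range(4))
        scores = pd.Series([1.0, 1.0, 1.0, 1.0], index=groups.index)
        kw_stat, kw_p, _ = hrd_compare(scores, groups)
        assert np.isnan(kw_p)

    def test_paired_requires_equal_sizes(self, rng):
        groups = pd.Series(["a"] * 4 + ["b"] * 6, index=range(10))
        scores = pd.Series(rng.normal(size=10), index=groups.index)
        with pytest.raises(ValueError, match="equal-size"):
            hrd_compare(scores, groups, paired=True)
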