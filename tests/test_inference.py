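"""Age aggregation, pattern summaries, shift/group tests, process matrix."""

import itertools

import numpy as np
import pandas as pd
import pytest
from scipy import stats

import phylocomm as pc


class TestAggregateByAge:
    def test_identical_plots_collapse(self):
        cover = pd.DataFrame({"s1": [2.0, 2.0], "s2": [6.0, 6.0]}, index=["p1", "p2"])
        comm = pc.CommunityTable(cover=cover, ages=pd.Series({"p1": 4.0, "p2": 4.0}))
        agg = pc.aggregate_by_age(comm)
        assert len(agg.plots) == 1
        np.testing.assert_allclose(agg.relative().iloc[0], [0.25, 0.75])

    def test_disjoint_species_sum_richness(self):
        cover = pd.DataFrame({"s1": [2.0, 0.0], "s2": [0.0, 6.0]}, index=["p1", "p2"])
        comm = pc.CommunityTable(cover=cover, ages=pd.Series({"p1": 14.0, "p2": 14.0}))
        agg = pc.aggregate_by_age(comm)
        assert int((agg.cover.iloc[0] > 0).sum()) == 2

    def test_aggregate_cwm_is_cover_weighted_mean_of_plot_cwms(self):
        rng = np.random.default_rng(1)
        species = [f"s{i}" for i in range(10)]
        cover = pd.DataFrame(rng.lognormal(0, 1, (4, 10)), columns=species,
                             index=[f"p{i}" for i in range(4)])
        comm = pc.CommunityTable(cover=cover, ages=pd.Series(55.0, index=cover.index))
        x = rng.normal(size=10)
        agg = pc.aggregate_by_age(comm)
        w_agg = agg.relative().iloc[0].to_numpy()
        cwm_agg = pc.cwm(x, w_agg)
        totals = cover.sum(axis=1)
        plot_cwms = [pc.cwm(x, pc.relative_abundance(cover.loc[p])) for p in cover.index]
        expected = float(np.average(plot_cwms, weights=totals))
        assert cwm_agg == pytest.approx(expected, abs=1e-10)


class TestPatternSummary:
    def _mk(self, patterns, metric="MPD", age=27.0):
        return pd.DataFrame(
            {"plot": [f"p{i}" for i in range(len(patterns))],
             "age": age, "metric": metric,
             "ses": np.where(np.asarray(patterns) == "clustering", -2.0, 0.0),
             "pattern": patterns}
        )

    def test_quarter_split(self):
        out = pc.pattern_summary(self._mk(["clustering", "random", "random", "random"]))
        row = out.iloc[0]
        assert (row["clustering"], row["random"], row["overdispersion"]) == (25.0, 75.0, 0.0)

    def test_all_random(self):
        out = pc.pattern_summary(self._mk(["random"] * 5, age=4.0))
        row = out.iloc[0]
        assert (row["clustering"], row["random"], row["overdispersion"]) == (0.0, 100.0, 0.0)

    def test_undefined_excluded_and_percentages_sum(self):
        df = pd.concat([
            self._mk(["clustering", "undefined", "divergence", "random"], metric="CWV.LA"),
        ])
        df.loc[df["pattern"] == "divergence", "ses"] = 2.0
        out = pc.pattern_summary(df)
        row = out.iloc[0]
        assert row["n"] == 3
        assert row["clustering"] + row["random"] + row["overdispersion"] == pytest.approx(100.0)


class TestShiftChisq:
    def test_perfect_separation(self):
        chi2, df, p, _ = pc.shift_chisq(["clustering"] * 10, ["random"] * 10)
        assert chi2 == pytest.approx(20.0)
        assert df == 1
        assert p < 0.001

    def test_independence_gives_zero(self):
        pats = ["clustering"] * 5 + ["random"] * 5
        chi2, _, p, _ = pc.shift_chisq(pats, pats)
        assert chi2 == pytest.approx(0.0)
        assert p == pytest.approx(1.0)

    @pytest.mark.parametrize("seed", range(5))
    def test_matches_textbook_formula(self, seed):
        rng = np.random.default_rng(seed)
        counts = rng.integers(1, 20, size=(2, 3))
        pats = ["clustering", "random", "overdispersion"]
        early = [p for p, c in zip(pats, counts[0]) for _ in range(c)]
        late = [p for p, c in zip(pats, counts[1]) for _ in range(c)]
        chi2, df, _, table = pc.shift_chisq(early, late)
        O = table.to_numpy().astype(float)
        E = np.outer(O.sum(1), O.sum(0)) / O.sum()
        assert chi2 == pytest.approx(((O - E) ** 2 / E).sum(), abs=1e-10)
        assert df == 2

    def test_degenerate_column_dropped(self):
        # overdispersion absent from both groups: chi-squared on the 2×2 table
        chi2, df, _, table = pc.shift_chisq(
            ["clustering", "random", "random"], ["clustering", "clustering", "random"])
        assert df == 1
        assert list(table.columns) == ["clustering", "random"]

    def test_single_category_rejected(self):
        with pytest.raises(ValueError):
            pc.shift_chisq(["random"] * 3, ["random"] * 3)


class TestRankGroupTest:
    def test_maximal_separation_h(self):
        # groups (1,2,3) vs (4,5,6): H = 12/(6·7)·(6²/3+15²/3) − 3·7 = 27/7
        h, p = pc.rank_group_test({"a": [1, 2, 3], "b": [4, 5, 6]})
        assert h == pytest.approx(27 / 7)
        # exhaustive enumeration: no rank split of 3/3 exceeds this H
        from itertools import combinations
        best = 0.0
        for combo in combinations(range(1, 7), 3):
            r1 = sum(combo)
            r2 = 21 - r1
            best = max(best, 12 / (6 * 7) * (r1**2 / 3 + r2**2 / 3) - 3 * 7)
        assert h == pytest.approx(best)

    def test_identical_groups_zero(self):
        h, p = pc.rank_group_test({"a": [2.0, 2.0], "b": [2.0, 2.0]})
        assert h == 0.0 and p == 1.0

    def test_matches_scipy_on_random_data(self):
        rng = np.random.default_rng(2)
        groups = {k: rng.normal(size=8) for k in "abc"}
        h, p = pc.rank_group_test(groups)
        h2, p2 = stats.kruskal(*groups.values())
        assert (h, p) == (pytest.approx(h2), pytest.approx(p2))

    def test_label_permutation_p_roughly_uniform(self):
        rng = np.random.default_rng(3)
        pooled = rng.normal(size=18)
        pvals = []
        for _ in range(300):
            perm = rng.permutation(pooled)
            _, p = pc.rank_group_test({"a": perm[:6], "b": perm[6:12], "c": perm[12:]})
            pvals.append(p)
        assert 0.01 <= np.mean(np.asarray(pvals) < 0.05) <= 0.10


class TestDunnPosthoc:
    def test_zero_difference(self):
        out = pc.dunn_posthoc({"a": [1, 2, 3, 4], "b": [4, 3, 2, 1]})
        assert out["z"].iloc[0] == pytest.approx(0.0)
        assert out["p"].iloc[0] == pytest.approx(1.0)

    def test_hand_computed_z_without_ties(self):
        groups = {"a": [1.0, 2.0], "b": [3.0, 4.0]}
        out = pc.dunn_posthoc(groups)
        # mean ranks 1.5 vs 3.5; var = N(N+1)/12 = 5/3; se = sqrt(5/3 · 1) ...
        se = np.sqrt(4 * 5 / 12 * (0.5 + 0.5))
        assert abs(out["z"].iloc[0]) == pytest.approx(2.0 / se)

    def test_bonferroni_monotone(self):
        rng = np.random.default_rng(4)
        groups = {k: rng.normal(loc=i, size=6) for i, k in enumerate("abcd")}
        raw = pc.dunn_posthoc(groups)
        bonf = pc.dunn_posthoc(groups, adjust="bonferroni")
        assert np.all(bonf["p_adjusted"].to_numpy() >= raw["p"].to_numpy() - 1e-12)
        bh = pc.dunn_posthoc(groups, adjust="bh")
        assert np.all(bh["p_adjusted"].to_numpy() <= bonf["p_adjusted"].to_numpy() + 1e-12)


class TestInterpretProcess:
    @pytest.mark.parametrize(
        "conservatism,phylo,func,disp,expected",
        [
            # conserved traits: aligned low patterns → filtering; high → exclusion
            ("conserved", "clustering", "clustering", "convergence", "environmental filtering"),
            ("conserved", "overdispersion", "overdispersion", "divergence", "competitive exclusion"),
            # convergent traits flip the phylogenetic reading
            ("convergent", "clustering", "random", "random", "competitive exclusion"),
            ("convergent", "random", "clustering", "random", "environmental filtering"),
            ("convergent", "random", "random", "convergence", "environmental filtering"),
            ("convergent", "random", "overdispersion", "divergence", "competitive exclusion"),
            # no signal anywhere → stochastic
            ("conserved", "random", "random", "random", "stochastic"),
            ("convergent", "random", "random", "random", "stochastic"),
        ],
    )
    def test_decision_matrix(self, conservatism, phylo, func, disp, expected):
        call = pc.interpret_process(conservatism, phylo, func, disp)
        assert call.process == expected

    def test_conflicting_evidence_is_ambiguous(self):
        call = pc.interpret_process("conserved", "clustering", "overdispersion", "random")
        assert call.process == "ambiguous"
        assert len(call.conflicts) == 2

    def test_total_over_all_inputs(self):
        phylo_opts = func_opts = ["clustering", "random", "overdispersion", "undefined"]
        disp_opts = ["convergence", "random", "divergence", "undefined"]
        valid = {"environmental filtering", "competitive exclusion", "stochastic", "ambiguous"}
        for cons, ph, fu, di in itertools.product(
            ("conserved", "convergent"), phylo_opts, func_opts, disp_opts
        ):
            assert pc.interpret_process(cons, ph, fu, di).process in valid

    def test_combine_dispersion(self):
        assert pc.combine_dispersion(["convergence", "random"]) == "convergence"
        assert pc.combine_dispersion(["divergence"] * 3) == "divergence"
        assert pc.combine_dispersion(["convergence", "divergence"]) == "random"
        assert pc.combine_dispersion(["random", "undefined"]) == "random"

    def test_classify_conservatism(self):
        bm_like = pd.DataFrame({"trait": list("abc"), "K": [1.0, 0.9, 1.1],
                                "p": [0.001, 0.002, 0.001]})
        conv_like = pd.DataFrame({"trait": list("abc"), "K": [0.18, 0.22, 0.08],
                                  "p": [0.02, 0.001, 0.4]})
        assert pc.classify_conservatism(bm_like) == "conserved"
        assert pc.classify_conservatism(conv_like) == "convergent"
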