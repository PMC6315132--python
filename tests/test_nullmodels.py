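"""Randomization null models, SES, quantile ranks, and pattern labels."""

import itertools

import numpy as np
import pandas as pd
import pytest

import phylocomm as pc
from conftest import random_community


class TestQuantileRank:
    def test_observed_below_all(self):
        assert pc.quantile_rank(-5.0, np.arange(999.0)) == pytest.approx(1 / 1000)

    def test_observed_above_all(self):
        assert pc.quantile_rank(1e9, np.arange(999.0)) == pytest.approx(1000 / 1000)

    def test_all_tied_splits_to_half(self):
        assert pc.quantile_rank(3.0, np.full(999, 3.0)) == pytest.approx(0.5005)

    def test_strictly_inside_unit_interval(self):
        rng = np.random.default_rng(0)
        null = rng.normal(size=99)
        for obs in (-10, 0.0, 10, null[3]):
            r = pc.quantile_rank(obs, null)
            assert 0.0 < r < 1.0 or r == pytest.approx(1.0)


class TestSES:
    def test_hand_value(self):
        # observed 5, null mean 3, null sd 1 → SES = 2
        null = np.array([2.0, 3.0, 4.0])
        s, mean, sd = pc.ses(5.0, null)
        assert (s, mean, sd) == (pytest.approx(2.0), pytest.approx(3.0), pytest.approx(1.0))

    def test_observed_at_mean_is_zero(self):
        null = np.array([1.0, 2.0, 3.0])
        assert pc.ses(2.0, null)[0] == pytest.approx(0.0)

    def test_zero_spread_undefined(self):
        s, _, sd = pc.ses(1.0, np.full(200, 1.0))
        assert np.isnan(s) and sd == 0.0

    def test_own_mean_has_small_ses(self):
        rng = np.random.default_rng(1)
        null = rng.standard_normal(999)
        s, _, _ = pc.ses(float(null.mean()), null)
        assert abs(s) < 3 / np.sqrt(999) * 5


class TestClassifyPattern:
    @pytest.mark.parametrize(
        "ses_value,rank,metric,expected",
        [
            (-2.1, 0.01, "MPD", "clustering"),
            (1.9, 0.97, "MPD", "overdispersion"),
            (-0.3, 0.40, "MPD", "random"),
            (-2.1, 0.01, "CWV.LA", "convergence"),
            (1.9, 0.97, "CWV.LA", "divergence"),
            (-2.1, 0.20, "MFD", "random"),   # low SES but interior rank
            (0.5, 0.01, "MFD", "random"),    # tail rank but disagreeing sign
            (float("nan"), 0.5, "MPD", "undefined"),
        ],
    )
    def test_threshold_rule(self, ses_value, rank, metric, expected):
        assert pc.classify_pattern(ses_value, rank, metric) == expected


class TestTaxaShuffle:
    def test_fixed_seed_bit_identical(self, small_dataset):
        tree, _, community = small_dataset
        d = tree.cophenetic_distances()
        e1 = pc.null_taxa_shuffle(d, community, runs=99, seed=77)
        e2 = pc.null_taxa_shuffle(d, community, runs=99, seed=77)
        for a, b in zip(e1, e2):
            np.testing.assert_array_equal(a.values, b.values)

    def test_equal_distances_degenerate(self, small_dataset):
        _, _, community = small_dataset
        n = len(community.species)
        d = np.full((n, n), 3.0)
        np.fill_diagonal(d, 0.0)
        dm = pc.DistanceMatrix(labels=tuple(community.species), values=d, kind="phylogenetic")
        for ens in pc.null_taxa_shuffle(dm, community, runs=99, seed=1):
            np.testing.assert_allclose(ens.values, ens.observed)
            rec = pc.make_record(ens.plot, ens.metric, ens.observed, ens.values)
            assert rec.pattern == "undefined"

    def test_complete_pool_equal_weights_is_noop(self, yule_tree):
        # label shuffling permutes the full submatrix; with equal weights the
        # weighted MPD is invariant
        rng = np.random.default_rng(2)
        comm = random_community(yule_tree.tip_labels, 1, yule_tree.n_tips, rng,
                                equal_weights=True)
        d = yule_tree.cophenetic_distances()
        (ens,) = pc.null_taxa_shuffle(d, comm, runs=99, seed=3)
        np.testing.assert_allclose(ens.values, ens.observed, rtol=1e-12)

    def test_tiny_pool_rejected(self, yule_tree):
        d = yule_tree.cophenetic_distances()
        comm = random_community(yule_tree.tip_labels, 1, 3, np.random.default_rng(0))
        with pytest.raises(ValueError):
            pc.null_taxa_shuffle(d, comm, runs=99, seed=1, pool=[comm.species[0]])

    def test_null_matches_metric_recomputation(self, small_dataset):
        # one run of the ensemble equals weighted_mpd on the relabelled matrix
        tree, _, community = small_dataset
        d = tree.cophenetic_distances()
        ens = pc.null_taxa_shuffle(d, community, runs=99, seed=5)
        # reproduce the internal permutation stream
        rng = np.random.default_rng(5)
        P = len(community.species)
        perms = rng.permuted(np.tile(np.arange(P), (99, 1)), axis=1)
        rel = community.relative()
        pool = list(community.species)
        D = d.submatrix(pool)
        for e in ens:
            w_full = rel.loc[e.plot].to_numpy()
            present = np.flatnonzero(w_full > 0)
            w = w_full[present] / w_full[present].sum()
            for r in (0, 42, 98):
                sub = perms[r][present]
                expected = pc.weighted_mpd(D[np.ix_(sub, sub)], w)
                assert e.values[r] == pytest.approx(expected, abs=1e-10)


class TestAbundanceShuffle:
    def test_two_species_plot_two_values(self, yule_tree):
        labels = list(yule_tree.tip_labels)
        cover = pd.DataFrame(0.0, index=["p1"], columns=labels)
        cover.loc["p1", labels[0]] = 1.0
        cover.loc["p1", labels[1]] = 3.0
        comm = pc.CommunityTable(cover=cover, ages=pd.Series({"p1": 4.0}))
        traits = pd.DataFrame({"x": np.arange(len(labels), dtype=float)}, index=labels)
        ens = pc.null_abundance_shuffle(comm, traits, runs=200, seed=4)
        assert len(np.unique(np.round(ens[0].values, 12))) <= 2

    def test_equal_abundances_zero_spread_flagged(self, yule_tree):
        rng = np.random.default_rng(5)
        comm = random_community(yule_tree.tip_labels, 1, 6, rng, equal_weights=True)
        traits = pd.DataFrame({"x": rng.normal(size=yule_tree.n_tips)},
                              index=list(yule_tree.tip_labels))
        (ens,) = pc.null_abundance_shuffle(comm, traits, runs=99, seed=6)
        rec = pc.make_record(ens.plot, ens.metric, ens.observed, ens.values)
        assert rec.pattern == "undefined"

    def test_matches_exhaustive_enumeration(self, yule_tree):
        # 5-species plot: sampled ensemble statistics match all 120 permutations
        labels = list(yule_tree.tip_labels)[:5]
        rng = np.random.default_rng(7)
        cover = pd.DataFrame(0.0, index=["p1"], columns=list(yule_tree.tip_labels))
        w_raw = rng.lognormal(0, 1, 5)
        cover.loc["p1", labels] = w_raw
        comm = pc.CommunityTable(cover=cover, ages=pd.Series({"p1": 4.0}))
        x = rng.normal(size=5)
        traits = pd.DataFrame({"x": np.zeros(yule_tree.n_tips)},
                              index=list(yule_tree.tip_labels))
        traits.loc[labels, "x"] = x
        (ens,) = pc.null_abundance_shuffle(comm, traits, runs=4000, seed=8)
        p = w_raw / w_raw.sum()
        exhaustive = [
            pc.cwv(x, np.asarray(perm)) for perm in itertools.permutations(p)
        ]
        assert ens.values.mean() == pytest.approx(np.mean(exhaustive), rel=0.02)
        assert ens.values.std(ddof=1) == pytest.approx(np.std(exhaustive, ddof=1), rel=0.1)

    def test_preserves_abundance_multiset(self, small_dataset):
        # a shuffle run must redistribute, never alter, the covers: the null
        # CWV values all lie in the finite set generated by permutations
        tree, traits, community = small_dataset
        ens = pc.null_abundance_shuffle(community, traits[["LA"]], runs=99, seed=9)
        rel = community.relative()
        for e in ens:
            w_full = rel.loc[e.plot].to_numpy()
            present = np.flatnonzero(w_full > 0)
            w = w_full[present] / w_full[present].sum()
            x = traits["LA"].reindex([community.species[i] for i in present]).to_numpy()
            allowed = np.array(sorted(
                pc.cwv(x, np.asarray(p)) for p in itertools.permutations(w)
            ))
            for v in e.values:
                assert np.isclose(allowed, v, rtol=1e-9).any()


class TestSESTable:
    def test_tidy_schema_and_determinism(self, small_dataset):
        tree, traits, community = small_dataset
        dp = tree.cophenetic_distances()
        dd = pc.trait_dendrogram(traits).cophenetic()
        df1 = pc.ses_table(community, dp, dd, traits, runs=99, seed=11)
        df2 = pc.ses_table(community, dp, dd, traits, runs=99, seed=11)
        pd.testing.assert_frame_equal(df1, df2)
        assert set(df1.columns) == {"plot", "age", "metric", "observed", "null_mean",
                                    "null_sd", "ses", "rank", "pattern"}
        metrics = set(df1["metric"])
        assert {"MPD", "MFD"} <= metrics
        assert any(m.startswith("CWV.") for m in metrics)

    def test_neutral_assembly_calibrated(self):
        # uniform random plots: ≈5% clustering and ≈5% overdispersion
        tree = pc.simulate_tree(40, seed=60)
        d = tree.cophenetic_distances()
        comm = random_community(tree.tip_labels, 300, 8, np.random.default_rng(61))
        df = pc.ses_table(comm, phylo_dist=d, runs=199, seed=62)
        rate_low = (df["pattern"] == "clustering").mean()
        rate_high = (df["pattern"] == "overdispersion").mean()
        assert 0.01 <= rate_low <= 0.10
        assert 0.01 <= rate_high <= 0.10
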