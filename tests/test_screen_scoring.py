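"""Screen scoring: parser filter, counting, NB test, RRA, summaries."""

import collections

import numpy as np
import pandas as pd
import pytest
from scipy import stats

import levelscan as ls
from levelscan.screen_scoring import (
    fit_mean_variance_trend,
    nb_tail_probabilities,
    rank_plot_table,
)


@pytest.fixture
def tiny_library():
    rows = []
    for gene, cassette in [("TARDBP", "TARDBP_c1"), ("TARDBP", "TARDBP_c2"),
                           ("BORCS6", "BORCS6_c1"), (ls.NT_GENE, "NT_c1"),
                           (ls.NT_GENE, "NT_c2")]:
        rows.append((cassette + "_a", cassette, gene))
        rows.append((cassette + "_b", cassette, gene))
    return pd.DataFrame(rows, columns=["guide_id", "guide_pair_id", "gene"])


class TestRecombinationFilter:
    def test_same_gene_kept_cross_gene_removed(self, tiny_library):
        calls = pd.DataFrame(
            {
                "read_id": ["r1", "r2", "r3"],
                "sample": ["high"] * 3,
                "guide_a": ["TARDBP_c1_a", "TARDBP_c1_a", "NT_c1_a"],
                "guide_b": ["TARDBP_c2_b", "BORCS6_c1_b", "NT_c2_b"],
            }
        )
        kept, tally = ls.filter_recombined_pairs(calls, tiny_library)
        # same-gene pair (even across cassettes) and NT-NT pair survive
        assert list(kept["read_id"]) == ["r1", "r3"]
        assert tally == {"recombined": 1, "unknown_guide": 0}

    def test_unknown_guide_goes_to_error_channel(self, tiny_library):
        calls = pd.DataFrame(
            {
                "read_id": ["r1"],
                "sample": ["high"],
                "guide_a": ["MYSTERY_g1"],
                "guide_b": ["TARDBP_c1_b"],
            }
        )
        kept, tally = ls.filter_recombined_pairs(calls, tiny_library)
        assert len(kept) == 0
        assert tally == {"recombined": 0, "unknown_guide": 1}

    def test_random_fixture_matches_brute_force_and_idempotent(self, tiny_library):
        rng = np.random.default_rng(0)
        guides = tiny_library["guide_id"].tolist()
        gene_of = dict(zip(tiny_library["guide_id"], tiny_library["gene"]))
        calls = pd.DataFrame(
            {
                "read_id": [f"r{i}" for i in range(1000)],
                "sample": rng.choice(["high", "low"], 1000),
                "guide_a": rng.choice(guides, 1000),
                "guide_b": rng.choice(guides, 1000),
            }
        )
        kept, tally = ls.filter_recombined_pairs(calls, tiny_library)
        expected = {
            r.read_id
            for r in calls.itertuples()
            if gene_of[r.guide_a] == gene_of[r.guide_b]
        }
        assert set(kept["read_id"]) == expected
        assert tally["recombined"] == 1000 - len(expected)
        kept2, tally2 = ls.filter_recombined_pairs(kept, tiny_library)
        assert len(kept2) == len(kept) and tally2["recombined"] == 0


class TestAggregation:
    def test_tally_matches_counter_oracle(self, tiny_library):
        rng = np.random.default_rng(1)
        cassettes = tiny_library["guide_pair_id"].unique()
        chosen = rng.choice(cassettes, 1000)
        sample = rng.choice(["high", "low"], 1000)
        calls = pd.DataFrame(
            {
                "read_id": [f"r{i}" for i in range(1000)],
                "sample": sample,
                "guide_a": [c + "_a" for c in chosen],
                "guide_b": [c + "_b" for c in chosen],
            }
        )
        counts = ls.aggregate_counts(calls, tiny_library, samples=["high", "low"])
        oracle = collections.Counter(zip(chosen, sample))
        for row in counts.itertuples():
            assert row.high == oracle[(row.guide_pair_id, "high")]
            assert row.low == oracle[(row.guide_pair_id, "low")]

    def test_missing_cassettes_get_zero_rows(self, tiny_library):
        calls = pd.DataFrame(
            {
                "read_id": ["r1"] * 5,
                "sample": ["high"] * 5,
                "guide_a": ["TARDBP_c1_a"] * 5,
                "guide_b": ["TARDBP_c1_b"] * 5,
            }
        )
        counts = ls.aggregate_counts(calls, tiny_library, samples=["high"])
        assert len(counts) == tiny_library["guide_pair_id"].nunique()
        tab = counts.set_index("guide_pair_id")["high"]
        assert tab["TARDBP_c1"] == 5 and tab.drop("TARDBP_c1").eq(0).all()


class TestLowCountFilter:
    def test_zero_threshold_is_identity(self):
        df = pd.DataFrame(
            {"guide_pair_id": ["a", "b"], "gene": ["G1", "G2"],
             "high": [0, 5], "low": [0, 5]}
        )
        out = ls.filter_low_count_guides(df, min_count=0)
        pd.testing.assert_frame_equal(out, df)

    def test_boundary_mean_below_threshold_removed(self):
        df = pd.DataFrame(
            {"guide_pair_id": ["a", "b"], "gene": ["G1", "G2"],
             "high": [9, 10], "low": [10.8, 10]}
        )
        out = ls.filter_low_count_guides(df, min_count=10)
        assert list(out["guide_pair_id"]) == ["b"]  # mean 9.9 fails, 10 passes

    def test_random_fixture_matches_row_rule(self):
        rng = np.random.default_rng(2)
        df = pd.DataFrame(
            {
                "guide_pair_id": [f"c{i}" for i in range(500)],
                "gene": "G",
                "high": rng.integers(0, 40, 500),
                "low": rng.integers(0, 40, 500),
            }
        )
        out = ls.filter_low_count_guides(df, min_count=10)
        expected = df[(df["high"] + df["low"]) / 2 >= 10]
        assert list(out["guide_pair_id"]) == list(expected["guide_pair_id"])


class TestNormalization:
    def _table(self, rng, n=300):
        return pd.DataFrame(
            {
                "guide_pair_id": [f"c{i}" for i in range(n)],
                "gene": "G",
                "s1": rng.negative_binomial(10, 0.05, n) + 1,
                "s2": rng.negative_binomial(10, 0.05, n) + 1,
            }
        )

    def test_identical_samples_equal_factors(self):
        rng = np.random.default_rng(3)
        df = self._table(rng)
        df["s2"] = df["s1"]
        _, size = ls.normalize_counts(df)
        assert size["s1"] == pytest.approx(size["s2"])

    def test_doubled_sample_factor_ratio_two_and_columns_agree(self):
        # within one table, B = 2A exactly: size factor ratio 2 and the
        # normalized columns coincide
        rng = np.random.default_rng(4)
        df = self._table(rng)
        df["s2"] = df["s1"] * 2
        norm, size = ls.normalize_counts(df)
        assert size["s2"] / size["s1"] == pytest.approx(2.0)
        np.testing.assert_allclose(norm["s1"], norm["s2"])

    def test_median_ratio_matches_direct_formula(self):
        rng = np.random.default_rng(5)
        df = self._table(rng)
        _, size = ls.normalize_counts(df)
        mat = df[["s1", "s2"]].to_numpy(float)
        rows = (mat > 0).all(axis=1)
        gm = np.exp(np.log(mat[rows]).mean(axis=1))
        for j, s in enumerate(["s1", "s2"]):
            assert size[s] == pytest.approx(np.median(mat[rows, j] / gm))

    def test_all_zero_sample_rejected(self):
        df = pd.DataFrame(
            {"guide_pair_id": ["a"], "gene": ["G"], "s1": [5], "s2": [0]}
        )
        with pytest.raises(ValueError, match="all-zero"):
            ls.normalize_counts(df)


class TestGuideNBTest:
    def test_pvalues_match_pmf_summation(self):
        # direct pmf summation oracle, 100 random (mu, var, obs) triples
        rng = np.random.default_rng(6)
        mu = rng.uniform(2, 200, 100)
        var = mu * rng.uniform(1.05, 4.0, 100)
        obs = rng.integers(0, 300, 100)
        p_low, p_high = nb_tail_probabilities(obs, mu, var)
        for i in range(100):
            r = mu[i] ** 2 / (var[i] - mu[i])
            pnb = r / (r + mu[i])
            pmf = stats.nbinom.pmf(np.arange(0, max(obs[i] + 1, 1)), r, pnb)
            assert abs(p_low[i] - pmf[: obs[i] + 1].sum()) < 1e-10
            assert abs(p_high[i] - (1.0 - pmf[: obs[i]].sum())) < 1e-10

    def test_null_cassette_near_median(self):
        rng = np.random.default_rng(7)
        n = 400
        base = rng.negative_binomial(20, 0.1, n).astype(float) + 1
        df = pd.DataFrame(
            {
                "guide_pair_id": [f"c{i}" for i in range(n)],
                "gene": "G",
                "high": base * rng.uniform(0.9, 1.1, n),
                "low": base,
            }
        )
        out = ls.guide_nb_test(df, high=["high"], low=["low"])
        row = out.iloc[0]
        # a cassette observed at its reference mean sits mid-distribution
        mid = df.index[np.argsort(base)[n // 2]]
        row = out.iloc[mid]
        assert 0.2 < row["p_low"] < 0.9 and 0.2 < row["p_high"] < 0.9

    def test_extreme_depletion_direction(self):
        df = pd.DataFrame(
            {
                "guide_pair_id": [f"c{i}" for i in range(200)],
                "gene": "G",
                "high": [0.0] + [100.0] * 199,
                "low": [500.0] + [100.0] * 199,
            }
        )
        out = ls.guide_nb_test(df, high=["high"], low=["low"])
        assert out.loc[0, "p_low"] < 1e-4
        assert out.loc[0, "lfc"] < -5

    def test_trend_fit_recovers_overdispersion(self):
        rng = np.random.default_rng(8)
        mu = np.exp(rng.uniform(np.log(20), np.log(2000), 2000))
        phi = 0.1
        r = 1 / phi
        mat = rng.negative_binomial(r, r / (r + mu[:, None]), (2000, 4))
        fit = fit_mean_variance_trend(mat.astype(float))
        assert fit is not None
        k, b = fit
        # var = mu + k mu^b should roughly match var = mu + phi mu^2
        assert b == pytest.approx(2.0, abs=0.25)


class TestRRA:
    def test_rho_closed_form_beta_order_statistics(self):
        # ranks (0.1, 0.2): min(1 - 0.9^2, 0.2^2) = 0.04
        assert ls.rra_rho([0.1, 0.2]) == pytest.approx(0.04, abs=1e-12)
        assert ls.rra_rho([]) == 1.0
        assert 0 < ls.rra_rho([0.99, 0.995]) <= 1.0

    def test_select_only_alpha_behavior(self):
        # a guide failing alpha contributes nothing but still counts in m
        full = ls.rra_rho([0.1, 0.8])
        selected = ls.rra_rho([0.1], m=2)
        assert selected == pytest.approx(1 - 0.9**2, abs=1e-12)
        assert full <= selected

    def _stats_frame(self, p_values, genes):
        return pd.DataFrame(
            {
                "guide_pair_id": [f"c{i:02d}" for i in range(len(p_values))],
                "gene": genes,
                "p_low": p_values,
                "p_high": 1.0 - np.asarray(p_values) / 2,
                "lfc": -np.asarray(p_values),
            }
        )

    def test_top_ranked_gene_hits_permutation_floor(self):
        # with a large background the chance of the null redrawing the hit's
        # own top ranks is negligible, so p bottoms out at 1/(n_perm+1)
        n_bg = 400
        p = [1e-9, 2e-9] + list(np.linspace(0.3, 0.9, n_bg))
        gs = self._stats_frame(p, ["HIT"] * 2 + [f"G{i}" for i in range(n_bg)])
        out = ls.gene_rra(gs, "neg", alpha=0.25, n_perm=500, seed=0)
        assert out.set_index("gene").loc["HIT", "p_neg"] == pytest.approx(
            1 / 501
        )

    def test_permutation_p_matches_exhaustive_enumeration(self):
        p = [0.01, 0.04, 0.12, 0.2, 0.5, 0.8]
        gs = self._stats_frame(p, ["A", "A", "B", "B", "C", "C"])
        mc = ls.gene_rra(gs, "neg", alpha=1.0, n_perm=20000, seed=1)
        ex = ls.gene_rra(gs, "neg", alpha=1.0, exhaustive=True)
        for gene in "ABC":
            p_mc = mc.set_index("gene").loc[gene, "p_neg"]
            p_ex = ex.set_index("gene").loc[gene, "p_neg"]
            se = np.sqrt(p_ex * (1 - p_ex) / 20000)
            assert abs(p_mc - p_ex) < 4 * se + 2e-4

    def test_fdr_not_below_p(self):
        p = list(np.linspace(0.001, 0.9, 12))
        gs = self._stats_frame(p, [f"G{i // 2}" for i in range(12)])
        out = ls.gene_rra(gs, "neg", alpha=0.5, n_perm=200, seed=2)
        assert (out["fdr_neg"] >= out["p_neg"] - 1e-12).all()
        assert out["rho_neg"].between(0, 1, inclusive="right").all()

    def test_nt_cassettes_form_pseudogenes_not_genes(self):
        p = np.linspace(0.01, 0.9, 12)
        genes = ["G1"] * 2 + ["G2"] * 2 + [ls.NT_GENE] * 8
        gs = self._stats_frame(p, genes)
        out = ls.gene_rra(gs, "neg", alpha=1.0, n_perm=200, seed=3,
                          nt_pseudogene_size=4)
        assert set(out.loc[out["is_control"], "gene"]) == {
            "NTPSEUDO_001", "NTPSEUDO_002"
        }
        assert ls.NT_GENE not in set(out["gene"])

    def test_null_screen_permutation_p_uniform(self):
        # fully null screen, alpha=1 so every guide contributes: gene-level
        # permutation p should be uniform (alpha-selection would instead put
        # a legitimate point mass at p=1 for genes with no selected guide)
        from scipy.stats import kstest

        cfg = ls.ScreenSimConfig(
            n_genes=400, guides_per_gene=4, n_control_guides=40,
            frac_true_hits=0.0, cells_per_guide=300, reads_per_bin=200_000,
            recombination_rate=0.0, seed=13,
        )
        calls, counts, _, library = ls.simulate_sorting_screen(cfg)
        norm, _ = ls.normalize_counts(counts)
        gstats = ls.guide_nb_test(norm, high=["high"], low=["low"])
        out = ls.gene_rra(gstats, "neg", alpha=1.0, n_perm=2000, seed=14)
        ks = kstest(out["p_neg"], "uniform")
        assert ks.pvalue > 0.01


class TestScreenSummary:
    def test_doubling_rule_and_cap(self):
        gs = pd.DataFrame(
            {
                "gene": ["A", "B"],
                "gene_lfc": [-2.0, 0.1],
                "p_neg": [0.001, 1.0],
                "p_pos": [0.8, 1.0],
                "is_control": [False, False],
            }
        )
        out = ls.screen_summary(gs).set_index("gene")
        assert out.loc["A", "p"] == pytest.approx(0.002)
        assert out.loc["A", "direction"] == "neg"
        assert out.loc["B", "p"] == 1.0

    def test_random_table_row_oracle(self):
        rng = np.random.default_rng(9)
        gs = pd.DataFrame(
            {
                "gene": [f"G{i}" for i in range(200)],
                "gene_lfc": rng.normal(size=200),
                "p_neg": rng.uniform(1e-4, 1, 200),
                "p_pos": rng.uniform(1e-4, 1, 200),
                "is_control": False,
            }
        )
        out = ls.screen_summary(gs)
        expected = np.minimum(1.0, 2 * np.minimum(gs["p_neg"], gs["p_pos"]))
        np.testing.assert_allclose(out["p"], expected)

    def test_rank_plot_orders_by_effect(self):
        gs = pd.DataFrame(
            {
                "gene": ["A", "B", "C"],
                "gene_lfc": [1.0, -2.0, 0.5],
                "p_neg": [0.5, 0.01, 0.7],
                "p_pos": [0.05, 0.9, 0.6],
                "is_control": [False, False, False],
            }
        )
        out = rank_plot_table(gs)
        assert list(out["gene"]) == ["B", "A", "C"] or list(out["gene"]) == [
            "B", "C", "A"
        ]
        assert out.loc[out["gene"] == "B", "signed_log10_p"].iloc[0] < 0
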