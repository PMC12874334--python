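import itertools

import numpy as np
import pandas as pd
import pytest

from lungomics.expression import (
    deconvolution_group_test,
    filter_low_counts,
    gsea_es,
    marker_deconvolution,
    module_score,
    nb_wald_de,
    preranked_gsea,
    preranked_gsea_collection,
    size_factors_median_of_ratios,
    tmm_factors,
)


def toy_counts():
    return pd.DataFrame(
        {"s1": [10, 20, 30, 40, 100], "s2": [20, 40, 60, 80, 200]},
        index=[f"g{i}" for i in range(5)],
    )


class TestFilter:
    def test_boundaries(self):
        counts = pd.DataFrame({"s1": [4, 5], "s2": [5, 5]}, index=["low", "ok"])
        kept = filter_low_counts(counts, 10)
        assert list(kept.index) == ["ok"]

    def test_all_zero(self, caplog):
        counts = pd.DataFrame({"s1": [0], "s2": [0]}, index=["g"])
        with caplog.at_level("WARNING"):
            assert filter_low_counts(counts).empty

    def test_order_preserved(self):
        counts = pd.DataFrame(
            {"s1": [50, 1, 60], "s2": [50, 1, 60]}, index=["b", "skip", "a"]
        )
        assert list(filter_low_counts(counts).index) == ["b", "a"]


class TestSizeFactors:
    def test_doubling_example(self):
        f = size_factors_median_of_ratios(toy_counts())
        assert f["s1"] == pytest.approx(1 / np.sqrt(2))
        assert f["s2"] == pytest.approx(np.sqrt(2))

    def test_identical_samples(self):
        counts = pd.DataFrame({"s1": [5, 10], "s2": [5, 10]})
        assert np.allclose(size_factors_median_of_ratios(counts), 1.0)

    def test_permutation_equivariance(self):
        counts = toy_counts()
        f = size_factors_median_of_ratios(counts)
        g = size_factors_median_of_ratios(counts[["s2", "s1"]])
        assert f["s1"] == pytest.approx(g["s1"])
        assert f["s2"] == pytest.approx(g["s2"])

    def test_no_common_gene_rejected(self):
        counts = pd.DataFrame({"s1": [5, 0], "s2": [0, 5]})
        with pytest.raises(ValueError):
            size_factors_median_of_ratios(counts)


class TestTMM:
    def test_identical_samples(self):
        counts = pd.DataFrame({"s1": [5, 10, 50], "s2": [5, 10, 50]})
        assert np.allclose(tmm_factors(counts), 1.0)

    def test_geometric_mean_one(self):
        rng = np.random.default_rng(0)
        counts = pd.DataFrame(
            rng.integers(1, 500, size=(200, 4)), columns=list("abcd")
        )
        f = tmm_factors(counts)
        assert np.exp(np.mean(np.log(f))) == pytest.approx(1.0)

    def test_pure_library_size_difference(self):
        rng = np.random.default_rng(1)
        base = rng.integers(10, 500, size=100)
        counts = pd.DataFrame({"s1": base, "s2": 3 * base})
        assert np.allclose(tmm_factors(counts), 1.0, atol=1e-9)

    def test_single_sample_rejected(self):
        with pytest.raises(ValueError):
            tmm_factors(pd.DataFrame({"s1": [1, 2]}))


def null_design(n=3):
    samples = [f"s{j}" for j in range(2 * n)]
    return pd.DataFrame(
        {"tissue": "normal", "treatment": ["HDM"] * n + ["VEH"] * n},
        index=samples,
    )


class TestDE:
    def test_identical_groups_zero_fc(self):
        counts = pd.DataFrame(
            np.tile([[100], [50]], (1, 6)), index=["g1", "g2"],
            columns=null_design().index,
        )
        de = nb_wald_de(counts, null_design(), "normal")
        assert np.allclose(de["log2fc"], 0.0)
        assert not de["is_deg"].any()

    def test_planted_power(self):
        rng = np.random.default_rng(4)
        n_genes, n = 400, 3
        mu0 = np.full(n_genes, 200.0)
        fc = np.zeros(n_genes)
        fc[:80] = 3.0  # planted log2FC = 3, low dispersion
        mu = mu0[:, None] * np.exp2(
            np.concatenate([np.tile(fc[:, None], (1, n)),
                            np.zeros((n_genes, n))], axis=1)
        )
        r = 1 / 0.01
        counts = pd.DataFrame(
            rng.negative_binomial(r, r / (r + mu)),
            index=[f"g{i}" for i in range(n_genes)], columns=null_design().index,
        )
        de = nb_wald_de(filter_low_counts(counts), null_design(), "normal")
        planted = de.iloc[:80]
        assert planted["is_deg"].mean() > 0.9

    def test_deg_flag_invariant(self):
        rng = np.random.default_rng(5)
        counts = pd.DataFrame(
            rng.integers(5, 400, size=(100, 6)), columns=null_design().index,
            index=[f"g{i}" for i in range(100)],
        )
        de = nb_wald_de(counts, null_design(), "normal")
        assert ((de["fdr"] < 0.05) & (de["log2fc"].abs() >= 1)).equals(de["is_deg"])

    def test_gene_and_sample_order_invariance(self):
        rng = np.random.default_rng(6)
        counts = pd.DataFrame(
            rng.integers(5, 400, size=(50, 6)), columns=null_design().index,
            index=[f"g{i}" for i in range(50)],
        )
        design = null_design()
        de1 = nb_wald_de(counts, design, "normal")
        shuffled = counts.sample(frac=1, random_state=1)
        de2 = nb_wald_de(shuffled, design, "normal").loc[de1.index]
        pd.testing.assert_frame_equal(de1, de2)

    def test_small_group_rejected(self):
        design = null_design().iloc[[0, 3, 4]]
        counts = pd.DataFrame(
            np.ones((5, 3)) * 10, columns=design.index,
            index=[f"g{i}" for i in range(5)],
        )
        with pytest.raises(ValueError):
            nb_wald_de(counts, design, "normal")


class TestModuleScore:
    def test_all_members_at_z1(self):
        # one sample exactly 1 sd above each gene's mean
        log_expr = pd.DataFrame(
            {"s1": [1.0, 2.0], "s2": [3.0, 4.0], "s3": [2.0, 3.0]},
            index=["a", "b"],
        )
        score = module_score(log_expr, ["a", "b"])
        sd = log_expr.std(axis=1, ddof=1)
        expected = ((log_expr["s2"] - log_expr.mean(axis=1)) / sd).mean()
        assert score["s2"] == pytest.approx(expected)

    def test_scores_center_to_zero(self):
        rng = np.random.default_rng(7)
        log_expr = pd.DataFrame(
            rng.normal(5, 1, size=(10, 6)),
            index=[f"g{i}" for i in range(10)],
            columns=[f"s{j}" for j in range(6)],
        )
        score = module_score(log_expr, [f"g{i}" for i in range(4)])
        assert score.sum() == pytest.approx(0.0, abs=1e-10)

    def test_constant_gene_contributes_zero(self):
        log_expr = pd.DataFrame(
            {"s1": [5.0, 1.0], "s2": [5.0, 3.0], "s3": [5.0, 2.0]},
            index=["flat", "var"],
        )
        with_flat = module_score(log_expr, ["flat", "var"])
        only_var = module_score(log_expr, ["var"])
        assert np.allclose(with_flat, only_var / 2)

    def test_invariant_to_extra_genes(self):
        rng = np.random.default_rng(8)
        log_expr = pd.DataFrame(
            rng.normal(5, 1, size=(20, 4)),
            index=[f"g{i}" for i in range(20)],
            columns=[f"s{j}" for j in range(4)],
        )
        members = ["g0", "g1", "g2"]
        full = module_score(log_expr, members)
        subset = module_score(log_expr.loc[members], members)
        assert np.allclose(full, subset)

    def test_no_member_present_rejected(self):
        log_expr = pd.DataFrame({"s1": [1.0], "s2": [2.0], "s3": [1.5]}, index=["a"])
        with pytest.raises(ValueError):
            module_score(log_expr, ["missing"])


def gsea_es_oracle(stats_sorted, hits):
    """Brute-force running-sum enrichment score (positive extreme wins
    exact-magnitude ties).  Returns (es, best_pos, best_neg)."""
    n = len(stats_sorted)
    nh = sum(hits)
    denom_hit = sum(abs(s) for s, h in zip(stats_sorted, hits) if h)
    unweighted = denom_hit == 0
    running, best_pos, best_neg = 0.0, -np.inf, np.inf
    for s, h in zip(stats_sorted, hits):
        if h:
            running += (1.0 / nh) if unweighted else abs(s) / denom_hit
        else:
            running -= 1.0 / (n - nh)
        best_pos = max(best_pos, running)
        best_neg = min(best_neg, running)
    es = best_pos if best_pos >= -best_neg else best_neg
    return es, best_pos, best_neg


def assert_es_matches_oracle(es, stats_sorted, hits):
    oracle_es, best_pos, best_neg = gsea_es_oracle(stats_sorted, hits)
    if abs(best_pos + best_neg) < 1e-9:
        # magnitude tie: sign is a convention, magnitude must agree
        assert abs(es) == pytest.approx(best_pos, abs=1e-9)
    else:
        assert es == pytest.approx(oracle_es, abs=1e-9)


class TestGsea:
    def test_top_gene_set_es_one(self):
        ranked = pd.Series([1.0, 1.0, 1.0, 1.0], index=list("abcd"))
        rng = np.random.default_rng(0)
        res = preranked_gsea(ranked, ["a"], n_perm=100, rng=rng)
        assert res.es == pytest.approx(1.0)

    def test_reversed_ranking_negates_es(self):
        rng = np.random.default_rng(1)
        stats = pd.Series([4.0, 3.0, 2.0, 1.0, 0.5], index=list("abcde"))
        es_fwd = preranked_gsea(stats, ["a", "b"], n_perm=50,
                                rng=np.random.default_rng(0)).es
        es_rev = preranked_gsea(-stats, ["a", "b"], n_perm=50,
                                rng=np.random.default_rng(0)).es
        assert es_fwd == pytest.approx(-es_rev)

    def test_exhaustive_oracle_small(self):
        rng = np.random.default_rng(2)
        for n in range(3, 9):
            for trial in range(3):
                stats = np.sort(rng.normal(size=n))[::-1]
                if trial == 2:
                    stats = np.round(stats)  # introduce ties / zeros
                for r in range(1, n):
                    for subset in itertools.combinations(range(n), r):
                        hits = np.zeros(n, dtype=bool)
                        hits[list(subset)] = True
                        es, _ = gsea_es(stats, hits)
                        assert_es_matches_oracle(es, list(stats), list(hits))

    def test_full_set_rejected(self):
        ranked = pd.Series([2.0, 1.0], index=["a", "b"])
        with pytest.raises(ValueError):
            preranked_gsea(ranked, ["a", "b"], n_perm=10)

    def test_random_set_null_p(self):
        rng = np.random.default_rng(3)
        stats = pd.Series(rng.normal(size=60),
                          index=[f"g{i}" for i in range(60)])
        ps = []
        for k in range(40):
            members = [f"g{i}" for i in rng.choice(60, 8, replace=False)]
            res = preranked_gsea(stats, members, n_perm=200,
                                 rng=np.random.default_rng(k))
            ps.append(res.p)
        # null permutation p-values should not concentrate near zero
        assert np.mean(np.array(ps) < 0.1) < 0.3
        assert 0.2 < np.mean(ps) < 0.8

    def test_collection_fdr(self):
        rng = np.random.default_rng(4)
        stats = pd.Series(rng.normal(size=30), index=[f"g{i}" for i in range(30)])
        sets = {"s1": ["g0", "g1"], "s2": ["g5", "g6", "g7"]}
        table = preranked_gsea_collection(stats, sets, n_perm=100,
                                          rng=np.random.default_rng(0))
        assert set(table.index) == {"s1", "s2"}
        assert (table["fdr"] >= table["p"] - 1e-12).all()
        assert np.all(np.sign(table["nes"]) == np.sign(table["es"]))


class TestDeconvolution:
    def test_constant_markers(self):
        log_expr = pd.DataFrame(
            5.0, index=["m1", "m2"], columns=["s1", "s2", "s3"]
        )
        scores = marker_deconvolution(log_expr, {"pop": ["m1", "m2"]})
        assert np.allclose(scores.loc["pop"], 5.0)

    def test_doubling_tpm_adds_one(self):
        tpm = pd.DataFrame(
            {"s1": [10.0, 20.0], "s2": [40.0, 80.0]}, index=["m1", "m2"]
        )
        lo = marker_deconvolution(np.log2(tpm), {"pop": ["m1", "m2"]})
        hi = marker_deconvolution(np.log2(2 * tpm), {"pop": ["m1", "m2"]})
        assert np.allclose(hi - lo, 1.0)

    def test_absent_population_omitted(self, caplog):
        log_expr = pd.DataFrame({"s1": [1.0], "s2": [2.0]}, index=["m1"])
        with caplog.at_level("WARNING"):
            scores = marker_deconvolution(
                log_expr, {"pop": ["m1"], "ghost": ["nope"]}
            )
        assert list(scores.index) == ["pop"]

    def test_planted_myeloid_up(self, light_study):
        bundle = light_study
        log_tpm = np.log2(bundle.tpm + 1.0)
        scores = marker_deconvolution(log_tpm, bundle.truth.markers)
        tests = deconvolution_group_test(scores, bundle.design, "normal")
        assert tests.loc["myeloid", "p"] < 0.05
        assert tests.loc["myeloid", "t"] > 0
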