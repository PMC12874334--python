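import numpy as np
import pandas as pd
import pytest

from conftest import light_config, run_integration_chain
from lungomics.integration import (
    build_promoter_map,
    classify_quadrants,
    derive_dmgs,
    integration_report,
    inverse_correlation_filter,
)
from lungomics.simulate import simulate_study


def annotation(rows):
    return pd.DataFrame(rows).set_index("gene")


class TestPromoterMap:
    def test_plus_strand(self):
        ann = annotation([{"gene": "g", "chrom": "chr1", "strand": "+", "tss": 10000}])
        pmap = build_promoter_map(ann)
        assert pmap.loc["g", "start"] == 8500
        assert pmap.loc["g", "end"] == 10500

    def test_minus_strand_mirror(self):
        ann = annotation([{"gene": "g", "chrom": "chr1", "strand": "-", "tss": 10000}])
        pmap = build_promoter_map(ann)
        assert pmap.loc["g", "start"] == 9501
        assert pmap.loc["g", "end"] == 11501

    def test_width_2000(self):
        ann = annotation(
            [{"gene": f"g{i}", "chrom": "chr1", "strand": s, "tss": 50000 + 7 * i}
             for i, s in enumerate("+-+-")]
        )
        pmap = build_promoter_map(ann)
        assert ((pmap["end"] - pmap["start"]) == 2000).all()

    def test_clipping_warns(self, caplog):
        ann = annotation([{"gene": "g", "chrom": "chr1", "strand": "+", "tss": 100}])
        with caplog.at_level("WARNING"):
            pmap = build_promoter_map(ann, {"chr1": 1000})
        assert pmap.loc["g", "start"] == 0
        assert "clipped" in caplog.text

    def test_unknown_strand_rejected(self):
        ann = annotation([{"gene": "g", "chrom": "chr1", "strand": ".", "tss": 5000}])
        with pytest.raises(ValueError):
            build_promoter_map(ann)


def site_diff_table(rows):
    df = pd.DataFrame(rows).set_index("site")
    return df


class TestDeriveDmgs:
    def pmap(self):
        ann = annotation(
            [{"gene": "G", "chrom": "chr1", "strand": "+", "tss": 10000}]
        )
        return build_promoter_map(ann)

    def test_interval_membership(self):
        sd = site_diff_table(
            [{"site": "c1", "p": 0.01, "delta_beta": 0.3, "mean_quot_log2": 0.5}]
        )
        coords = pd.DataFrame({"chrom": ["chr1"], "pos": [9000]}, index=["c1"])
        dmgs = derive_dmgs(sd, coords, self.pmap())
        assert list(dmgs.index) == ["G"]
        assert dmgs.loc["G", "meth_log2fc"] == pytest.approx(0.5)

    def test_outside_promoter_ignored(self):
        sd = site_diff_table(
            [{"site": "c1", "p": 0.01, "delta_beta": 0.3, "mean_quot_log2": 0.5}]
        )
        coords = pd.DataFrame({"chrom": ["chr1"], "pos": [20000]}, index=["c1"])
        assert derive_dmgs(sd, coords, self.pmap()).empty

    def test_nonsignificant_ignored(self):
        sd = site_diff_table(
            [{"site": "c1", "p": 0.5, "delta_beta": 0.3, "mean_quot_log2": 0.5}]
        )
        coords = pd.DataFrame({"chrom": ["chr1"], "pos": [9000]}, index=["c1"])
        assert derive_dmgs(sd, coords, self.pmap()).empty

    def test_overlapping_promoters_assign_to_both(self):
        ann = annotation(
            [{"gene": "A", "chrom": "chr1", "strand": "+", "tss": 10000},
             {"gene": "B", "chrom": "chr1", "strand": "+", "tss": 10400}]
        )
        pmap = build_promoter_map(ann)
        sd = site_diff_table(
            [{"site": "c1", "p": 0.01, "delta_beta": 0.3, "mean_quot_log2": 0.5}]
        )
        coords = pd.DataFrame({"chrom": ["chr1"], "pos": [9600]}, index=["c1"])
        dmgs = derive_dmgs(sd, coords, pmap)
        assert sorted(dmgs.index) == ["A", "B"]

    def test_no_significant_sites(self):
        sd = site_diff_table(
            [{"site": "c1", "p": 0.9, "delta_beta": 0.0, "mean_quot_log2": 0.0}]
        )
        coords = pd.DataFrame({"chrom": ["chr1"], "pos": [9000]}, index=["c1"])
        assert derive_dmgs(sd, coords, self.pmap()).empty


def de_table(rows):
    df = pd.DataFrame(rows).set_index("gene")
    df["fdr"] = df.get("fdr", 0.01)
    df["is_deg"] = (df["fdr"] < 0.05) & (df["log2fc"].abs() >= 1)
    return df


def dmg_table(rows):
    return pd.DataFrame(rows).set_index("gene")


class TestQuadrants:
    def test_hypo_up(self):
        rec = classify_quadrants(
            dmg_table([{"gene": "g", "meth_log2fc": -0.5}]),
            de_table([{"gene": "g", "log2fc": 2.0, "fdr": 0.01}]),
        )
        assert rec.loc["g", "quadrant"] == "hypo_up"

    def test_low_effect_rna(self):
        rec = classify_quadrants(
            dmg_table([{"gene": "g", "meth_log2fc": -0.5}]),
            de_table([{"gene": "g", "log2fc": 0.5, "fdr": 0.01}]),
        )
        assert rec.loc["g", "quadrant"] == "low_effect"

    def test_hyper_down_at_threshold(self):
        rec = classify_quadrants(
            dmg_table([{"gene": "g", "meth_log2fc": 0.15}]),
            de_table([{"gene": "g", "log2fc": -1.2, "fdr": 0.01}]),
        )
        assert rec.loc["g", "quadrant"] == "hyper_down"

    def test_missing_gene_skipped(self):
        rec = classify_quadrants(
            dmg_table([{"gene": "g", "meth_log2fc": 0.2},
                       {"gene": "ghost", "meth_log2fc": 0.2}]),
            de_table([{"gene": "g", "log2fc": -1.2, "fdr": 0.01}]),
        )
        assert list(rec.index) == ["g"]

    def test_label_swap_symmetry(self):
        # negating both effect axes maps hyper_up<->hypo_down etc.
        rng = np.random.default_rng(0)
        genes = [f"g{i}" for i in range(30)]
        meth = rng.normal(0, 0.4, 30)
        rna = rng.normal(0, 2.0, 30)
        fwd = classify_quadrants(
            dmg_table([{"gene": g, "meth_log2fc": m} for g, m in zip(genes, meth)]),
            de_table([{"gene": g, "log2fc": r, "fdr": 0.01}
                      for g, r in zip(genes, rna)]),
        )
        rev = classify_quadrants(
            dmg_table([{"gene": g, "meth_log2fc": -m} for g, m in zip(genes, meth)]),
            de_table([{"gene": g, "log2fc": -r, "fdr": 0.01}
                      for g, r in zip(genes, rna)]),
        )
        mapping = {
            "hyper_up": "hypo_down", "hypo_down": "hyper_up",
            "hyper_down": "hypo_up", "hypo_up": "hyper_down",
            "low_effect": "low_effect",
        }
        assert (fwd["quadrant"].map(mapping) == rev["quadrant"]).all()


class TestInverseCorrelation:
    def base_records(self, quadrant="hypo_up"):
        return pd.DataFrame(
            {
                "rna_log2fc": [2.0], "meth_log2fc": [-0.5], "rna_fdr": [0.01],
                "is_deg": [True], "quadrant": [quadrant],
            },
            index=["g"],
        )

    def matrices(self, beta_vals, expr_vals):
        cols = ["h1", "h2", "h3"]
        return (
            pd.DataFrame([beta_vals], index=["g"], columns=cols),
            pd.DataFrame([expr_vals], index=["g"], columns=cols),
        )

    def test_perfect_inverse_retained(self):
        beta, expr = self.matrices([0.1, 0.5, 0.9], [9.0, 5.0, 1.0])
        rec = inverse_correlation_filter(
            self.base_records(), beta, expr, ["h1", "h2", "h3"]
        )
        assert rec.loc["g", "pearson_r"] == -1.0
        assert rec.loc["g", "epi_control"] == "activated"

    def test_concordant_rejected(self):
        beta, expr = self.matrices([0.1, 0.5, 0.9], [1.0, 5.0, 9.0])
        rec = inverse_correlation_filter(
            self.base_records(), beta, expr, ["h1", "h2", "h3"]
        )
        assert rec.loc["g", "pearson_r"] == 1.0
        assert rec.loc["g", "epi_control"] == "none"

    def test_hyper_down_labeled_repressed(self):
        beta, expr = self.matrices([0.9, 0.5, 0.1], [1.0, 5.0, 9.0])
        rec = inverse_correlation_filter(
            self.base_records("hyper_down"), beta, expr, ["h1", "h2", "h3"]
        )
        assert rec.loc["g", "epi_control"] == "repressed"

    def test_r_boundary_inclusive_p_boundary_strict(self):
        # r <= -0.6 passes; p < 0.1 is strict
        rec = self.base_records()
        beta, expr = self.matrices([0.2, 0.5, 0.8], [5.0, 4.9, 1.0])
        out = inverse_correlation_filter(rec, beta, expr, ["h1", "h2", "h3"])
        r, p = out.loc["g", "pearson_r"], out.loc["g", "pearson_p"]
        expected = "activated" if (r <= -0.6 and p < 0.1) else "none"
        assert out.loc["g", "epi_control"] == expected

    def test_constant_vector_excluded(self):
        beta, expr = self.matrices([0.5, 0.5, 0.5], [9.0, 5.0, 1.0])
        rec = inverse_correlation_filter(
            self.base_records(), beta, expr, ["h1", "h2", "h3"]
        )
        assert rec.loc["g", "epi_control"] == "none"
        assert np.isnan(rec.loc["g", "pearson_r"])

    def test_too_few_samples_rejected(self):
        beta, expr = self.matrices([0.1, 0.5, 0.9], [9.0, 5.0, 1.0])
        with pytest.raises(ValueError):
            inverse_correlation_filter(self.base_records(), beta, expr, ["h1", "h2"])


class TestReport:
    def test_empty(self):
        rec = pd.DataFrame(
            columns=["rna_log2fc", "meth_log2fc", "rna_fdr", "is_deg",
                     "quadrant", "pearson_r", "pearson_p", "epi_control"]
        )
        rep = integration_report(rec, n_dmg=0, n_deg=0)
        assert rep["n_classified"] == 0
        assert rep["n_epi_control"] == 0

    def test_quadrant_partition(self, light_study):
        rec = run_integration_chain(light_study)
        rep = integration_report(rec, n_dmg=len(rec), n_deg=0)
        assert sum(rep["quadrant_counts"].values()) == rep["n_classified"]


class TestEndToEnd:
    def test_epi_control_subset_of_dmg_and_deg(self, light_study):
        rec = run_integration_chain(light_study)
        epi = rec[rec["epi_control"] != "none"]
        assert epi["is_deg"].all()
        assert epi["quadrant"].isin(["hyper_down", "hypo_up"]).all()

    def test_planted_recovery_single_seed(self, light_study):
        rec = run_integration_chain(light_study)
        truth_epi = light_study.truth.epi_genes()
        found = set(rec.index[rec["epi_control"] != "none"])
        tp = len(found & set(truth_epi))
        assert tp / len(truth_epi) >= 0.8
        assert tp / max(len(found), 1) >= 0.8
        # labels match the planted class
        for g, cls in truth_epi.items():
            if g in found:
                want = "activated" if cls == "hypo_up" else "repressed"
                assert rec.loc[g, "epi_control"] == want

    def test_null_dataset_near_zero(self):
        bundle = simulate_study(light_config(seed=201, couple_epi=False))
        rec = run_integration_chain(bundle)
        assert (rec["epi_control"] != "none").sum() <= 2
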