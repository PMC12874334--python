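"""End-to-end orchestration: simulate -> mutations -> spectra -> expression
-> methylation -> integrate.

Each stage reads only files written by earlier stages (the pipeline is a DAG
over files), and a machine-readable manifest records thresholds, seeds,
per-stage record counts and sha256 digests of every output.  Rerunning with
the same config reproduces byte-identical outputs.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Dict, List, Optional

import numpy as np
import pandas as pd
import yaml

from . import expression as expr_mod
from . import integration as integ_mod
from . import methylation as meth_mod
from . import mutations as mut_mod
from . import spectra as spec_mod
from .io import load_fasta, read_bed, read_gmt
from .simulate import SimulationConfig, TruthTable, simulate_study, write_study

logger = logging.getLogger(__name__)

__all__ = ["RunConfig", "run_all"]

STAGES = ("simulate", "mutations", "spectra", "expression", "methylation", "integrate")


@dataclass
class RunConfig:
    """Flat pipeline configuration; threshold defaults are the study values."""

    outdir: str = "pipeline_out"
    seed: int = 0
    simulation: SimulationConfig = field(default_factory=SimulationConfig)
    # mutation filters
    min_callers: int = 2
    min_samples_shared: int = 2
    cluster_window_bp: int = 10
    cluster_max_in_window: int = 3
    # expression
    min_row_sum: int = 10
    deg_fdr: float = 0.05
    deg_abs_log2fc: float = 1.0
    gsea_n_perm: int = 2000
    # methylation
    dms_abs_delta: float = 0.20
    dms_p: float = 0.05
    # integration
    dmg_min_abs_delta: float = 0.20
    promoter_upstream: int = 1500
    promoter_downstream: int = 500
    quadrant_rna_log2fc: float = 1.0
    quadrant_meth_log2fc: float = 0.1
    corr_r_max: float = -0.6
    corr_p_max: float = 0.1

    def __post_init__(self) -> None:
        if isinstance(self.simulation, dict):
            self.simulation = SimulationConfig(**self.simulation)
        # one seed drives every stage
        self.simulation = dataclasses.replace(self.simulation, seed=self.seed)

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        payload = yaml.safe_load(Path(path).read_text()) or {}
        return cls(**payload)

    def to_yaml(self, path) -> None:
        payload = dataclasses.asdict(self)
        Path(path).write_text(yaml.safe_dump(payload, sort_keys=True))


def _sha256(path) -> str:
    h = hashlib.sha256()
    h.update(Path(path).read_bytes())
    return h.hexdigest()


def _write_tsv(df: pd.DataFrame, path, index_label: str = "id") -> None:
    df.rename_axis(index_label).to_csv(path, sep="\t", float_format="%.8g")


def run_all(cfg: RunConfig) -> Dict:
    """Run every stage; returns (and writes) the run manifest."""
    out = Path(cfg.outdir)
    out.mkdir(parents=True, exist_ok=True)
    manifest: Dict = {
        "seed": cfg.seed,
        "thresholds": {
            "min_callers": cfg.min_callers,
            "min_samples_shared": cfg.min_samples_shared,
            "cluster_window_bp": cfg.cluster_window_bp,
            "cluster_max_in_window": cfg.cluster_max_in_window,
            "min_row_sum": cfg.min_row_sum,
            "deg_fdr": cfg.deg_fdr,
            "deg_abs_log2fc": cfg.deg_abs_log2fc,
            "dms_abs_delta": cfg.dms_abs_delta,
            "dms_p": cfg.dms_p,
            "promoter_window": [cfg.promoter_upstream, cfg.promoter_downstream],
            "quadrant": [cfg.quadrant_rna_log2fc, cfg.quadrant_meth_log2fc],
            "correlation": [cfg.corr_r_max, cfg.corr_p_max],
        },
        "stages": {},
    }

    def finish_stage(name: str, files: List[Path], counts: Dict) -> None:
        manifest["stages"][name] = {
            "outputs": {str(p.relative_to(out)): _sha256(p) for p in sorted(files)},
            "counts": counts,
        }
        logger.info("stage %s complete", name)

    # ------------------------------------------------------------- simulate
    try:
        bundle = simulate_study(cfg.simulation)
        sim_dir = out / "sim"
        paths = write_study(bundle, sim_dir)
        sim_files = sorted(p for p in sim_dir.rglob("*") if p.is_file())
        finish_stage(
            "simulate", sim_files,
            {"n_genes": int(len(bundle.annotation)), "n_cpg": int(len(bundle.beta)),
             "n_samples": int(len(bundle.design))},
        )
    except Exception as exc:  # pragma: no cover - abort path
        raise RuntimeError(f"stage 'simulate' failed: {exc}") from exc

    design = bundle.design
    reference = bundle.reference
    callable_mb = sum(len(s) for s in reference.values()) / 1e6

    # ------------------------------------------------------------ mutations
    try:
        vcf_map = mut_mod.discover_caller_vcfs(paths["vcf_dir"], cfg.simulation.callers)
        records = mut_mod.read_caller_vcfs(vcf_map)
        known = mut_mod.read_known_sites(paths["known_sites"])
        records, audit = mut_mod.apply_filter_chain(
            records, known, min_callers=cfg.min_callers,
            min_samples=cfg.min_samples_shared, window_bp=cfg.cluster_window_bp,
            max_in_window=cfg.cluster_max_in_window,
        )
        mut_dir = out / "mutations"
        mut_dir.mkdir(exist_ok=True)
        table = mut_mod.records_to_table(records)
        table.to_csv(mut_dir / "mutations.tsv", sep="\t", index=False)
        pd.DataFrame(audit).to_csv(mut_dir / "filter_audit.tsv", sep="\t", index=False)
        burdens = mut_mod.mutational_burden(records, callable_mb)
        burden_df = pd.DataFrame([dataclasses.asdict(b) for b in burdens])
        tests = []
        for tissue in ("normal", "tumor"):
            sub = design[design["tissue"] == tissue]
            res = mut_mod.burden_group_test(
                burdens, sub["treatment"].to_dict(), "HDM", "VEH"
            )
            tests.append({"tissue": tissue, "t": res.t, "df": res.df, "p": res.p})
        burden_df.to_csv(mut_dir / "burden.tsv", sep="\t", index=False)
        pd.DataFrame(tests).to_csv(mut_dir / "burden_tests.tsv", sep="\t", index=False)
        finish_stage(
            "mutations", list(mut_dir.glob("*.tsv")),
            {"n_records": int(len(records)),
             "n_pass": int((records["status"] == "pass").sum())},
        )
    except Exception as exc:
        raise RuntimeError(f"stage 'mutations' failed: {exc}") from exc

    # -------------------------------------------------------------- spectra
    try:
        passing = records[records["status"] == "pass"]
        spec_dir = out / "spectra"
        spec_dir.mkdir(exist_ok=True)
        spec_counts = {}
        for schema in ("SBS96", "DBS78", "ID83"):
            sm = spec_mod.build_spectrum(passing, reference, schema)
            sm.to_frame().to_csv(spec_dir / f"{schema.lower()}.tsv", sep="\t",
                                 index=False)
            spec_mod.pairwise_cosine_table(sm).to_csv(
                spec_dir / f"{schema.lower()}_cosine.tsv", sep="\t", index=False,
                float_format="%.8g",
            )
            spec_counts[schema] = int(sm.counts.sum())
        finish_stage("spectra", list(spec_dir.glob("*.tsv")), spec_counts)
    except Exception as exc:
        raise RuntimeError(f"stage 'spectra' failed: {exc}") from exc

    # ----------------------------------------------------------- expression
    try:
        expr_dir = out / "expression"
        expr_dir.mkdir(exist_ok=True)
        counts = bundle.counts
        tpm = bundle.tpm
        filtered = expr_mod.filter_low_counts(counts, cfg.min_row_sum)
        de_tables = {}
        for tissue in ("normal", "tumor"):
            de = expr_mod.nb_wald_de(filtered, design, tissue)
            de_tables[tissue] = de
            _write_tsv(de, expr_dir / f"de_{tissue}.tsv", "gene")
        log_tpm = np.log2(tpm + 1.0)
        gene_sets = bundle.truth.modules
        module_rows = []
        for tissue in ("normal", "tumor"):
            cols = design.index[design["tissue"] == tissue]
            for name, members in gene_sets.items():
                score = expr_mod.module_score(log_tpm[cols], members)
                for s, v in score.items():
                    module_rows.append(
                        {"tissue": tissue, "set": name, "sample": s, "score": v}
                    )
        pd.DataFrame(module_rows).to_csv(
            expr_dir / "module_scores.tsv", sep="\t", index=False, float_format="%.8g"
        )
        rng = np.random.default_rng([cfg.seed, 6])
        ranking = de_tables["normal"]["wald_z"]
        gsea = expr_mod.preranked_gsea_collection(
            ranking, gene_sets, n_perm=cfg.gsea_n_perm, rng=rng
        )
        _write_tsv(gsea, expr_dir / "gsea_normal.tsv", "set")
        scores = expr_mod.marker_deconvolution(log_tpm, bundle.truth.markers)
        _write_tsv(scores, expr_dir / "deconvolution_scores.tsv", "population")
        decon_tests = []
        for tissue in ("normal", "tumor"):
            t = expr_mod.deconvolution_group_test(scores, design, tissue)
            t.insert(0, "tissue", tissue)
            decon_tests.append(t)
        _write_tsv(pd.concat(decon_tests), expr_dir / "deconvolution_tests.tsv",
                   "population")
        finish_stage(
            "expression", list(expr_dir.glob("*.tsv")),
            {"n_genes_tested": int(len(filtered)),
             "n_deg_normal": int(de_tables["normal"]["is_deg"].sum()),
             "n_deg_tumor": int(de_tables["tumor"]["is_deg"].sum())},
        )
    except Exception as exc:
        raise RuntimeError(f"stage 'expression' failed: {exc}") from exc

    # ---------------------------------------------------------- methylation
    try:
        meth_dir = out / "methylation"
        meth_dir.mkdir(exist_ok=True)
        beta = bundle.beta
        coords = bundle.cpg_coords
        annotation = bundle.annotation
        promoter_map = integ_mod.build_promoter_map(
            annotation, {c: len(s) for c, s in reference.items()},
            upstream=cfg.promoter_upstream, downstream=cfg.promoter_downstream,
        )
        region_sets = {
            "promoters": promoter_map.reset_index().rename(columns={"gene": "name"})[
                ["chrom", "start", "end", "name"]
            ],
            "genes": annotation.reset_index().rename(columns={"gene": "name"})[
                ["chrom", "start", "end", "name"]
            ],
            "cpg_islands": bundle.cpg_islands,
            "tiles": bundle.tiles,
        }
        site_results = {}
        count_tables = {}
        for tissue in ("normal", "tumor"):
            sd = meth_mod.site_differential(beta, design, tissue)
            site_results[tissue] = sd
            _write_tsv(sd.join(coords[["chrom", "pos"]]),
                       meth_dir / f"sites_{tissue}.tsv", "site")
            count_tables[f"sites/{tissue}"] = sd
        for name, regions in region_sets.items():
            region_beta = meth_mod.aggregate_regions(beta, coords, regions)
            for tissue in ("normal", "tumor"):
                rd = meth_mod.region_differential(region_beta, design, tissue)
                _write_tsv(rd, meth_dir / f"{name}_{tissue}.tsv", "region")
                count_tables[f"{name}/{tissue}"] = rd
        summary = meth_mod.count_dms(count_tables)
        summary.to_csv(meth_dir / "dms_counts.tsv", sep="\t", index=False)
        finish_stage(
            "methylation", list(meth_dir.glob("*.tsv")),
            {"n_sites": int(len(beta)),
             "n_dms_normal": int((site_results["normal"]["call"] != "none").sum())},
        )
    except Exception as exc:
        raise RuntimeError(f"stage 'methylation' failed: {exc}") from exc

    # ------------------------------------------------------------ integrate
    try:
        integ_dir = out / "integration"
        integ_dir.mkdir(exist_ok=True)
        tmm = expr_mod.tmm_factors(filtered)
        lib = filtered.sum(axis=0)
        norm_expr = np.log2(filtered / (lib * tmm) * 1e6 + 1.0)
        reports = {}
        for tissue in ("normal", "tumor"):
            dmgs = integ_mod.derive_dmgs(
                site_results[tissue], coords, promoter_map, p_max=cfg.dms_p,
                min_abs_delta=cfg.dmg_min_abs_delta,
            )
            promoter_beta = integ_mod.promoter_beta_from_sites(
                beta, site_results[tissue], coords, promoter_map, p_max=cfg.dms_p,
                min_abs_delta=cfg.dmg_min_abs_delta,
            )
            rec = integ_mod.classify_quadrants(
                dmgs, de_tables[tissue],
                rna_threshold=cfg.quadrant_rna_log2fc,
                meth_threshold=cfg.quadrant_meth_log2fc,
            )
            hdm_samples = design.index[
                (design["tissue"] == tissue) & (design["treatment"] == "HDM")
            ]
            rec = integ_mod.inverse_correlation_filter(
                rec, promoter_beta, norm_expr, hdm_samples,
                r_max=cfg.corr_r_max, p_max=cfg.corr_p_max,
            )
            _write_tsv(rec, integ_dir / f"integration_{tissue}.tsv", "gene")
            reports[tissue] = integ_mod.integration_report(
                rec, n_dmg=len(dmgs),
                n_deg=int(de_tables[tissue]["is_deg"].sum()),
            )
        (integ_dir / "integration_summary.json").write_text(
            json.dumps(reports, sort_keys=True, indent=1)
        )
        finish_stage(
            "integrate",
            list(integ_dir.glob("*.tsv")) + [integ_dir / "integration_summary.json"],
            {"n_epi_control_normal": reports["normal"]["n_epi_control"],
             "n_epi_control_tumor": reports["tumor"]["n_epi_control"]},
        )
    except Exception as exc:
        raise RuntimeError(f"stage 'integrate' failed: {exc}") from exc

    manifest["n_stages_completed"] = len(manifest["stages"])
    (out / "manifest.json").write_text(json.dumps(manifest, sort_keys=True, indent=1))
    return manifest
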