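"""Promoter methylation-expression integration.

Two steps mirror the analysis contract: (1) significant promoter CpGs are
assigned to genes by promoter overlap and intersected with the DE table,
then classified into five quadrant categories from the paired effect sizes
(|log2FC| >= 1 for expression, |log2FC| >= 0.1 for methylation); (2) a
per-gene Pearson inverse-correlation screen across the treated samples
(r <= -0.6 and p < 0.1, boundary semantics exactly as written) yields the
"epigenetically controlled" list: hypo-up genes are called activated,
hyper-down genes repressed.
"""

from __future__ import annotations

import logging
from typing import Dict, Iterable, List, Mapping, Optional, Tuple

import numpy as np
import pandas as pd

from .stats import pearson_corr_test

logger = logging.getLogger(__name__)

__all__ = [
    "PROMOTER_UP",
    "PROMOTER_DOWN",
    "RNA_ABS_LOG2FC",
    "METH_ABS_LOG2FC",
    "R_MAX",
    "P_MAX",
    "build_promoter_map",
    "derive_dmgs",
    "classify_quadrants",
    "inverse_correlation_filter",
    "integration_report",
]

PROMOTER_UP = 1500   # bp upstream of the TSS (transcription orientation)
PROMOTER_DOWN = 500  # bp downstream of the TSS
RNA_ABS_LOG2FC = 1.0
METH_ABS_LOG2FC = 0.1
R_MAX = -0.6
P_MAX = 0.1

QUADRANTS = ("hyper_up", "hyper_down", "hypo_up", "hypo_down", "low_effect")


def build_promoter_map(
    annotation: pd.DataFrame,
    chrom_sizes: Optional[Mapping[str, int]] = None,
    upstream: int = PROMOTER_UP,
    downstream: int = PROMOTER_DOWN,
) -> pd.DataFrame:
    """Promoter intervals, 1.5 kb upstream / 0.5 kb downstream of the TSS.

    ``annotation`` is indexed by gene id with columns chrom, strand, tss
    (0-based position of the first transcribed base).  Plus-strand TSS t
    maps to [t-1500, t+500); minus strand mirrors the window in
    transcription orientation: [t-499, t+1501).  Intervals are clipped to
    chromosome bounds with a warning.
    """
    rows = []
    n_clipped = 0
    for gene, row in annotation.iterrows():
        strand = row["strand"]
        t = int(row["tss"])
        if strand == "+":
            start, end = t - upstream, t + downstream
        elif strand == "-":
            start, end = t - downstream + 1, t + upstream + 1
        else:
            raise ValueError(f"unknown strand {strand!r} for gene {gene}")
        if chrom_sizes is not None:
            size = chrom_sizes[row["chrom"]]
            c_start, c_end = max(0, start), min(size, end)
            if (c_start, c_end) != (start, end):
                n_clipped += 1
            start, end = c_start, c_end
        elif start < 0:
            n_clipped += 1
            start = 0
        rows.append(
            {"gene": gene, "chrom": row["chrom"], "start": start, "end": end,
             "strand": strand}
        )
    if n_clipped:
        logger.warning("%d promoter intervals clipped to chromosome bounds", n_clipped)
    return pd.DataFrame(rows).set_index("gene")


def derive_dmgs(
    site_diff: pd.DataFrame,
    site_coords: pd.DataFrame,
    promoter_map: pd.DataFrame,
    p_max: float = 0.05,
    min_abs_delta: float = 0.20,
) -> pd.DataFrame:
    """Gene-level promoter methylation effects from differential CpGs.

    Differentially methylated CpGs (p < ``p_max`` and |delta beta| >=
    ``min_abs_delta``, the site-level call thresholds) that fall inside a
    promoter interval are assigned to that promoter's gene (a CpG in several
    overlapping promoters is assigned to each).  The per-gene effect is the
    mean of the member sites' mean_quot_log2; genes with >= 1 assigned CpG
    form the DMG set.  Set ``min_abs_delta=0`` to gate on significance only;
    with the default n = 3 design that admits enough chance-significant CpGs
    to contaminate the downstream correlation screen.
    """
    sig = site_diff[
        (site_diff["p"] < p_max)
        & (site_diff["delta_beta"].abs() >= min_abs_delta)
    ]
    if sig.empty:
        return pd.DataFrame(columns=["meth_log2fc", "n_sites", "mean_delta_beta"])
    coords = site_coords.loc[sig.index]
    assigned: Dict[str, List] = {}
    by_chrom = {c: g.sort_values("pos") for c, g in coords.groupby("chrom")}
    for gene, prom in promoter_map.iterrows():
        grp = by_chrom.get(prom["chrom"])
        if grp is None:
            continue
        pos = grp["pos"].to_numpy()
        lo = np.searchsorted(pos, prom["start"], side="left")
        hi = np.searchsorted(pos, prom["end"], side="left")
        if hi > lo:
            assigned[gene] = list(grp.index[lo:hi])
    rows = []
    for gene, site_ids in assigned.items():
        sub = sig.loc[site_ids]
        rows.append(
            {
                "gene": gene,
                "meth_log2fc": float(sub["mean_quot_log2"].mean()),
                "n_sites": len(site_ids),
                "mean_delta_beta": float(sub["delta_beta"].mean()),
            }
        )
    if not rows:
        return pd.DataFrame(columns=["meth_log2fc", "n_sites", "mean_delta_beta"])
    return pd.DataFrame(rows).set_index("gene").sort_index()


def promoter_beta_from_sites(
    beta: pd.DataFrame,
    site_diff: pd.DataFrame,
    site_coords: pd.DataFrame,
    promoter_map: pd.DataFrame,
    p_max: float = 0.05,
    min_abs_delta: float = 0.20,
) -> pd.DataFrame:
    """Gene x sample promoter methylation from differential promoter CpGs.

    The correlation screen pairs each DMG's promoter methylation with its
    expression; the promoter value is the per-sample mean beta over the same
    differential CpGs that defined the DMG (see :func:`derive_dmgs`), so
    unrelated CpGs from overlapping neighbor promoters do not dilute the
    signal.
    """
    sig = site_diff[
        (site_diff["p"] < p_max)
        & (site_diff["delta_beta"].abs() >= min_abs_delta)
    ]
    if sig.empty:
        return pd.DataFrame(columns=beta.columns)
    coords = site_coords.loc[sig.index]
    by_chrom = {c: g.sort_values("pos") for c, g in coords.groupby("chrom")}
    rows = {}
    for gene, prom in promoter_map.iterrows():
        grp = by_chrom.get(prom["chrom"])
        if grp is None:
            continue
        pos = grp["pos"].to_numpy()
        lo = np.searchsorted(pos, prom["start"], side="left")
        hi = np.searchsorted(pos, prom["end"], side="left")
        if hi > lo:
            rows[gene] = beta.loc[grp.index[lo:hi]].mean(axis=0)
    if not rows:
        return pd.DataFrame(columns=beta.columns)
    return pd.DataFrame(rows).T[beta.columns]


def classify_quadrants(
    dmgs: pd.DataFrame,
    de: pd.DataFrame,
    rna_threshold: float = RNA_ABS_LOG2FC,
    meth_threshold: float = METH_ABS_LOG2FC,
) -> pd.DataFrame:
    """Five-way quadrant classification of DMG genes with expression results.

    Genes missing from the DE table are skipped with a log message.  A gene
    passing both effect-size thresholds is labeled hyper_up / hyper_down /
    hypo_up / hypo_down by the signs of its effects; otherwise low_effect.
    """
    genes = [g for g in dmgs.index if g in de.index]
    skipped = len(dmgs) - len(genes)
    if skipped:
        logger.info("%d DMG genes missing from the DE table were skipped", skipped)
    rows = []
    for gene in genes:
        rna = float(de.loc[gene, "log2fc"])
        meth = float(dmgs.loc[gene, "meth_log2fc"])
        if abs(rna) >= rna_threshold and abs(meth) >= meth_threshold:
            quadrant = ("hyper_" if meth > 0 else "hypo_") + ("up" if rna > 0 else "down")
        else:
            quadrant = "low_effect"
        rows.append(
            {
                "gene": gene,
                "rna_log2fc": rna,
                "meth_log2fc": meth,
                "rna_fdr": float(de.loc[gene, "fdr"]),
                "is_deg": bool(de.loc[gene, "is_deg"]),
                "quadrant": quadrant,
            }
        )
    cols = ["rna_log2fc", "meth_log2fc", "rna_fdr", "is_deg", "quadrant"]
    if not rows:
        return pd.DataFrame(columns=cols)
    return pd.DataFrame(rows).set_index("gene")[cols]


def inverse_correlation_filter(
    records: pd.DataFrame,
    promoter_beta: pd.DataFrame,
    expr: pd.DataFrame,
    samples: Iterable[str],
    r_max: float = R_MAX,
    p_max: float = P_MAX,
) -> pd.DataFrame:
    """Pearson anti-correlation screen over candidate genes.

    ``records`` is the quadrant table; only hyper_down / hypo_up genes that
    are DEGs are candidates.  For each candidate, promoter beta and
    expression are correlated across ``samples`` (the treated group, usually
    n = 3).  Retained iff r <= r_max and p < p_max; hyper_down ->
    "repressed", hypo_up -> "activated".  Genes with a constant vector are
    excluded with a log message.  Adds pearson_r / pearson_p / epi_control
    columns to a copy of ``records``.
    """
    samples = list(samples)
    if len(samples) < 3:
        raise ValueError("inverse-correlation screen needs >= 3 shared samples")
    out = records.copy()
    out["pearson_r"] = np.nan
    out["pearson_p"] = np.nan
    out["epi_control"] = "none"
    candidates = out.index[
        out["quadrant"].isin(["hyper_down", "hypo_up"]) & out["is_deg"]
    ]
    for gene in candidates:
        if gene not in promoter_beta.index or gene not in expr.index:
            logger.info("candidate %s missing from a matrix; excluded", gene)
            continue
        b = promoter_beta.loc[gene, samples].to_numpy(dtype=float)
        e = expr.loc[gene, samples].to_numpy(dtype=float)
        if np.any(np.isnan(b)) or np.any(np.isnan(e)):
            logger.info("candidate %s has missing values; excluded", gene)
            continue
        try:
            r, p = pearson_corr_test(b, e)
        except ValueError:
            logger.info("candidate %s has a constant vector; excluded", gene)
            continue
        out.loc[gene, "pearson_r"] = r
        out.loc[gene, "pearson_p"] = p
        if r <= r_max and p < p_max:
            out.loc[gene, "epi_control"] = (
                "repressed" if out.loc[gene, "quadrant"] == "hyper_down" else "activated"
            )
    return out


def integration_report(records: pd.DataFrame, n_dmg: int, n_deg: int) -> Dict:
    """Per-quadrant counts, overlap counts, and the epi-control gene lists."""
    quad_counts = {q: int((records.get("quadrant") == q).sum()) for q in QUADRANTS}
    epi = records[records.get("epi_control", pd.Series(dtype=object)) != "none"] \
        if len(records) else records
    activated = sorted(epi.index[epi["epi_control"] == "activated"]) if len(epi) else []
    repressed = sorted(epi.index[epi["epi_control"] == "repressed"]) if len(epi) else []
    return {
        "quadrant_counts": quad_counts,
        "n_classified": int(len(records)),
        "n_dmg": int(n_dmg),
        "n_deg": int(n_deg),
        "n_dmg_and_deg": int(records["is_deg"].sum()) if len(records) else 0,
        "epi_activated": activated,
        "epi_repressed": repressed,
        "n_epi_control": len(activated) + len(repressed),
    }
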