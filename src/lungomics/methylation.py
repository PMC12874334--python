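"""Site- and region-level differential DNA methylation.

Effect sizes are reported on the beta scale (group-mean difference) plus a
stabilized log2 mean-quotient; significance testing is done on M-values
(logit2 of beta), which are closer to homoscedastic.  Hyper/hypo calls use
|delta beta| >= 0.2 (inclusive) and p < 0.05.
"""

from __future__ import annotations

import logging
from typing import Dict, Iterable, Mapping, Optional, Tuple

import numpy as np
import pandas as pd

from .stats import welch_t_test_rows

logger = logging.getLogger(__name__)

__all__ = [
    "BETA_CLAMP",
    "DMS_ABS_DELTA",
    "DMS_P",
    "beta_to_m",
    "m_to_beta",
    "clamp_beta",
    "site_differential",
    "aggregate_regions",
    "region_differential",
    "count_dms",
]

BETA_CLAMP = 1e-6
DMS_ABS_DELTA = 0.20
DMS_P = 0.05
MEAN_QUOT_EPS = 0.01


def clamp_beta(beta):
    """Clamp beta values into [1e-6, 1 - 1e-6] (done once on load)."""
    return np.clip(np.asarray(beta, dtype=float), BETA_CLAMP, 1.0 - BETA_CLAMP)


def beta_to_m(beta):
    """M = log2(beta / (1 - beta)); strictly increasing bijection on (0,1)."""
    beta = np.asarray(beta, dtype=float)
    if np.any(beta <= 0) or np.any(beta >= 1):
        raise ValueError("beta values must lie strictly in (0, 1)")
    return np.log2(beta / (1.0 - beta))


def m_to_beta(m):
    """Inverse of :func:`beta_to_m`."""
    m = np.asarray(m, dtype=float)
    x = np.exp2(m)
    return x / (1.0 + x)


def _differential(
    values: pd.DataFrame,
    design: pd.DataFrame,
    tissue: str,
    group_a: str,
    group_b: str,
    eps: float = MEAN_QUOT_EPS,
) -> pd.DataFrame:
    sub = design[design["tissue"] == tissue]
    a_cols = sub.index[sub["treatment"] == group_a].tolist()
    b_cols = sub.index[sub["treatment"] == group_b].tolist()
    if len(a_cols) < 2 or len(b_cols) < 2:
        raise ValueError("each group needs >= 2 samples")
    beta_a = clamp_beta(values[a_cols].to_numpy())
    beta_b = clamp_beta(values[b_cols].to_numpy())
    mean_a = beta_a.mean(axis=1)
    mean_b = beta_b.mean(axis=1)
    delta = mean_a - mean_b
    mean_quot_log2 = np.log2((mean_a + eps) / (mean_b + eps))
    _, _, p = welch_t_test_rows(beta_to_m(beta_a), beta_to_m(beta_b))
    call = np.where(
        (delta >= DMS_ABS_DELTA) & (p < DMS_P),
        "hyper",
        np.where((delta <= -DMS_ABS_DELTA) & (p < DMS_P), "hypo", "none"),
    )
    return pd.DataFrame(
        {
            "mean_beta_a": mean_a,
            "mean_beta_b": mean_b,
            "delta_beta": delta,
            "mean_quot_log2": mean_quot_log2,
            "p": p,
            "call": call,
        },
        index=values.index,
    )


def site_differential(
    beta: pd.DataFrame,
    design: pd.DataFrame,
    tissue: str,
    group_a: str = "HDM",
    group_b: str = "VEH",
) -> pd.DataFrame:
    """Per-CpG differential methylation for one tissue's treatment contrast.

    ``beta`` is a site x sample matrix whose index carries site ids; the
    caller keeps site coordinates alongside.  Returns delta beta (A - B),
    the stabilized log2 mean quotient, the M-value Welch p, and the
    hyper/hypo/none call.
    """
    return _differential(beta, design, tissue, group_a, group_b)


def aggregate_regions(
    beta: pd.DataFrame,
    sites: pd.DataFrame,
    regions: pd.DataFrame,
) -> pd.DataFrame:
    """Region x sample beta matrix: unweighted mean of member sites.

    ``sites`` maps the beta index to coordinates (columns chrom, pos);
    ``regions`` has columns chrom, start, end, name with half-open
    [start, end) intervals.  Regions without any site are dropped (count
    logged).
    """
    if (regions["end"] <= regions["start"]).any():
        bad = regions[regions["end"] <= regions["start"]].iloc[0]
        raise ValueError(f"malformed region {bad['name']}: end <= start")
    site_tab = sites.loc[beta.index]
    out_rows = {}
    by_chrom = {
        chrom: grp.sort_values("pos") for chrom, grp in site_tab.groupby("chrom")
    }
    n_empty = 0
    for row in regions.itertuples(index=False):
        grp = by_chrom.get(row.chrom)
        if grp is None:
            n_empty += 1
            continue
        pos = grp["pos"].to_numpy()
        lo = np.searchsorted(pos, row.start, side="left")
        hi = np.searchsorted(pos, row.end, side="left")
        if hi <= lo:
            n_empty += 1
            continue
        member_idx = grp.index[lo:hi]
        out_rows[row.name] = beta.loc[member_idx].mean(axis=0)
    if n_empty:
        logger.info("%d regions had no CpG site and were dropped", n_empty)
    if not out_rows:
        return pd.DataFrame(columns=beta.columns)
    return pd.DataFrame(out_rows).T[beta.columns]


def region_differential(
    region_beta: pd.DataFrame,
    design: pd.DataFrame,
    tissue: str,
    group_a: str = "HDM",
    group_b: str = "VEH",
) -> pd.DataFrame:
    """Site-level differential applied to a region-aggregated matrix."""
    return _differential(region_beta, design, tissue, group_a, group_b)


def count_dms(results: Mapping[str, pd.DataFrame]) -> pd.DataFrame:
    """Hyper/hypo counts per feature class.

    ``results`` maps a feature-class label (e.g. "promoters/normal") to its
    differential table.  Returns a table with n_hyper, n_hypo, n_tested.
    """
    rows = []
    for label, table in results.items():
        rows.append(
            {
                "feature_class": label,
                "n_hyper": int((table["call"] == "hyper").sum()),
                "n_hypo": int((table["call"] == "hypo").sum()),
                "n_tested": int(len(table)),
            }
        )
    return pd.DataFrame(rows, columns=["feature_class", "n_hyper", "n_hypo", "n_tested"])
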