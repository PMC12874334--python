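"""Bulk expression analysis.

Count filtering, median-of-ratios and TMM normalization, a simplified
per-gene negative-binomial Wald differential-expression test, curated
gene-module z-scoring, preranked gene-set enrichment, and marker-based
microenvironment scores.

The DE stage is a deliberate simplification of the full count-model
machinery it stands in for: size factors by median-of-ratios, a per-gene
method-of-moments dispersion (floored at 1e-8), and a Wald statistic
z = log2FC / SE.  There is no dispersion shrinkage, no outlier replacement
and no independent filtering.  Two-sided p-values use a t reference
distribution with n_A + n_B - 2 degrees of freedom as a small-sample
correction (a plain normal reference is anti-conservative at n = 3).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Dict, Iterable, List, Mapping, Optional, Sequence, Tuple

import numpy as np
import pandas as pd
from scipy import stats as _sps

from .stats import bh_adjust, welch_t_test

logger = logging.getLogger(__name__)

__all__ = [
    "filter_low_counts",
    "size_factors_median_of_ratios",
    "tmm_factors",
    "nb_wald_de",
    "module_score",
    "gsea_es",
    "preranked_gsea",
    "preranked_gsea_collection",
    "marker_deconvolution",
    "deconvolution_group_test",
    "GseaResult",
]

DEG_FDR = 0.05
DEG_ABS_LOG2FC = 1.0


def filter_low_counts(counts: pd.DataFrame, min_row_sum: int = 10) -> pd.DataFrame:
    """Remove genes whose total count is below ``min_row_sum``."""
    kept = counts[counts.sum(axis=1) >= min_row_sum]
    if kept.empty:
        logger.warning("all genes removed by the low-count filter")
    return kept


def size_factors_median_of_ratios(counts: pd.DataFrame) -> pd.Series:
    """Median-of-ratios size factors.

    For genes expressed in every sample, s_j = median_g of
    count_gj / geometric_mean_g(count).
    """
    mat = counts.to_numpy(dtype=float)
    all_pos = (mat > 0).all(axis=1)
    if not all_pos.any():
        raise ValueError("no gene has nonzero counts in all samples")
    sub = mat[all_pos]
    log_geo = np.mean(np.log(sub), axis=1, keepdims=True)
    ratios = sub / np.exp(log_geo)
    factors = np.median(ratios, axis=0)
    return pd.Series(factors, index=counts.columns, name="size_factor")


def tmm_factors(counts: pd.DataFrame, ref_sample: Optional[str] = None,
                m_trim: float = 0.30, a_trim: float = 0.05) -> pd.Series:
    """Trimmed-mean-of-M-values scaling factors.

    M-values (log2 expression ratio against a reference sample, after
    library-size division) are doubly trimmed (30 % on M, 5 % on A by
    default); the factor is 2**mean(trimmed M).  Factors are normalized to
    geometric mean 1.
    """
    if counts.shape[1] < 2:
        raise ValueError("TMM requires >= 2 samples")
    mat = counts.to_numpy(dtype=float)
    lib = mat.sum(axis=0)
    if np.any(lib <= 0):
        raise ValueError("sample with zero library size")
    frac = mat / lib

    if ref_sample is None:
        # reference: sample whose upper-quartile fraction is closest to the mean
        uq = np.array([np.quantile(frac[:, j][mat[:, j] > 0], 0.75)
                       for j in range(mat.shape[1])])
        ref_idx = int(np.argmin(np.abs(uq - uq.mean())))
    else:
        ref_idx = list(counts.columns).index(ref_sample)

    factors = np.ones(mat.shape[1])
    fr = frac[:, ref_idx]
    for j in range(mat.shape[1]):
        if j == ref_idx:
            continue
        fj = frac[:, j]
        ok = (fj > 0) & (fr > 0)
        if ok.sum() < 2:
            raise ValueError(f"degenerate sample {counts.columns[j]!r} for TMM")
        M = np.log2(fj[ok] / fr[ok])
        A = 0.5 * np.log2(fj[ok] * fr[ok])
        m_lo, m_hi = np.quantile(M, [m_trim, 1 - m_trim])
        a_lo, a_hi = np.quantile(A, [a_trim, 1 - a_trim])
        keep = (M >= m_lo) & (M <= m_hi) & (A >= a_lo) & (A <= a_hi)
        if not keep.any():
            keep = np.ones_like(M, dtype=bool)
        factors[j] = 2.0 ** np.mean(M[keep])
    factors = factors / np.exp(np.mean(np.log(factors)))
    return pd.Series(factors, index=counts.columns, name="tmm_factor")


def _mom_dispersion(q: np.ndarray, groups: Sequence[np.ndarray],
                    inv_s: np.ndarray) -> np.ndarray:
    """Pooled within-group method-of-moments NB dispersion per gene.

    For normalized counts q = K/s, Var(q) = mu * E[1/s] + alpha * mu^2;
    alpha is solved from the pooled within-group sample variance.
    """
    n_genes = q.shape[0]
    num = np.zeros(n_genes)
    den = 0
    pooled_var = np.zeros(n_genes)
    mu_terms = np.zeros(n_genes)
    total_df = 0
    for idx in groups:
        sub = q[:, idx]
        n = len(idx)
        mu = sub.mean(axis=1)
        var = sub.var(axis=1, ddof=1)
        pooled_var += var * (n - 1)
        mu_terms += (mu * np.mean(inv_s[idx])) * (n - 1)
        num += mu**2 * (n - 1)
        total_df += n - 1
    pooled_var /= total_df
    mu_terms /= total_df
    mu2 = num / total_df
    with np.errstate(divide="ignore", invalid="ignore"):
        alpha = (pooled_var - mu_terms) / mu2
    alpha = np.where(np.isfinite(alpha), alpha, 0.0)
    return np.maximum(alpha, 1e-8)


def nb_wald_de(
    counts: pd.DataFrame,
    design: pd.DataFrame,
    tissue: str,
    group_a: str = "HDM",
    group_b: str = "VEH",
    size_factors: Optional[pd.Series] = None,
    pseudo: float = 0.5,
) -> pd.DataFrame:
    """Two-group negative-binomial Wald test (treatment within one tissue).

    Parameters
    ----------
    counts : filtered integer counts, genes x samples.
    design : per-sample table with ``tissue`` and ``treatment`` columns,
        indexed by sample id.
    tissue : which tissue's samples enter the contrast.
    size_factors : optional precomputed factors; median-of-ratios otherwise.

    Returns
    -------
    DataFrame indexed by gene: baseMean, log2fc, wald_z, p, fdr, is_deg,
    direction.  DEG flag: fdr < 0.05 and |log2fc| >= 1.
    """
    sub_design = design[design["tissue"] == tissue]
    a_samples = sub_design.index[sub_design["treatment"] == group_a].tolist()
    b_samples = sub_design.index[sub_design["treatment"] == group_b].tolist()
    if len(a_samples) < 2 or len(b_samples) < 2:
        raise ValueError("each contrast level needs >= 2 samples")
    used = a_samples + b_samples
    sub = counts[used]
    if size_factors is None:
        size_factors = size_factors_median_of_ratios(sub)
    s = size_factors.loc[used].to_numpy(dtype=float)
    mat = sub.to_numpy(dtype=float)
    q = mat / s
    ia = np.arange(len(a_samples))
    ib = np.arange(len(a_samples), len(used))
    inv_s = 1.0 / s

    alpha = _mom_dispersion(q, [ia, ib], inv_s)
    ma = q[:, ia].mean(axis=1)
    mb = q[:, ib].mean(axis=1)
    base_mean = q.mean(axis=1)

    ma_p = ma + pseudo
    mb_p = mb + pseudo
    log2fc = np.log2(ma_p / mb_p)
    # delta-method variance of log2 group means under the NB model
    var_ma = np.sum(ma_p[:, None] * inv_s[None, ia] + alpha[:, None] * ma_p[:, None] ** 2,
                    axis=1) / len(ia) ** 2
    var_mb = np.sum(mb_p[:, None] * inv_s[None, ib] + alpha[:, None] * mb_p[:, None] ** 2,
                    axis=1) / len(ib) ** 2
    ln2sq = np.log(2.0) ** 2
    se = np.sqrt(var_ma / ma_p**2 + var_mb / mb_p**2) / np.log(2.0)
    with np.errstate(divide="ignore", invalid="ignore"):
        z = log2fc / se
    z = np.where(se == 0, 0.0, z)
    dof = len(used) - 2
    p = 2.0 * _sps.t.sf(np.abs(z), dof)
    fdr = bh_adjust(p).adjusted_p
    is_deg = (fdr < DEG_FDR) & (np.abs(log2fc) >= DEG_ABS_LOG2FC)
    direction = np.where(~is_deg, "none", np.where(log2fc > 0, "up", "down"))

    return pd.DataFrame(
        {
            "baseMean": base_mean,
            "log2fc": log2fc,
            "wald_z": z,
            "p": p,
            "fdr": fdr,
            "is_deg": is_deg,
            "direction": direction,
        },
        index=counts.index,
    )


def module_score(log_expr: pd.DataFrame, members: Iterable[str]) -> pd.Series:
    """Mean per-gene z-score over a gene set, per sample.

    Each member gene is z-scored across the samples in ``log_expr`` (the
    scoring scope); constant genes contribute z = 0.  Missing members are
    logged.
    """
    members = list(dict.fromkeys(members))
    present = [g for g in members if g in log_expr.index]
    missing = [g for g in members if g not in log_expr.index]
    if missing:
        logger.info("module members absent from matrix: %s", ",".join(missing))
    if not present:
        raise ValueError("no gene-set member present in the expression matrix")
    sub = log_expr.loc[present].to_numpy(dtype=float)
    mu = sub.mean(axis=1, keepdims=True)
    sd = sub.std(axis=1, ddof=1, keepdims=True)
    with np.errstate(divide="ignore", invalid="ignore"):
        z = (sub - mu) / sd
    z = np.where(sd == 0, 0.0, z)
    return pd.Series(z.mean(axis=0), index=log_expr.columns, name="module_score")


# ---------------------------------------------------------------------------
# preranked GSEA
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class GseaResult:
    name: str
    es: float
    nes: float
    p: float
    fdr: float
    leading_edge: Tuple[str, ...]
    size: int


def gsea_es(stats_sorted: np.ndarray, hits: np.ndarray) -> Tuple[float, int]:
    """Weighted Kolmogorov-Smirnov enrichment score.

    ``stats_sorted`` must be ranked high-to-low; ``hits`` is a boolean
    membership mask in the same order.  Weight is |stat|.  Returns (ES,
    index of the extreme point).
    """
    n = stats_sorted.size
    nh = int(hits.sum())
    if nh == 0 or nh == n:
        raise ValueError("gene set must be a non-empty proper subset of the ranking")
    w = np.abs(stats_sorted) * hits
    total = w.sum()
    if total == 0:
        # all member stats are zero: fall back to unweighted hits
        w = hits.astype(float)
        total = float(nh)
    p_hit = np.cumsum(w) / total
    p_miss = np.cumsum(~hits) / (n - nh)
    running = p_hit - p_miss
    i_max = int(np.argmax(running))
    i_min = int(np.argmin(running))
    # extreme deviation; exact-magnitude ties resolve to the positive side
    if running[i_max] >= -running[i_min]:
        return float(running[i_max]), i_max
    return float(running[i_min]), i_min


def preranked_gsea(
    ranked: pd.Series,
    members: Iterable[str],
    n_perm: int = 10_000,
    rng: Optional[np.random.Generator] = None,
    name: str = "set",
) -> GseaResult:
    """Preranked GSEA for one gene set with gene-label permutations.

    ``ranked`` maps gene -> ranking statistic (no duplicate genes).  NES is
    ES normalized by the mean magnitude of same-sign permutation scores;
    the permutation p-value is one-sided within the matching sign class.
    """
    if ranked.index.duplicated().any():
        raise ValueError("ranking contains duplicate genes")
    if rng is None:
        rng = np.random.default_rng()
    order = np.argsort(-ranked.to_numpy(), kind="mergesort")
    genes = ranked.index.to_numpy()[order]
    stats_sorted = ranked.to_numpy()[order]
    member_set = set(members) & set(genes)
    if not member_set:
        raise ValueError("gene set does not intersect the ranking")
    hits = np.isin(genes, list(member_set))
    es, peak = gsea_es(stats_sorted, hits)
    nh = int(hits.sum())

    perm_es = np.empty(n_perm)
    n = genes.size
    for k in range(n_perm):
        idx = rng.choice(n, size=nh, replace=False)
        ph = np.zeros(n, dtype=bool)
        ph[idx] = True
        perm_es[k], _ = gsea_es(stats_sorted, ph)

    same_sign = perm_es >= 0 if es >= 0 else perm_es < 0
    n_same = int(same_sign.sum())
    if n_same == 0:
        nes = np.sign(es) * np.inf
        p = 1.0 / (n_perm + 1)
    else:
        mean_mag = float(np.mean(np.abs(perm_es[same_sign])))
        nes = es / mean_mag if mean_mag > 0 else 0.0
        p = (1 + int(np.sum(np.abs(perm_es[same_sign]) >= abs(es)))) / (n_same + 1)

    if es >= 0:
        le = tuple(genes[: peak + 1][hits[: peak + 1]])
    else:
        le = tuple(genes[peak:][hits[peak:]])
    return GseaResult(name=name, es=es, nes=float(nes), p=float(p),
                      fdr=np.nan, leading_edge=le, size=nh)


def preranked_gsea_collection(
    ranked: pd.Series,
    gene_sets: Mapping[str, Iterable[str]],
    n_perm: int = 10_000,
    rng: Optional[np.random.Generator] = None,
) -> pd.DataFrame:
    """Run preranked GSEA over several sets; BH-FDR across sets."""
    results = [
        preranked_gsea(ranked, members, n_perm=n_perm, rng=rng, name=nm)
        for nm, members in gene_sets.items()
    ]
    fdr = bh_adjust([r.p for r in results]).adjusted_p
    return pd.DataFrame(
        {
            "set": [r.name for r in results],
            "size": [r.size for r in results],
            "es": [r.es for r in results],
            "nes": [r.nes for r in results],
            "p": [r.p for r in results],
            "fdr": fdr,
            "leading_edge": [",".join(r.leading_edge) for r in results],
        }
    ).set_index("set")


# ---------------------------------------------------------------------------
# marker-based deconvolution
# ---------------------------------------------------------------------------

def marker_deconvolution(
    log_expr: pd.DataFrame, marker_sets: Mapping[str, Iterable[str]]
) -> pd.DataFrame:
    """Population x sample scores: mean log2(TPM+1) over each marker set.

    Populations with no marker present in the matrix are omitted with a
    warning.
    """
    rows = {}
    for pop, markers in marker_sets.items():
        present = [g for g in dict.fromkeys(markers) if g in log_expr.index]
        if not present:
            logger.warning("population %r has no marker in the matrix; omitted", pop)
            continue
        rows[pop] = log_expr.loc[present].mean(axis=0)
    if not rows:
        raise ValueError("no marker set had any member present")
    return pd.DataFrame(rows).T


def deconvolution_group_test(
    scores: pd.DataFrame,
    design: pd.DataFrame,
    tissue: str,
    group_a: str = "HDM",
    group_b: str = "VEH",
) -> pd.DataFrame:
    """Welch's t-test per population between treatment groups, BH across
    populations."""
    sub = design[design["tissue"] == tissue]
    a_cols = sub.index[sub["treatment"] == group_a]
    b_cols = sub.index[sub["treatment"] == group_b]
    stats = [
        welch_t_test(scores.loc[pop, a_cols], scores.loc[pop, b_cols])
        for pop in scores.index
    ]
    fdr = bh_adjust([s.p for s in stats]).adjusted_p
    return pd.DataFrame(
        {
            "t": [s.t for s in stats],
            "p": [s.p for s in stats],
            "fdr": fdr,
            "mean_a": scores[a_cols].mean(axis=1),
            "mean_b": scores[b_cols].mean(axis=1),
        },
        index=scores.index,
    )
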