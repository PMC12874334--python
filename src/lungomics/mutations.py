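"""Ensemble somatic-mutation consolidation and post-calling filters.

Per-sample candidate variants from several callers are merged by
(chrom, pos, ref, alt) key and then pushed through a fixed filter chain:

    consensus (>= min_callers) -> known-site removal -> shared-across-samples
    removal -> clustered-mutation removal

Each filter only demotes ``pass`` records to an explicit dropped status; no
record is ever created or deleted, so the chain is idempotent and the output
is always a subset of the caller inputs.  Known-site matching requires
allele identity, not just position.  The clustered filter uses span
semantics: any variant that belongs to a set of more than ``max_in_window``
variants whose positions span at most ``window_bp`` bases
(pos_max - pos_min + 1 <= window_bp) is dropped.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from pathlib import Path
from typing import Dict, Iterable, List, Mapping, Set, Tuple

import numpy as np
import pandas as pd
import pysam

from .stats import welch_t_test

logger = logging.getLogger(__name__)

__all__ = [
    "STATUS_ORDER",
    "BurdenResult",
    "read_caller_vcfs",
    "read_known_sites",
    "discover_caller_vcfs",
    "consensus_filter",
    "known_site_filter",
    "shared_mutation_filter",
    "clustered_mutation_filter",
    "apply_filter_chain",
    "mutational_burden",
]

PASS = "pass"
STATUS_ORDER = (
    PASS,
    "dropped_consensus",
    "dropped_known_site",
    "dropped_shared",
    "dropped_clustered",
)

_COLUMNS = ["sample", "chrom", "pos", "ref", "alt", "callers", "n_callers", "status"]


@dataclass(frozen=True)
class BurdenResult:
    sample: str
    n_mutations: int
    callable_mb: float
    burden: float


def _parse_vcf(path, sample: str, caller: str) -> List[Tuple]:
    """Parse one caller VCF into (sample, chrom, pos, ref, alt) keys.

    Multiallelic rows are split into one record per ALT; duplicate keys
    within one file are deduplicated with a warning.
    """
    seen: Set[Tuple[str, str, int, str, str]] = set()
    out: List[Tuple] = []
    try:
        vcf = pysam.VariantFile(str(path))
    except (ValueError, OSError) as exc:
        raise ValueError(f"cannot parse VCF {path}: {exc}") from exc
    with vcf:
        for lineno, rec in enumerate(vcf, start=1):
            if rec.ref is None or not rec.alts:
                raise ValueError(f"malformed VCF record in {path} (record {lineno})")
            for alt in rec.alts:
                if alt == rec.ref:
                    raise ValueError(
                        f"REF == ALT in {path} (record {lineno}): {rec.ref}"
                    )
                key = (sample, rec.chrom, rec.pos, rec.ref, alt)
                if key in seen:
                    logger.warning(
                        "duplicate record %s:%d %s>%s in %s; deduplicated",
                        rec.chrom, rec.pos, rec.ref, alt, path,
                    )
                    continue
                seen.add(key)
                out.append(key + (caller,))
    return out


def read_caller_vcfs(paths: Mapping[str, Mapping[str, str]]) -> pd.DataFrame:
    """Read per-sample, per-caller VCFs into one mutation table.

    Parameters
    ----------
    paths : {sample: {caller: vcf_path}}

    Returns
    -------
    DataFrame with one row per distinct (sample, chrom, pos, ref, alt),
    caller support accumulated into a frozenset, status ``pass``.
    """
    raw: List[Tuple] = []
    for sample, by_caller in paths.items():
        for caller, path in by_caller.items():
            raw.extend(_parse_vcf(path, sample, caller))
    support: Dict[Tuple, Set[str]] = {}
    for *key, caller in raw:
        support.setdefault(tuple(key), set()).add(caller)
    rows = [
        {
            "sample": k[0],
            "chrom": k[1],
            "pos": int(k[2]),
            "ref": k[3],
            "alt": k[4],
            "callers": frozenset(callers),
            "n_callers": len(callers),
            "status": PASS,
        }
        for k, callers in support.items()
    ]
    df = pd.DataFrame(rows, columns=_COLUMNS)
    if len(df):
        df = df.sort_values(["sample", "chrom", "pos", "ref", "alt"]).reset_index(
            drop=True
        )
    return df


def discover_caller_vcfs(vcf_dir, callers: Iterable[str]) -> Dict[str, Dict[str, str]]:
    """Find ``<sample>.<caller>.vcf`` files under a directory."""
    callers = list(callers)
    found: Dict[str, Dict[str, str]] = {}
    for path in sorted(Path(vcf_dir).glob("*.vcf")):
        parts = path.stem.rsplit(".", 1)
        if len(parts) != 2 or parts[1] not in callers:
            continue
        found.setdefault(parts[0], {})[parts[1]] = str(path)
    return found


def read_known_sites(path) -> Set[Tuple[str, int, str, str]]:
    """Load a sites-only VCF of known germline variants as exact keys."""
    sites: Set[Tuple[str, int, str, str]] = set()
    with pysam.VariantFile(str(path)) as vcf:
        for rec in vcf:
            for alt in rec.alts or ():
                sites.add((rec.chrom, rec.pos, rec.ref, alt))
    return sites


def _demote(df: pd.DataFrame, mask: pd.Series, status: str) -> pd.DataFrame:
    out = df.copy()
    out.loc[mask & (out["status"] == PASS), "status"] = status
    return out


def consensus_filter(records: pd.DataFrame, min_callers: int = 2) -> pd.DataFrame:
    """Keep variants supported by at least ``min_callers`` callers."""
    if min_callers < 1:
        raise ValueError("min_callers must be >= 1")
    if not len(records):
        return records.copy()
    return _demote(records, records["n_callers"] < min_callers, "dropped_consensus")


def known_site_filter(
    records: pd.DataFrame, known_sites: Set[Tuple[str, int, str, str]]
) -> pd.DataFrame:
    """Drop variants exactly matching a known germline site (allele-exact)."""
    if not len(records) or not known_sites:
        return records.copy()
    keys = list(zip(records["chrom"], records["pos"], records["ref"], records["alt"]))
    mask = pd.Series([k in known_sites for k in keys], index=records.index)
    return _demote(records, mask, "dropped_known_site")


def shared_mutation_filter(records: pd.DataFrame, min_samples: int = 2) -> pd.DataFrame:
    """Drop variants whose key passes in >= ``min_samples`` distinct samples."""
    if min_samples < 1:
        raise ValueError("min_samples must be >= 1")
    if not len(records):
        return records.copy()
    passing = records[records["status"] == PASS]
    key_cols = ["chrom", "pos", "ref", "alt"]
    n_samples = passing.groupby(key_cols)["sample"].nunique()
    shared = set(n_samples[n_samples >= min_samples].index)
    keys = list(zip(records["chrom"], records["pos"], records["ref"], records["alt"]))
    mask = pd.Series([k in shared for k in keys], index=records.index)
    return _demote(records, mask, "dropped_shared")


def clustered_positions(positions: np.ndarray, window_bp: int, max_in_window: int) -> np.ndarray:
    """Boolean mask over (sorted-order-agnostic) positions: True = clustered.

    A variant is clustered when some window of span <= window_bp (inclusive,
    pos_max - pos_min + 1) contains more than max_in_window variants
    including it.  Two-pointer scan over the sorted multiset.
    """
    positions = np.asarray(positions)
    n = positions.size
    mask = np.zeros(n, dtype=bool)
    order = np.argsort(positions, kind="mergesort")
    pos_sorted = positions[order]
    left = 0
    for right in range(n):
        while pos_sorted[right] - pos_sorted[left] + 1 > window_bp:
            left += 1
        if right - left + 1 > max_in_window:
            mask[order[left : right + 1]] = True
    return mask


def clustered_mutation_filter(
    records: pd.DataFrame, window_bp: int = 10, max_in_window: int = 3
) -> pd.DataFrame:
    """Drop clustered variants (> max_in_window within a window_bp span)."""
    if not len(records):
        return records.copy()
    out = records.copy()
    passing = out[out["status"] == PASS]
    for (_, _), grp in passing.groupby(["sample", "chrom"], sort=False):
        mask = clustered_positions(grp["pos"].to_numpy(), window_bp, max_in_window)
        out.loc[grp.index[mask], "status"] = "dropped_clustered"
    return out


def apply_filter_chain(
    records: pd.DataFrame,
    known_sites: Set[Tuple[str, int, str, str]] | None = None,
    min_callers: int = 2,
    min_samples: int = 2,
    window_bp: int = 10,
    max_in_window: int = 3,
) -> Tuple[pd.DataFrame, List[Dict]]:
    """Run the fixed filter chain and return (records, audit log).

    Order: consensus -> known sites -> shared -> clustered.  The audit log
    records pass counts after each stage.
    """
    audit: List[Dict] = []

    def log(stage: str, df: pd.DataFrame) -> None:
        audit.append(
            {"stage": stage, "n_pass": int((df["status"] == PASS).sum()),
             "n_total": int(len(df))}
        )

    log("input", records)
    records = consensus_filter(records, min_callers=min_callers)
    log("consensus", records)
    records = known_site_filter(records, known_sites or set())
    log("known_site", records)
    records = shared_mutation_filter(records, min_samples=min_samples)
    log("shared", records)
    records = clustered_mutation_filter(
        records, window_bp=window_bp, max_in_window=max_in_window
    )
    log("clustered", records)
    return records, audit


def mutational_burden(records: pd.DataFrame, callable_mb: float) -> List[BurdenResult]:
    """Mutations per megabase for each sample's pass-status records."""
    if callable_mb <= 0:
        raise ValueError("callable_mb must be positive")
    passing = records[records["status"] == PASS]
    samples = sorted(records["sample"].unique()) if len(records) else []
    return [
        BurdenResult(
            sample=s,
            n_mutations=int((passing["sample"] == s).sum()),
            callable_mb=float(callable_mb),
            burden=float((passing["sample"] == s).sum()) / callable_mb,
        )
        for s in samples
    ]


def burden_group_test(
    burdens: Iterable[BurdenResult], groups: Mapping[str, str], group_a: str, group_b: str
):
    """Welch's t-test on per-sample burden between two groups."""
    a = [b.burden for b in burdens if groups.get(b.sample) == group_a]
    b = [b.burden for b in burdens if groups.get(b.sample) == group_b]
    return welch_t_test(a, b)


def records_to_table(records: pd.DataFrame) -> pd.DataFrame:
    """Flatten caller sets for TSV output."""
    out = records.copy()
    out["callers"] = out["callers"].map(lambda s: ",".join(sorted(s)))
    return out[["chrom", "pos", "ref", "alt", "sample", "callers", "n_callers", "status"]]
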