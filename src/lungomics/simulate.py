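"""Synthetic two-group, two-tissue study generator with planted ground truth.

Generates a fully self-contained toy study: a small random genome (two
chromosomes), a non-overlapping gene annotation with strands and TSSs, CpG
islands and 5-kb tiles, per-sample quartets of somatic caller VCFs with a
known consensus design, a sites-only VCF of known germline variants, a
negative-binomial count matrix (plus TPM), and a beta-value methylation
matrix.  Every planted effect is recorded in a :class:`TruthTable` so
recovery can be scored exactly.

Design: 2 tissues (normal, tumor) x 2 treatments (HDM, VEH) x n replicates.
Planted effects live in the normal-tissue HDM-vs-VEH contrast: DEGs with
|log2FC| >= 1, promoter differentially-methylated sites, and a set of
"epigenetically controlled" genes whose promoter methylation and expression
are anti-correlated across the HDM samples (hypo-up = activated, hyper-down
= repressed).

All randomness flows through integer-seeded numpy generators with fixed
stream ids per stage, so regeneration under a fixed seed is byte-identical.
"""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass, field, replace
from pathlib import Path
from typing import Dict, List, Mapping, Optional, Sequence, Set, Tuple

import numpy as np
import pandas as pd

from .io import write_bed, write_fasta, write_gmt
from .spectra import SBS96_CATEGORIES

__all__ = [
    "SimulationConfig",
    "TruthTable",
    "StudyBundle",
    "planted_sbs_spectrum",
    "simulate_genome_and_annotation",
    "simulate_caller_vcfs",
    "simulate_expression",
    "simulate_methylation",
    "simulate_study",
    "write_study",
]

_BASES = "ACGT"
_COMP = {"A": "T", "C": "G", "G": "C", "T": "A"}

TISSUES = ("normal", "tumor")
TREATMENTS = ("HDM", "VEH")


@dataclass(frozen=True)
class SimulationConfig:
    """Knobs for the synthetic study; defaults mirror the 2x2xn=3 design."""

    seed: int = 0
    n_per_group: int = 3
    n_genes: int = 2000
    n_cpg: int = 20000
    n_chromosomes: int = 2
    chromosome_length: int = 1_000_000
    gene_length: int = 300
    tile_bp: int = 5000
    promoter_cpg_per_gene: int = 4
    # somatic-variant design
    n_mutations_per_sample: int = 1000
    n_decoys_per_sample: int = 60
    n_dbs_per_sample: int = 15
    n_indels_per_sample: int = 25
    n_germline_sites: int = 30
    n_shared_artifacts: int = 10
    n_clustered_artifacts: int = 3
    callers: Tuple[str, ...] = ("mutect2", "varscan2", "strelka2", "muse")
    # expression
    planted_deg_frac: float = 0.05
    deg_log2fc: float = 2.5
    nb_dispersion: float = 0.05
    # methylation
    planted_dms_frac: float = 0.002
    dms_delta_beta: float = 0.30
    beta_precision: float = 60.0
    # epigenetically controlled genes (coupled methylation/expression)
    n_epi_up: int = 12
    n_epi_down: int = 8
    couple_epi: bool = True
    epi_meth_step: float = 0.08
    epi_expr_step: float = 0.4
    epi_site_precision: float = 2000.0
    epi_expr_baseline: float = 20000.0
    epi_dispersion: float = 1e-4
    epi_log2fc: float = 2.5
    epi_delta_beta: float = 0.45

    def validate(self) -> None:
        positive = [
            self.n_per_group, self.n_genes, self.n_cpg, self.n_chromosomes,
            self.chromosome_length, self.gene_length, self.tile_bp,
            self.n_mutations_per_sample,
        ]
        if any(v <= 0 for v in positive):
            raise ValueError("all counts must be positive")
        for frac in (self.planted_deg_frac, self.planted_dms_frac):
            if not 0 < frac < 1:
                raise ValueError("fractions must lie in (0, 1)")
        n_deg = round(self.planted_deg_frac * self.n_genes)
        if self.n_epi_up + self.n_epi_down > n_deg:
            raise ValueError("epigenetic genes cannot exceed the planted DEG count")
        if self.n_cpg < self.promoter_cpg_per_gene * self.n_genes:
            raise ValueError("n_cpg must cover promoter CpGs for every gene")

    @property
    def samples(self) -> List[str]:
        return [
            f"{tissue}_{treat}_{r}"
            for tissue in TISSUES
            for treat in TREATMENTS
            for r in range(1, self.n_per_group + 1)
        ]

    def design(self) -> pd.DataFrame:
        rows = [
            {"sample": f"{tissue}_{treat}_{r}", "tissue": tissue, "treatment": treat}
            for tissue in TISSUES
            for treat in TREATMENTS
            for r in range(1, self.n_per_group + 1)
        ]
        return pd.DataFrame(rows).set_index("sample")


@dataclass
class TruthTable:
    """Planted ground truth for parameter-recovery tests."""

    genes: Dict[str, Dict] = field(default_factory=dict)
    cpgs: Dict[str, Dict] = field(default_factory=dict)
    variants: Dict[str, Dict[str, List]] = field(default_factory=dict)
    spectrum: Dict = field(default_factory=dict)
    coupling_offsets: Dict[str, float] = field(default_factory=dict)
    modules: Dict[str, List[str]] = field(default_factory=dict)
    markers: Dict[str, List[str]] = field(default_factory=dict)

    def validate(self) -> None:
        for gene, info in self.genes.items():
            if info.get("epi_class") in ("hypo_up", "hyper_down"):
                if not (info["is_deg"] and info["is_dmg"]):
                    raise ValueError(f"epi gene {gene} must be DEG and DMG")
                want = "up" if info["epi_class"] == "hypo_up" else "down"
                if info["direction"] != want:
                    raise ValueError(f"epi gene {gene} direction inconsistent")

    def epi_genes(self) -> Dict[str, str]:
        return {
            g: info["epi_class"]
            for g, info in self.genes.items()
            if info.get("epi_class") not in (None, "none")
        }

    def designed_pass_set(self, sample: str) -> Set[Tuple[str, int, str, str]]:
        return {tuple(v) for v in self.variants[sample]["true"]}

    def to_json(self, path) -> None:
        payload = asdict(self)
        Path(path).write_text(json.dumps(payload, sort_keys=True, indent=1))

    @classmethod
    def from_json(cls, path) -> "TruthTable":
        payload = json.loads(Path(path).read_text())
        return cls(**payload)


# ---------------------------------------------------------------------------
# genome / annotation
# ---------------------------------------------------------------------------

def _chrom_names(cfg: SimulationConfig) -> List[str]:
    return [f"chr{i + 1}" for i in range(cfg.n_chromosomes)]


def simulate_genome_and_annotation(cfg: SimulationConfig):
    """Random genome plus a non-overlapping gene annotation.

    Returns (reference dict, annotation DataFrame indexed by gene with
    chrom/strand/tss/start/end/length, cpg_islands DataFrame, tiles
    DataFrame).  Genes sit in evenly spaced slots with >= 1.5 kb clearance
    from chromosome edges; ~50 % of strands are minus.
    """
    cfg.validate()
    rng = np.random.default_rng([cfg.seed, 1])
    chroms = _chrom_names(cfg)
    alphabet = np.frombuffer(_BASES.encode(), dtype=np.uint8)
    reference = {
        c: alphabet[rng.integers(0, 4, cfg.chromosome_length)].tobytes().decode()
        for c in chroms
    }

    per_chrom = [cfg.n_genes // cfg.n_chromosomes] * cfg.n_chromosomes
    for i in range(cfg.n_genes % cfg.n_chromosomes):
        per_chrom[i] += 1
    margin = 2000  # keeps the promoter window inside the chromosome
    rows = []
    gid = 0
    for chrom, n_here in zip(chroms, per_chrom):
        usable = cfg.chromosome_length - 2 * margin
        slot = usable // n_here
        if slot < cfg.gene_length + 10:
            raise ValueError("genome too small for the requested gene count")
        jitter_max = slot - cfg.gene_length
        for k in range(n_here):
            start = margin + k * slot + int(rng.integers(0, jitter_max))
            end = start + cfg.gene_length
            strand = "+" if rng.random() < 0.5 else "-"
            tss = start if strand == "+" else end - 1
            rows.append(
                {
                    "gene": f"g{gid:05d}",
                    "chrom": chrom,
                    "strand": strand,
                    "tss": tss,
                    "start": start,
                    "end": end,
                    "length": cfg.gene_length,
                }
            )
            gid += 1
    annotation = pd.DataFrame(rows).set_index("gene")

    islands = pd.DataFrame(
        {
            "chrom": annotation["chrom"],
            "start": np.maximum(annotation["tss"] - 100, 0),
            "end": annotation["tss"] + 100,
            "name": [f"island_{g}" for g in annotation.index],
        }
    ).reset_index(drop=True)

    tile_rows = []
    for chrom in chroms:
        for i, s in enumerate(range(0, cfg.chromosome_length, cfg.tile_bp)):
            tile_rows.append(
                {
                    "chrom": chrom,
                    "start": s,
                    "end": min(s + cfg.tile_bp, cfg.chromosome_length),
                    "name": f"tile_{chrom}_{i}",
                }
            )
    tiles = pd.DataFrame(tile_rows)
    return reference, annotation, islands, tiles


def promoter_interval(strand: str, tss: int) -> Tuple[int, int]:
    """Transcription-oriented promoter window (-1.5 kb / +0.5 kb), half-open."""
    if strand == "+":
        return tss - 1500, tss + 500
    return tss - 499, tss + 1501


# ---------------------------------------------------------------------------
# planted mutational spectrum and caller VCFs
# ---------------------------------------------------------------------------

def planted_sbs_spectrum() -> np.ndarray:
    """Deterministic planted SBS96 probability vector.

    A uniform floor, a strong peak on N[C>T]G (deamination-like), and a
    moderate lift of all T>C categories.
    """
    probs = np.ones(96)
    for i, cat in enumerate(SBS96_CATEGORIES):
        if "[C>T]" in cat and cat.endswith("G"):
            probs[i] += 40.0
        if "[T>C]" in cat:
            probs[i] += 4.0
    return probs / probs.sum()


def _trinuc_index(reference: Mapping[str, str]) -> Dict[str, Tuple[np.ndarray, np.ndarray]]:
    """Map each SBS96 context to candidate genome positions.

    Returns {pyrimidine trinucleotide: (chrom_idx array, 1-based pos array)}
    over interior positions of every chromosome, collapsing purine centers
    by reverse complement.
    """
    b2i = {b: i for i, b in enumerate(_BASES)}
    ctx_positions: Dict[int, List[Tuple[np.ndarray, np.ndarray]]] = {}
    chroms = list(reference)
    for ci, chrom in enumerate(chroms):
        arr = np.frombuffer(reference[chrom].encode(), dtype=np.uint8)
        code = np.full(arr.shape, -1, dtype=np.int8)
        for b, i in b2i.items():
            code[arr == ord(b)] = i
        left, center, right = code[:-2], code[1:-1], code[2:]
        pyr = (center == 1) | (center == 3)
        ids = np.where(
            pyr,
            left * 4 + right + np.where(center == 1, 0, 16),
            (3 - right) * 4 + (3 - left) + np.where(center == 2, 0, 16),
        )
        pos = np.arange(2, len(arr))  # 1-based position of the center base
        for t in range(32):
            sel = ids == t
            ctx_positions.setdefault(t, []).append((np.full(sel.sum(), ci), pos[sel]))
    merged: Dict[str, Tuple[np.ndarray, np.ndarray]] = {}
    for t, parts in ctx_positions.items():
        five = _BASES[(t % 16) // 4]
        three = _BASES[t % 4]
        center = "C" if t < 16 else "T"
        key = five + center + three
        merged[key] = (
            np.concatenate([p[0] for p in parts]),
            np.concatenate([p[1] for p in parts]),
        )
    return merged


class _PositionBook:
    """Tracks used loci: global uniqueness plus a per-sample minimum gap."""

    def __init__(self, gap: int = 12):
        self.gap = gap
        self.global_used: Set[Tuple[int, int]] = set()
        self.by_sample: Dict[str, Set[Tuple[int, int]]] = {}

    def ok(self, sample: str, ci: int, pos: int, span: int = 1) -> bool:
        for p in range(pos, pos + span):
            if (ci, p) in self.global_used:
                return False
        sset = self.by_sample.get(sample, set())
        for d in range(-self.gap, span + self.gap):
            if (ci, pos + d) in sset:
                return False
        return True

    def add(self, sample: str, ci: int, pos: int, span: int = 1) -> None:
        for p in range(pos, pos + span):
            self.global_used.add((ci, p))
            self.by_sample.setdefault(sample, set()).add((ci, p))

    def add_many(self, samples: Sequence[str], ci: int, pos: int, span: int = 1) -> None:
        for p in range(pos, pos + span):
            self.global_used.add((ci, p))
            for s in samples:
                self.by_sample.setdefault(s, set()).add((ci, p))


def _caller_subset(rng: np.random.Generator, callers: Sequence[str], k: int) -> List[str]:
    idx = rng.choice(len(callers), size=k, replace=False)
    return sorted(callers[i] for i in sorted(idx))


def _random_snv(rng, reference, chroms, book, sample, margin=2) -> Tuple[str, int, str, str]:
    while True:
        ci = int(rng.integers(0, len(chroms)))
        pos = int(rng.integers(margin + 1, len(reference[chroms[ci]]) - margin))
        if not book.ok(sample, ci, pos):
            continue
        ref = reference[chroms[ci]][pos - 1]
        alt = _BASES[(int(rng.integers(1, 4)) + _BASES.index(ref)) % 4]
        return chroms[ci], pos, ref, alt


def simulate_caller_vcfs(cfg: SimulationConfig, reference: Mapping[str, str]):
    """Design per-sample caller calls with a known consensus outcome.

    Returns (calls, known_sites, truth_update) where ``calls`` maps
    sample -> caller -> list of (chrom, pos, ref, alt); ``known_sites`` is
    the germline site list; ``truth_update`` holds the per-sample designed
    variant classes:

    * true      — consensus >= 2 callers, globally unique locus (pass set)
    * decoy     — exactly one caller (dropped by consensus)
    * germline  — all callers, all samples, also in the known-site set
    * shared    — >= 2 callers in >= 2 samples (dropped as shared)
    * clustered — 4 variants within a 10-bp span (dropped as clustered)

    True SNVs are drawn from :func:`planted_sbs_spectrum` by trinucleotide
    context.
    """
    rng = np.random.default_rng([cfg.seed, 2])
    chroms = _chrom_names(cfg)
    samples = cfg.samples
    callers = list(cfg.callers)
    book = _PositionBook(gap=12)
    trinuc = _trinuc_index(reference)
    spectrum = planted_sbs_spectrum()

    calls: Dict[str, Dict[str, List]] = {
        s: {c: [] for c in callers} for s in samples
    }
    truth_variants: Dict[str, Dict[str, List]] = {
        s: {"true": [], "decoy": [], "germline": [], "shared": [], "clustered": []}
        for s in samples
    }

    def emit(sample: str, key, support: Sequence[str]) -> None:
        for caller in support:
            calls[sample][caller].append(key)

    # --- germline sites: in every sample and in the known-site VCF
    known_sites: List[Tuple[str, int, str, str]] = []
    for _ in range(cfg.n_germline_sites):
        while True:
            ci = int(rng.integers(0, len(chroms)))
            pos = int(rng.integers(3, cfg.chromosome_length - 2))
            if all(book.ok(s, ci, pos) for s in samples):
                break
        ref = reference[chroms[ci]][pos - 1]
        alt = _BASES[(int(rng.integers(1, 4)) + _BASES.index(ref)) % 4]
        key = (chroms[ci], pos, ref, alt)
        book.add_many(samples, ci, pos)
        known_sites.append(key)
        for s in samples:
            emit(s, key, callers)
            truth_variants[s]["germline"].append(list(key))

    # --- shared artifacts: pass consensus in >= 2 samples
    for _ in range(cfg.n_shared_artifacts):
        n_carriers = int(rng.integers(2, len(samples) + 1))
        carriers = sorted(
            samples[i] for i in rng.choice(len(samples), n_carriers, replace=False)
        )
        while True:
            ci = int(rng.integers(0, len(chroms)))
            pos = int(rng.integers(3, cfg.chromosome_length - 2))
            if all(book.ok(s, ci, pos) for s in carriers):
                break
        ref = reference[chroms[ci]][pos - 1]
        alt = _BASES[(int(rng.integers(1, 4)) + _BASES.index(ref)) % 4]
        key = (chroms[ci], pos, ref, alt)
        book.add_many(carriers, ci, pos)
        for s in carriers:
            emit(s, key, _caller_subset(rng, callers, int(rng.integers(2, 5))))
            truth_variants[s]["shared"].append(list(key))

    cat_context = {cat: cat[0] + cat[2] + cat[-1] for cat in SBS96_CATEGORIES}
    cat_alt = {cat: cat[4] for cat in SBS96_CATEGORIES}

    for sample in samples:
        # --- clustered artifacts: 4 variants in a 10-bp span, >= 2 callers
        for _ in range(cfg.n_clustered_artifacts):
            while True:
                ci = int(rng.integers(0, len(chroms)))
                base = int(rng.integers(30, cfg.chromosome_length - 30))
                if book.ok(sample, ci, base, span=10):
                    break
            offsets = (0, 2, 5, 9)
            book.add(sample, ci, base, span=10)
            for off in offsets:
                pos = base + off
                ref = reference[chroms[ci]][pos - 1]
                alt = _BASES[(int(rng.integers(1, 4)) + _BASES.index(ref)) % 4]
                key = (chroms[ci], pos, ref, alt)
                emit(sample, key, _caller_subset(rng, callers, int(rng.integers(2, 5))))
                truth_variants[sample]["clustered"].append(list(key))

        # --- true consensus SNVs drawn from the planted spectrum
        counts = rng.multinomial(cfg.n_mutations_per_sample, spectrum)
        for cat_i, n_cat in enumerate(counts):
            cat = SBS96_CATEGORIES[cat_i]
            ctx_chrom, ctx_pos = trinuc[cat_context[cat]]
            for _ in range(int(n_cat)):
                while True:
                    j = int(rng.integers(0, len(ctx_pos)))
                    ci, pos = int(ctx_chrom[j]), int(ctx_pos[j])
                    if book.ok(sample, ci, pos):
                        break
                ref = reference[chroms[ci]][pos - 1]
                alt = cat_alt[cat] if ref in "CT" else _COMP[cat_alt[cat]]
                key = (chroms[ci], pos, ref, alt)
                book.add(sample, ci, pos)
                n_support = 2 + int(rng.choice(3, p=[0.3, 0.3, 0.4]))
                emit(sample, key, _caller_subset(rng, callers, n_support))
                truth_variants[sample]["true"].append(list(key))

        # --- true doublet substitutions
        for _ in range(cfg.n_dbs_per_sample):
            while True:
                ci = int(rng.integers(0, len(chroms)))
                pos = int(rng.integers(3, cfg.chromosome_length - 3))
                if book.ok(sample, ci, pos, span=2):
                    break
            ref = reference[chroms[ci]][pos - 1 : pos + 1]
            alt = "".join(
                _BASES[(int(rng.integers(1, 4)) + _BASES.index(b)) % 4] for b in ref
            )
            key = (chroms[ci], pos, ref, alt)
            book.add(sample, ci, pos, span=2)
            emit(sample, key, _caller_subset(rng, callers, int(rng.integers(2, 5))))
            truth_variants[sample]["true"].append(list(key))

        # --- true indels (VCF anchored form)
        for k in range(cfg.n_indels_per_sample):
            length = int(rng.integers(1, 4))
            is_del = bool(rng.random() < 0.5)
            while True:
                ci = int(rng.integers(0, len(chroms)))
                pos = int(rng.integers(30, cfg.chromosome_length - 30))
                if book.ok(sample, ci, pos, span=length + 1):
                    break
            seq = reference[chroms[ci]]
            if is_del:
                ref = seq[pos - 1 : pos + length]
                alt = ref[0]
            else:
                ref = seq[pos - 1]
                alt = ref + "".join(
                    _BASES[int(rng.integers(0, 4))] for _ in range(length)
                )
            key = (chroms[ci], pos, ref, alt)
            book.add(sample, ci, pos, span=length + 1)
            emit(sample, key, _caller_subset(rng, callers, int(rng.integers(2, 5))))
            truth_variants[sample]["true"].append(list(key))

        # --- decoys: one caller only
        for _ in range(cfg.n_decoys_per_sample):
            key = _random_snv(rng, reference, chroms, book, sample)
            book.add(sample, _chrom_names(cfg).index(key[0]), key[1])
            emit(sample, key, [callers[int(rng.integers(0, len(callers)))]])
            truth_variants[sample]["decoy"].append(list(key))

    truth_update = {
        "variants": truth_variants,
        "spectrum": {
            "id": "planted_sbs_v1",
            "categories": list(SBS96_CATEGORIES),
            "probs": planted_sbs_spectrum().tolist(),
        },
    }
    return calls, known_sites, truth_update


def _vcf_header(reference: Mapping[str, str]) -> str:
    lines = ["##fileformat=VCFv4.2"]
    for chrom, seq in reference.items():
        lines.append(f"##contig=<ID={chrom},length={len(seq)}>")
    lines.append('##FILTER=<ID=PASS,Description="All filters passed">')
    lines.append("#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO")
    return "\n".join(lines) + "\n"


def write_vcf(path, records: Sequence[Tuple[str, int, str, str]],
              reference: Mapping[str, str]) -> None:
    """Write a minimal sites-only VCF v4.2."""
    chrom_order = {c: i for i, c in enumerate(reference)}
    recs = sorted(records, key=lambda r: (chrom_order[r[0]], r[1], r[2], r[3]))
    with open(path, "w") as fh:
        fh.write(_vcf_header(reference))
        for chrom, pos, ref, alt in recs:
            fh.write(f"{chrom}\t{pos}\t.\t{ref}\t{alt}\t.\tPASS\t.\n")


# ---------------------------------------------------------------------------
# planted gene/CpG truth shared by expression and methylation
# ---------------------------------------------------------------------------

def plan_truth(cfg: SimulationConfig, annotation: pd.DataFrame) -> TruthTable:
    """Decide DEGs, module stand-ins, marker sets and epi-coupled genes."""
    cfg.validate()
    rng = np.random.default_rng([cfg.seed, 3])
    genes = list(annotation.index)
    n_deg = round(cfg.planted_deg_frac * cfg.n_genes)
    deg_idx = rng.choice(len(genes), size=n_deg, replace=False)
    deg_genes = [genes[i] for i in sorted(deg_idx)]
    n_up = (n_deg + 1) // 2
    up_genes = deg_genes[:n_up]
    down_genes = deg_genes[n_up:]
    if cfg.n_epi_up > len(up_genes) or cfg.n_epi_down > len(down_genes):
        raise ValueError("not enough planted DEGs for the requested epi genes")
    epi_up = up_genes[: cfg.n_epi_up] if cfg.couple_epi else []
    epi_down = down_genes[: cfg.n_epi_down] if cfg.couple_epi else []

    truth = TruthTable()
    for g in genes:
        is_deg = g in set(deg_genes)
        direction = "up" if g in set(up_genes) else ("down" if is_deg else "none")
        epi_class = (
            "hypo_up" if g in set(epi_up)
            else "hyper_down" if g in set(epi_down)
            else "none"
        )
        truth.genes[g] = {
            "is_deg": is_deg,
            "direction": direction,
            "is_dmg": epi_class != "none",
            "epi_class": epi_class,
        }

    # module stand-ins (upshifted in HDM normal) among non-epi up DEGs
    pool = [g for g in up_genes if g not in set(epi_up)]
    truth.modules = {
        "IL1_module_standin": pool[:17],
        "IL17_module_standin": pool[17:29],
    }
    truth.markers = {
        "myeloid": pool[29:39],
        "lymphoid": [g for g in genes if g not in set(deg_genes)][:10],
    }

    offsets = np.linspace(-1.0, 1.0, cfg.n_per_group)
    for r in range(1, cfg.n_per_group + 1):
        truth.coupling_offsets[f"normal_HDM_{r}"] = float(offsets[r - 1])
    truth.validate()
    return truth


# ---------------------------------------------------------------------------
# expression
# ---------------------------------------------------------------------------

def simulate_expression(
    cfg: SimulationConfig,
    annotation: pd.DataFrame,
    truth: Optional[TruthTable] = None,
):
    """Negative-binomial counts and TPM with planted DEGs.

    Planted effects (DEGs, module upshifts, epi coupling) apply to the
    normal-tissue HDM samples; tumor tissue carries no planted treatment
    effect.
    """
    if truth is None:
        truth = plan_truth(cfg, annotation)
    rng = np.random.default_rng([cfg.seed, 4])
    genes = list(annotation.index)
    design = cfg.design()
    samples = list(design.index)
    n_genes, n_samples = len(genes), len(samples)

    base_log2 = rng.uniform(3.0, 9.0, n_genes)
    dispersion = np.exp(rng.normal(np.log(cfg.nb_dispersion), 0.3, n_genes))
    epi_mask = np.array(
        [truth.genes[g]["epi_class"] != "none" for g in genes]
    )
    base_mu = np.exp2(base_log2)
    base_mu[epi_mask] = cfg.epi_expr_baseline
    dispersion[epi_mask] = cfg.epi_dispersion

    log2fc = np.zeros(n_genes)
    for i, g in enumerate(genes):
        info = truth.genes[g]
        if not info["is_deg"]:
            continue
        sign = 1.0 if info["direction"] == "up" else -1.0
        if info["epi_class"] != "none":
            log2fc[i] = sign * cfg.epi_log2fc
        else:
            log2fc[i] = sign * (cfg.deg_log2fc + rng.uniform(0.0, 1.0))

    depth = rng.uniform(0.7, 1.4, n_samples)
    log2_shift = np.zeros((n_genes, n_samples))
    for j, s in enumerate(samples):
        row = design.loc[s]
        if row["tissue"] == "normal" and row["treatment"] == "HDM":
            log2_shift[:, j] += log2fc
            if cfg.couple_epi:
                a = truth.coupling_offsets.get(s, 0.0)
                sign_meth = np.array(
                    [
                        -1.0 if truth.genes[g]["epi_class"] == "hypo_up"
                        else 1.0 if truth.genes[g]["epi_class"] == "hyper_down"
                        else 0.0
                        for g in genes
                    ]
                )
                # expression moves opposite to methylation across samples
                log2_shift[:, j] += -sign_meth * cfg.epi_expr_step * a

    mu = base_mu[:, None] * np.exp2(log2_shift) * depth[None, :]
    r_param = 1.0 / dispersion
    p_param = r_param[:, None] / (r_param[:, None] + mu)
    counts = rng.negative_binomial(r_param[:, None], p_param)
    counts_df = pd.DataFrame(counts, index=genes, columns=samples)

    lengths = annotation["length"].to_numpy(dtype=float)
    rate = counts / lengths[:, None]
    tpm = rate / rate.sum(axis=0, keepdims=True) * 1e6
    tpm_df = pd.DataFrame(tpm, index=genes, columns=samples)
    return counts_df, tpm_df, design, truth


# ---------------------------------------------------------------------------
# methylation
# ---------------------------------------------------------------------------

def simulate_methylation(
    cfg: SimulationConfig,
    annotation: pd.DataFrame,
    truth: Optional[TruthTable] = None,
):
    """Beta-value matrix with planted promoter DMS and epi coupling.

    Every gene gets ``promoter_cpg_per_gene`` CpGs inside its promoter
    window; the rest are scattered (outside epi-gene promoters).  Planted
    effects live in the normal-tissue HDM group.
    """
    if truth is None:
        truth = plan_truth(cfg, annotation)
    rng = np.random.default_rng([cfg.seed, 5])
    design = cfg.design()
    samples = list(design.index)
    chroms = _chrom_names(cfg)
    epi = truth.epi_genes()

    # promoter CpGs
    site_rows = []
    used: Set[Tuple[str, int]] = set()
    for gene, row in annotation.iterrows():
        start, end = promoter_interval(row["strand"], int(row["tss"]))
        start = max(1, start)
        k = 0
        while k < cfg.promoter_cpg_per_gene:
            pos = int(rng.integers(start, end))
            if (row["chrom"], pos) in used:
                continue
            used.add((row["chrom"], pos))
            site_rows.append(
                {"chrom": row["chrom"], "pos": pos, "gene": gene, "kind": "promoter"}
            )
            k += 1

    # scattered CpGs, avoiding epi-gene promoters
    epi_intervals: Dict[str, List[Tuple[int, int]]] = {c: [] for c in chroms}
    for gene in epi:
        row = annotation.loc[gene]
        s, e = promoter_interval(row["strand"], int(row["tss"]))
        epi_intervals[row["chrom"]].append((s, e))
    n_scatter = cfg.n_cpg - len(site_rows)
    k = 0
    while k < n_scatter:
        chrom = chroms[int(rng.integers(0, len(chroms)))]
        pos = int(rng.integers(1, cfg.chromosome_length))
        if (chrom, pos) in used:
            continue
        if any(s <= pos < e for s, e in epi_intervals[chrom]):
            continue
        used.add((chrom, pos))
        site_rows.append({"chrom": chrom, "pos": pos, "gene": "", "kind": "scatter"})
        k += 1

    sites = pd.DataFrame(site_rows)
    sites = sites.sort_values(["chrom", "pos"]).reset_index(drop=True)
    sites.index = [f"cpg{i:06d}" for i in range(len(sites))]

    n_sites = len(sites)
    is_promoter = (sites["kind"] == "promoter").to_numpy()
    baseline = np.where(
        is_promoter, 0.15 + rng.uniform(-0.05, 0.05, n_sites),
        rng.uniform(0.2, 0.8, n_sites),
    )
    precision = np.full(n_sites, cfg.beta_precision)

    epi_site_mask = np.zeros(n_sites, dtype=bool)
    epi_sign = np.zeros(n_sites)
    for i, (gene, kind) in enumerate(zip(sites["gene"], sites["kind"])):
        if kind == "promoter" and gene in epi:
            epi_site_mask[i] = True
            if epi[gene] == "hyper_down":
                epi_sign[i] = 1.0
                baseline[i] = 0.25  # VEH low, HDM high
            else:
                epi_sign[i] = -1.0
                baseline[i] = 0.75  # VEH high, HDM low
            precision[i] = cfg.epi_site_precision

    # scattered planted DMS (normal-tissue contrast)
    n_dms = round(cfg.planted_dms_frac * cfg.n_cpg)
    scatter_idx = np.where(~is_promoter)[0]
    dms_pick = rng.choice(scatter_idx, size=min(n_dms, len(scatter_idx)), replace=False)
    dms_pick = np.sort(dms_pick)
    dms_sign = np.where(np.arange(len(dms_pick)) % 2 == 0, 1.0, -1.0)
    dms_shift = np.zeros(n_sites)
    dms_shift[dms_pick] = dms_sign * cfg.dms_delta_beta
    # keep shifted means inside (0, 1) with headroom
    base_at = baseline[dms_pick]
    dms_shift[dms_pick] = np.where(
        base_at + dms_shift[dms_pick] > 0.95,
        -cfg.dms_delta_beta,
        np.where(base_at + dms_shift[dms_pick] < 0.05, cfg.dms_delta_beta,
                 dms_shift[dms_pick]),
    )

    site_ids = list(sites.index)
    for j, i in enumerate(dms_pick):
        truth.cpgs[site_ids[i]] = {
            "is_dms": True,
            "direction": "hyper" if dms_shift[i] > 0 else "hypo",
        }
    for i in np.where(epi_site_mask)[0]:
        truth.cpgs[site_ids[i]] = {
            "is_dms": True,
            "direction": "hyper" if epi_sign[i] > 0 else "hypo",
            "gene": sites["gene"].iloc[i],
        }

    means = np.tile(baseline[:, None], (1, len(samples)))
    for j, s in enumerate(samples):
        row = design.loc[s]
        if row["tissue"] == "normal" and row["treatment"] == "HDM":
            means[:, j] += dms_shift
            if cfg.couple_epi:
                a = truth.coupling_offsets.get(s, 0.0)
                means[:, j] += epi_sign * (cfg.epi_delta_beta + cfg.epi_meth_step * a)
    means = np.clip(means, 0.03, 0.97)

    prec = precision[:, None]
    beta = rng.beta(means * prec, (1.0 - means) * prec)
    beta_df = pd.DataFrame(beta, index=sites.index, columns=samples)
    coords = sites[["chrom", "pos", "gene", "kind"]].copy()
    return beta_df, coords, truth


# ---------------------------------------------------------------------------
# full-study bundle
# ---------------------------------------------------------------------------

@dataclass
class StudyBundle:
    cfg: SimulationConfig
    reference: Dict[str, str]
    annotation: pd.DataFrame
    cpg_islands: pd.DataFrame
    tiles: pd.DataFrame
    calls: Dict[str, Dict[str, List]]
    known_sites: List[Tuple[str, int, str, str]]
    counts: pd.DataFrame
    tpm: pd.DataFrame
    design: pd.DataFrame
    beta: pd.DataFrame
    cpg_coords: pd.DataFrame
    truth: TruthTable


def simulate_study(cfg: SimulationConfig) -> StudyBundle:
    """Generate the complete synthetic study in memory."""
    cfg.validate()
    reference, annotation, islands, tiles = simulate_genome_and_annotation(cfg)
    truth = plan_truth(cfg, annotation)
    calls, known_sites, variant_truth = simulate_caller_vcfs(cfg, reference)
    truth.variants = variant_truth["variants"]
    truth.spectrum = variant_truth["spectrum"]
    counts, tpm, design, truth = simulate_expression(cfg, annotation, truth)
    beta, coords, truth = simulate_methylation(cfg, annotation, truth)
    truth.validate()
    return StudyBundle(
        cfg=cfg, reference=reference, annotation=annotation, cpg_islands=islands,
        tiles=tiles, calls=calls, known_sites=known_sites, counts=counts, tpm=tpm,
        design=design, beta=beta, cpg_coords=coords, truth=truth,
    )


def write_study(bundle: StudyBundle, outdir) -> Dict[str, str]:
    """Write every artifact of the bundle as plain text; returns path map."""
    out = Path(outdir)
    out.mkdir(parents=True, exist_ok=True)
    vcf_dir = out / "vcf"
    vcf_dir.mkdir(exist_ok=True)
    paths: Dict[str, str] = {}

    write_fasta(out / "reference.fa", bundle.reference)
    paths["reference"] = str(out / "reference.fa")

    ann = bundle.annotation.reset_index()[
        ["gene", "chrom", "strand", "tss", "start", "end", "length"]
    ]
    ann.to_csv(out / "annotation.tsv", sep="\t", index=False)
    paths["annotation"] = str(out / "annotation.tsv")

    write_bed(out / "cpg_islands.bed", bundle.cpg_islands)
    write_bed(out / "tiles.bed", bundle.tiles)
    paths["cpg_islands"] = str(out / "cpg_islands.bed")
    paths["tiles"] = str(out / "tiles.bed")

    genes_bed = bundle.annotation.reset_index().rename(columns={"gene": "name"})
    write_bed(out / "genes.bed", genes_bed[["chrom", "start", "end", "name"]])
    paths["genes_bed"] = str(out / "genes.bed")

    for sample, by_caller in bundle.calls.items():
        for caller, records in by_caller.items():
            path = vcf_dir / f"{sample}.{caller}.vcf"
            write_vcf(path, records, bundle.reference)
    paths["vcf_dir"] = str(vcf_dir)
    write_vcf(out / "known_sites.vcf", bundle.known_sites, bundle.reference)
    paths["known_sites"] = str(out / "known_sites.vcf")

    bundle.counts.rename_axis("gene").to_csv(out / "counts.tsv", sep="\t")
    bundle.tpm.rename_axis("gene").to_csv(
        out / "tpm.tsv", sep="\t", float_format="%.6g"
    )
    bundle.design.rename_axis("sample").to_csv(out / "design.tsv", sep="\t")
    bundle.beta.rename_axis("site").to_csv(
        out / "beta.tsv", sep="\t", float_format="%.6g"
    )
    bundle.cpg_coords.rename_axis("site").to_csv(out / "cpg_sites.tsv", sep="\t")
    paths.update(
        counts=str(out / "counts.tsv"), tpm=str(out / "tpm.tsv"),
        design=str(out / "design.tsv"), beta=str(out / "beta.tsv"),
        cpg_sites=str(out / "cpg_sites.tsv"),
    )

    write_gmt(out / "gene_sets.gmt", bundle.truth.modules)
    write_gmt(out / "markers.gmt", bundle.truth.markers)
    paths["gene_sets"] = str(out / "gene_sets.gmt")
    paths["markers"] = str(out / "markers.gmt")

    bundle.truth.to_json(out / "truth.json")
    paths["truth"] = str(out / "truth.json")
    return paths
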