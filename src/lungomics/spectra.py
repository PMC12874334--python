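"""Mutational-spectrum classification: SBS96, DBS78 and ID83 catalogs.

Single-base substitutions are labeled pyrimidine-centrically as
``5'[REF>ALT]3'`` over the six substitution types C>A, C>G, C>T, T>A, T>C,
T>G with both flanking bases, giving 96 classes.  Doublet substitutions are
collapsed to a canonical strand, giving 78 classes.  Indels follow the
83-category convention:

* 1-bp deletions/insertions, subtyped by the pyrimidine of the affected
  base (C or T), binned by homopolymer run length.  For deletions the
  encoded bin is ``min(run_length, 6) - 1`` where ``run_length`` counts the
  deleted base plus adjacent identical bases (so a T deleted from a run of
  six Ts is ``1:Del:T:5``).  For insertions the bin is
  ``min(existing_copies, 5)`` (an inserted C with no adjacent C is
  ``1:Ins:C:0``).
* Longer events, length-binned 2/3/4/5+ and repeat-binned by the number of
  additional copies of the event motif immediately 3' of the (left-aligned)
  event, encoded ``min(copies, 5)``.
* Deletions of length >= 2 with no adjacent repeat copy are checked for
  microhomology: the longest prefix of the deleted sequence matching the
  immediately following reference sequence, capped at min(len-1, 5).

Mutations whose required context contains ``N`` are excluded (never
guessed); complex indels (substitution-like after trimming shared
prefix/suffix) are excluded with a log count.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Dict, Iterable, List, Mapping, Sequence, Tuple

import numpy as np
import pandas as pd

__all__ = [
    "SBS96_CATEGORIES",
    "DBS78_CATEGORIES",
    "ID83_CATEGORIES",
    "SpectrumMatrix",
    "classify_sbs",
    "classify_dbs",
    "classify_indel",
    "build_spectrum",
    "cosine_similarity",
]

_COMPLEMENT = {"A": "T", "C": "G", "G": "C", "T": "A", "N": "N"}


def _revcomp(seq: str) -> str:
    return "".join(_COMPLEMENT[b] for b in reversed(seq))


class SpectrumClassificationError(ValueError):
    """Mutation cannot be placed in the schema (N context / complex event)."""


# ---------------------------------------------------------------------------
# canonical category orderings
# ---------------------------------------------------------------------------

_SBS_SUBS = ("C>A", "C>G", "C>T", "T>A", "T>C", "T>G")
SBS96_CATEGORIES: Tuple[str, ...] = tuple(
    f"{five}[{sub}]{three}"
    for sub in _SBS_SUBS
    for five in "ACGT"
    for three in "ACGT"
)

# canonical doublet classes: 78 representatives on the collapsed strand
DBS78_CATEGORIES: Tuple[str, ...] = tuple(
    f"{ref}>{alt}"
    for ref, alts in (
        ("AC", ("CA", "CG", "CT", "GA", "GG", "GT", "TA", "TG", "TT")),
        ("AT", ("CA", "CC", "CG", "GA", "GC", "TA")),
        ("CC", ("AA", "AG", "AT", "GA", "GG", "GT", "TA", "TG", "TT")),
        ("CG", ("AT", "GC", "GT", "TA", "TC", "TT")),
        ("CT", ("AA", "AC", "AG", "GA", "GC", "GG", "TA", "TC", "TG")),
        ("GC", ("AA", "AG", "AT", "CA", "CG", "TA")),
        ("TA", ("AT", "CG", "CT", "GC", "GG", "GT")),
        ("TC", ("AA", "AG", "AT", "CA", "CG", "CT", "GA", "GG", "GT")),
        ("TG", ("AA", "AC", "AT", "CA", "CC", "CT", "GA", "GC", "GT")),
        ("TT", ("AA", "AC", "AG", "CA", "CC", "CG", "GA", "GC", "GG")),
    )
    for alt in alts
)
_DBS78_SET = frozenset(DBS78_CATEGORIES)


def _id83_order() -> Tuple[str, ...]:
    cats: List[str] = []
    for base in ("C", "T"):
        cats += [f"1:Del:{base}:{k}" for k in range(6)]
    for base in ("C", "T"):
        cats += [f"1:Ins:{base}:{k}" for k in range(6)]
    for length in (2, 3, 4, 5):
        cats += [f"{length}:Del:R:{k}" for k in range(6)]
    for length in (2, 3, 4, 5):
        cats += [f"{length}:Ins:R:{k}" for k in range(6)]
    for length, max_mh in ((2, 1), (3, 2), (4, 3), (5, 5)):
        cats += [f"{length}:Del:M:{k}" for k in range(1, max_mh + 1)]
    return tuple(cats)


ID83_CATEGORIES: Tuple[str, ...] = _id83_order()

_SCHEMA_CATEGORIES = {
    "SBS96": SBS96_CATEGORIES,
    "DBS78": DBS78_CATEGORIES,
    "ID83": ID83_CATEGORIES,
}


# ---------------------------------------------------------------------------
# classifiers
# ---------------------------------------------------------------------------

def classify_sbs(chrom: str, pos: int, ref: str, alt: str,
                 reference: Mapping[str, str]) -> str:
    """Classify a single-base substitution into its SBS96 category.

    ``pos`` is 1-based.  Purine-reference mutations are reverse-complemented
    so the central base is a pyrimidine.
    """
    if len(ref) != 1 or len(alt) != 1 or ref == alt:
        raise ValueError(f"not a single-base substitution: {ref}>{alt}")
    seq = reference[chrom]
    i = pos - 1
    if i < 1 or i >= len(seq) - 1:
        raise SpectrumClassificationError(
            f"context not resolvable at {chrom}:{pos} (chromosome edge)"
        )
    if seq[i] != ref:
        raise ValueError(
            f"reference mismatch at {chrom}:{pos}: expected {ref}, found {seq[i]}"
        )
    tri = seq[i - 1 : i + 2]
    if "N" in tri or alt == "N":
        raise SpectrumClassificationError(f"ambiguous base in context at {chrom}:{pos}")
    if ref in "AG":
        tri = _revcomp(tri)
        ref = _COMPLEMENT[ref]
        alt = _COMPLEMENT[alt]
    return f"{tri[0]}[{ref}>{alt}]{tri[2]}"


def classify_dbs(chrom: str, pos: int, ref: str, alt: str,
                 reference: Mapping[str, str] | None = None) -> str:
    """Classify an adjacent-dinucleotide substitution into DBS78.

    The doublet is mapped to the canonical orientation (reverse complement
    when the as-given representation is not canonical).
    """
    if len(ref) != 2 or len(alt) != 2:
        raise ValueError(f"not a doublet substitution: {ref}>{alt}")
    if ref[0] == alt[0] or ref[1] == alt[1]:
        raise ValueError(
            f"doublet must substitute both positions: {ref}>{alt}"
        )
    if "N" in ref or "N" in alt:
        raise SpectrumClassificationError("ambiguous base in doublet")
    if reference is not None:
        seq = reference[chrom]
        if seq[pos - 1 : pos + 1] != ref:
            raise ValueError(f"reference mismatch at {chrom}:{pos}")
    label = f"{ref}>{alt}"
    if label in _DBS78_SET:
        return label
    rc = f"{_revcomp(ref)}>{_revcomp(alt)}"
    if rc in _DBS78_SET:
        return rc
    raise ValueError(f"doublet {label} not mappable to a canonical class")


def _left_align(i: int, seq_event: str, chrom_seq: str, is_del: bool) -> Tuple[int, str]:
    """Left-align an indel.  ``i`` is the 0-based start of the deleted bases
    (deletion) or of the base before which the insertion occurs (insertion).
    """
    ev = seq_event
    L = len(ev)
    if is_del:
        while i > 0 and chrom_seq[i - 1] == ev[-1]:
            ev = chrom_seq[i - 1] + ev[:-1]
            i -= 1
    else:
        while i > 0 and chrom_seq[i - 1] == ev[-1]:
            ev = ev[-1] + ev[:-1]
            i -= 1
    return i, ev


def classify_indel(chrom: str, pos: int, ref: str, alt: str,
                   reference: Mapping[str, str]) -> str:
    """Classify a pure insertion or deletion (VCF anchored form) into ID83."""
    seq = reference[chrom]
    # trim shared prefix (VCF anchor) and any shared suffix
    r, a = ref, alt
    start = pos - 1
    while r and a and r[0] == a[0]:
        r, a = r[1:], a[1:]
        start += 1
    while r and a and r[-1] == a[-1]:
        r, a = r[:-1], a[:-1]
    if r and a:
        raise SpectrumClassificationError(f"complex indel {ref}>{alt} at {chrom}:{pos}")
    if not r and not a:
        raise ValueError(f"no event after trimming: {ref}>{alt}")

    is_del = bool(r)
    event = r if is_del else a
    if "N" in event:
        raise SpectrumClassificationError("ambiguous base in indel event")
    if is_del and seq[start : start + len(event)] != event:
        raise ValueError(f"reference mismatch for deletion at {chrom}:{pos}")

    start, event = _left_align(start, event, seq, is_del)
    L = len(event)
    # position immediately after the event on the reference
    after = start + L if is_del else start

    if "N" in seq[max(0, start - 1) : after + 6 * L]:
        raise SpectrumClassificationError("ambiguous base adjacent to indel")

    if L == 1:
        base = event
        sub = base if base in "CT" else _COMPLEMENT[base]
        # run of identical bases at/after the event site
        run = 0
        j = after
        while j < len(seq) and seq[j] == base:
            run += 1
            j += 1
        if is_del:
            total = run + 1  # include the deleted copy
            bin_ = min(total, 6) - 1
            return f"1:Del:{sub}:{bin_}"
        bin_ = min(run, 5)
        return f"1:Ins:{sub}:{bin_}"

    len_bin = min(L, 5)
    copies = 0
    j = after
    while seq[j : j + L] == event:
        copies += 1
        j += L
    kind = "Del" if is_del else "Ins"
    if copies > 0 or not is_del:
        return f"{L if L < 5 else 5}:{kind}:R:{min(copies, 5)}"
    # deletion, no full repeat copy: microhomology with the 3' flank
    mh = 0
    flank = seq[after : after + L - 1]
    for k in range(min(L - 1, len(flank)), 0, -1):
        if event[:k] == flank[:k]:
            mh = k
            break
    if mh == 0:
        return f"{len_bin}:Del:R:0"
    return f"{len_bin}:Del:M:{min(mh, 5)}"


# ---------------------------------------------------------------------------
# reachable-label-space enumeration (schema cardinality checks)
# ---------------------------------------------------------------------------

def enumerate_sbs_labels() -> Tuple[set, int]:
    """Run classify_sbs over every substitution x flanking context.

    Returns (distinct labels, number of enumerated inputs).
    """
    import itertools

    labels = set()
    n = 0
    for five, center, three in itertools.product("ACGT", repeat=3):
        for alt in "ACGT":
            if alt == center:
                continue
            labels.add(classify_sbs("chr1", 2, center, alt,
                                    {"chr1": five + center + three}))
            n += 1
    return labels, n


def enumerate_dbs_labels() -> Tuple[set, int]:
    """Run classify_dbs over every valid adjacent-dinucleotide substitution."""
    import itertools

    labels = set()
    n = 0
    for ref in ("".join(p) for p in itertools.product("ACGT", repeat=2)):
        for alt in ("".join(p) for p in itertools.product("ACGT", repeat=2)):
            if alt[0] == ref[0] or alt[1] == ref[1]:
                continue
            labels.add(classify_dbs("chr1", 1, ref, alt))
            n += 1
    return labels, n


def enumerate_indel_labels() -> Tuple[set, int]:
    """Run classify_indel over constructed events covering every reachable
    combination of type, length bin, repeat bin and microhomology bin."""
    labels = set()
    n = 0

    def flank(base: str) -> str:
        return "G" if base != "G" else "C"

    # 1-bp deletions in homopolymer runs of length 1..7
    for base in "ACGT":
        f = flank(base)
        for k in range(1, 8):
            seq = f + base * k + f
            labels.add(classify_indel("chr1", 1, f + base, f, {"chr1": seq}))
            n += 1
    # 1-bp insertions next to 0..6 existing copies
    for base in "ACGT":
        f = flank(base)
        for k in range(0, 7):
            seq = f + base * k + f
            labels.add(classify_indel("chr1", 1, f, f + base, {"chr1": seq}))
            n += 1
    # longer events: motifs start with A (no microhomology with the G flank)
    # and end with C (no left-shift past the T anchor)
    motifs = {L: "A" + "C" * (L - 1) for L in range(2, 7)}
    for L, motif in motifs.items():
        for copies in range(0, 7):
            seq = "T" + motif * (copies + 1) + "G" * 6
            labels.add(classify_indel("chr1", 1, "T" + motif, "T", {"chr1": seq}))
            n += 1
            ins_seq = "T" + motif * copies + "G" * 6
            labels.add(classify_indel("chr1", 1, "T", "T" + motif,
                                      {"chr1": ins_seq}))
            n += 1
        for mh in range(1, L):
            seq = "T" + motif + motif[:mh] + "G" * 6
            labels.add(classify_indel("chr1", 1, "T" + motif, "T", {"chr1": seq}))
            n += 1
    return labels, n


# ---------------------------------------------------------------------------
# spectrum matrices
# ---------------------------------------------------------------------------

@dataclass
class SpectrumMatrix:
    """Category x sample count matrix for one classification schema."""

    schema: str
    categories: Tuple[str, ...]
    samples: List[str]
    counts: np.ndarray  # (n_categories, n_samples) int
    excluded: Dict[str, int] = field(default_factory=dict)

    def to_frame(self) -> pd.DataFrame:
        """SigProfiler-style layout: MutationType column + one per sample."""
        df = pd.DataFrame(self.counts, columns=self.samples)
        df.insert(0, "MutationType", list(self.categories))
        return df

    def column(self, sample: str) -> np.ndarray:
        return self.counts[:, self.samples.index(sample)].astype(float)


def _mutation_kind(ref: str, alt: str) -> str:
    if len(ref) == 1 and len(alt) == 1:
        return "sbs"
    if len(ref) == 2 and len(alt) == 2 and ref[0] != alt[0] and ref[1] != alt[1]:
        return "dbs"
    if len(ref) != len(alt):
        return "indel"
    return "mnv"


def build_spectrum(records: pd.DataFrame, reference: Mapping[str, str],
                   schema: str) -> SpectrumMatrix:
    """Build a spectrum matrix from a mutation table.

    ``records`` needs columns chrom, pos, ref, alt, sample.  Mutations of a
    different event class than the schema are ignored; mutations of the
    right class that cannot be classified (N context, complex indel) are
    counted per sample in ``excluded``.
    """
    schema = schema.upper()
    if schema not in _SCHEMA_CATEGORIES:
        raise ValueError(f"unknown schema {schema!r}")
    categories = _SCHEMA_CATEGORIES[schema]
    cat_index = {c: i for i, c in enumerate(categories)}
    samples = sorted(records["sample"].unique()) if len(records) else []
    counts = np.zeros((len(categories), len(samples)), dtype=int)
    excluded = {s: 0 for s in samples}
    want = {"SBS96": "sbs", "DBS78": "dbs", "ID83": "indel"}[schema]
    classify = {
        "SBS96": classify_sbs,
        "DBS78": classify_dbs,
        "ID83": classify_indel,
    }[schema]

    for row in records.itertuples(index=False):
        ref, alt = str(row.ref), str(row.alt)
        if _mutation_kind(ref, alt) != want:
            continue
        j = samples.index(row.sample)
        try:
            label = classify(str(row.chrom), int(row.pos), ref, alt, reference)
        except SpectrumClassificationError:
            excluded[row.sample] += 1
            continue
        counts[cat_index[label], j] += 1
    return SpectrumMatrix(schema, categories, samples, counts, excluded)


def cosine_similarity(a, b) -> float:
    """dot(a, b) / (||a|| * ||b||); scale-invariant, zero vectors rejected."""
    a = np.asarray(a, dtype=float).ravel()
    b = np.asarray(b, dtype=float).ravel()
    if a.shape != b.shape:
        raise ValueError("vectors must have equal length")
    if np.any(a < 0) or np.any(b < 0):
        raise ValueError("spectrum vectors must be non-negative")
    na, nb = np.linalg.norm(a), np.linalg.norm(b)
    if na == 0 or nb == 0:
        raise ValueError("cosine similarity undefined for a zero vector")
    return float(np.dot(a, b) / (na * nb))


def pairwise_cosine_table(spectrum: SpectrumMatrix) -> pd.DataFrame:
    """All-pairs cosine similarities between sample columns."""
    rows = []
    for i, si in enumerate(spectrum.samples):
        for sj in spectrum.samples[i + 1 :]:
            rows.append(
                {
                    "sample_a": si,
                    "sample_b": sj,
                    "cosine": cosine_similarity(
                        spectrum.column(si), spectrum.column(sj)
                    ),
                }
            )
    return pd.DataFrame(rows, columns=["sample_a", "sample_b", "cosine"])
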