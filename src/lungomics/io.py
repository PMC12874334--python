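"""Small text-format helpers shared across modules (FASTA, GMT, BED)."""

from __future__ import annotations

from pathlib import Path
from typing import Dict, List, Tuple

import pandas as pd
from pyfaidx import Fasta

__all__ = [
    "load_fasta",
    "write_fasta",
    "read_gmt",
    "write_gmt",
    "read_bed",
    "write_bed",
]


def load_fasta(path) -> Dict[str, str]:
    """Load a FASTA file into a dict of uppercase chromosome strings."""
    with Fasta(str(path), as_raw=True, sequence_always_upper=True) as fa:
        return {name: str(fa[name][:]) for name in fa.keys()}


def write_fasta(path, sequences: Dict[str, str], width: int = 80) -> None:
    with open(path, "w") as fh:
        for name, seq in sequences.items():
            fh.write(f">{name}\n")
            for i in range(0, len(seq), width):
                fh.write(seq[i : i + width] + "\n")


def read_gmt(path) -> Dict[str, List[str]]:
    """Read gene sets from GMT (name, description, members...)."""
    sets: Dict[str, List[str]] = {}
    for line in Path(path).read_text().splitlines():
        if not line.strip():
            continue
        fields = line.rstrip("\n").split("\t")
        if len(fields) < 3:
            raise ValueError(f"malformed GMT line: {line!r}")
        sets[fields[0]] = [g for g in fields[2:] if g]
    return sets


def write_gmt(path, sets: Dict[str, List[str]], description: str = "na") -> None:
    with open(path, "w") as fh:
        for name, members in sets.items():
            fh.write("\t".join([name, description] + list(members)) + "\n")


def read_bed(path) -> pd.DataFrame:
    """Read a BED-like file: chrom, start, end[, name]; half-open intervals."""
    df = pd.read_csv(path, sep="\t", header=None, comment="#")
    cols = ["chrom", "start", "end", "name"][: df.shape[1]]
    df.columns = cols + list(df.columns[len(cols) :])
    if "name" not in df.columns:
        df["name"] = [f"region_{i}" for i in range(len(df))]
    return df[["chrom", "start", "end", "name"]]


def write_bed(path, df: pd.DataFrame) -> None:
    df[["chrom", "start", "end", "name"]].to_csv(
        path, sep="\t", header=False, index=False
    )
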