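"""File formats and coordinate conventions.

TSV tables carry a mandatory header row, UTF-8, LF line endings, '.' for
missing values. FASTA is parsed case-insensitively, wrapped or unwrapped,
with record ids cut at the first whitespace. Alignment coordinates are
1-based inclusive on disk (BLAST convention) and 0-based half-open
in memory.
"""

from __future__ import annotations

from pathlib import Path
from typing import Mapping

import pandas as pd
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

__all__ = [
    "read_tsv",
    "write_tsv",
    "read_fasta",
    "write_fasta",
    "to_internal_coords",
    "to_file_coords",
]

MISSING = "."


def read_tsv(path: str | Path, **kwargs) -> pd.DataFrame:
    # only '.' marks missing data; tokens like 'null' are real values here
    return pd.read_csv(path, sep="\t", na_values=[MISSING], keep_default_na=False, **kwargs)


def write_tsv(frame: pd.DataFrame, path: str | Path, index: bool = False) -> None:
    Path(path).parent.mkdir(parents=True, exist_ok=True)
    frame.to_csv(path, sep="\t", index=index, na_rep=MISSING, lineterminator="\n")


def read_fasta(path: str | Path) -> dict[str, str]:
    """Sequences keyed by id (first whitespace-delimited token), uppercased."""
    return {rec.id: str(rec.seq).upper() for rec in SeqIO.parse(str(path), "fasta")}


def write_fasta(sequences: Mapping[str, str], path: str | Path, width: int = 80) -> None:
    Path(path).parent.mkdir(parents=True, exist_ok=True)
    records = [
        SeqRecord(Seq(seq), id=name, description="") for name, seq in sequences.items()
    ]
    with open(path, "w", newline="\n") as handle:
        writer = SeqIO.FastaIO.FastaWriter(handle, wrap=width)
        writer.write_file(records)


def to_internal_coords(start_1based: int, end_1based: int) -> tuple[int, int]:
    """1-based inclusive -> 0-based half-open."""
    if start_1based < 1 or end_1based < start_1based:
        raise ValueError(f"bad 1-based interval [{start_1based}, {end_1based}]")
    return start_1based - 1, end_1based


def to_file_coords(start_0based: int, end_0based: int) -> tuple[int, int]:
    """0-based half-open -> 1-based inclusive."""
    if start_0based < 0 or end_0based <= start_0based:
        raise ValueError(f"bad 0-based interval [{start_0based}, {end_0based})")
    return start_0based + 1, end_0based
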