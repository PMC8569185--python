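"""FASTA and tabular I/O.

FASTA reading accepts wrapped and unwrapped dialects and uppercases sequences;
writing wraps at 60 columns. All coordinates written to output tables are
1-based inclusive (BLAST convention); internal computation is 0-based
half-open, and this module is the boundary where the convention changes.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Sequence

import pandas as pd
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

from blennymine.exceptions import InputError

FASTA_WRAP = 60


@dataclass(frozen=True)
class FastaRecord:
    id: str
    sequence: str


def read_fasta(path: str | Path) -> list[FastaRecord]:
    """Read a (possibly line-wrapped) FASTA file; sequences are uppercased.

    Raises :class:`InputError` with a line number if sequence data precedes
    the first header.
    """
    path = Path(path)
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            stripped = line.strip()
            if not stripped:
                continue
            if not stripped.startswith(">"):
                raise InputError(
                    f"{path}:{lineno}: sequence data before first FASTA header"
                )
            break
    records = [
        FastaRecord(id=rec.id, sequence=str(rec.seq).upper())
        for rec in SeqIO.parse(str(path), "fasta")
    ]
    return records


def write_fasta(records: Iterable[FastaRecord], path: str | Path) -> None:
    """Write records wrapped at 60 columns; round-trips with :func:`read_fasta`."""
    seqrecords = [
        SeqRecord(Seq(rec.sequence), id=rec.id, description="") for rec in records
    ]
    with open(path, "w") as fh:
        writer = SeqIO.FastaIO.FastaWriter(fh, wrap=FASTA_WRAP)
        writer.write_file(seqrecords)


def read_metadata_tsv(path: str | Path) -> pd.DataFrame:
    """Read the 3-column contig metadata table (contig_id, species, taxon)."""
    df = pd.read_csv(path, sep="\t", dtype=str)
    required = {"contig_id", "species", "taxon"}
    missing = required - set(df.columns)
    if missing:
        raise InputError(f"metadata table missing columns: {sorted(missing)}")
    if df["contig_id"].duplicated().any():
        dup = df.loc[df["contig_id"].duplicated(), "contig_id"].iloc[0]
        raise InputError(f"duplicate contig_id in metadata: {dup}")
    return df


def write_tsv(df: pd.DataFrame, path: str | Path) -> None:
    df.to_csv(path, sep="\t", index=False)


def read_tsv(path: str | Path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t")


def write_long_csv(df: pd.DataFrame, path: str | Path) -> None:
    """Write a long-format assay table (dataset_id, replicate, x, channel, value)."""
    df.to_csv(path, index=False)


def read_long_csv(path: str | Path) -> pd.DataFrame:
    return pd.read_csv(path)


def checksum_file(path: str | Path) -> str:
    import hashlib

    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(1 << 16), b""):
            h.update(chunk)
    return h.hexdigest()


def ensure_columns(df: pd.DataFrame, columns: Sequence[str], what: str) -> None:
    missing = set(columns) - set(df.columns)
    if missing:
        raise InputError(f"{what} missing columns: {sorted(missing)}")
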