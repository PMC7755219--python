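"""Readers and writers for the plain-text formats the pipeline exchanges.

FASTA/FASTQ go through Biopython; BED6 and bedGraph are emitted with
0-based half-open coordinates and six-significant-digit scores so
round-trips are bit-exact for the dialects written here.
"""
from __future__ import annotations

import logging
import os

import numpy as np
import pandas as pd
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

log = logging.getLogger(__name__)

_FASTA_EXT = {".fa", ".fasta", ".fna"}
_FASTQ_EXT = {".fq", ".fastq"}

BED_COLUMNS = ["chrom", "start", "end", "name", "score", "strand"]


def detect_format(path) -> str:
    ext = os.path.splitext(str(path))[1].lower()
    if ext in _FASTA_EXT:
        return "fasta"
    if ext in _FASTQ_EXT:
        return "fastq"
    return "plain"


def read_sequences(path, fmt: str | None = None) -> list:
    """Read reads from FASTA, FASTQ or plain text (one read per line).

    Sequences are uppercased.  Blank lines in plain text are skipped
    with a log message.
    """
    fmt = fmt or detect_format(path)
    if fmt in ("fasta", "fastq"):
        return [str(rec.seq).upper() for rec in SeqIO.parse(str(path), fmt)]
    if fmt != "plain":
        raise ValueError(f"unknown sequence format {fmt!r}")
    out = []
    blanks = 0
    with open(path) as fh:
        for line in fh:
            line = line.strip()
            if not line:
                blanks += 1
                continue
            out.append(line.upper())
    if blanks:
        log.info("skipped %d blank line(s) in %s", blanks, path)
    return out


def write_sequences(seqs, path, fmt: str | None = None, prefix: str = "read") -> None:
    fmt = fmt or detect_format(path)
    if fmt == "fasta":
        records = (
            SeqRecord(Seq(s), id=f"{prefix}_{i + 1}", description="")
            for i, s in enumerate(seqs)
        )
        SeqIO.write(records, str(path), "fasta")
    elif fmt == "fastq":
        records = []
        for i, s in enumerate(seqs):
            rec = SeqRecord(Seq(s), id=f"{prefix}_{i + 1}", description="")
            rec.letter_annotations["phred_quality"] = [40] * len(s)
            records.append(rec)
        SeqIO.write(records, str(path), "fastq")
    elif fmt == "plain":
        with open(path, "w") as fh:
            for s in seqs:
                fh.write(s + "\n")
    else:
        raise ValueError(f"unknown sequence format {fmt!r}")


def read_fasta_genome(path) -> dict:
    """Contig name -> uppercase sequence (whole file in memory)."""
    return {rec.id: str(rec.seq).upper() for rec in SeqIO.parse(str(path), "fasta")}


def open_genome_indexed(path):
    """Random-access genome via a pyfaidx index (built on first use).

    Preferred over :func:`read_fasta_genome` for large contigs: slices
    are read from disk on demand.
    """
    from pyfaidx import Fasta

    return Fasta(str(path), sequence_always_upper=True)


def write_fasta_genome(contigs: dict, path) -> None:
    records = (SeqRecord(Seq(s), id=name, description="") for name, s in contigs.items())
    SeqIO.write(records, str(path), "fasta")


def read_bed(path) -> pd.DataFrame:
    """BED with >= 3 columns; validates 0 <= start < end per line."""
    rows = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.rstrip("\n")
            if not line or line.startswith(("#", "track", "browser")):
                continue
            parts = line.split("\t")
            if len(parts) < 3:
                raise ValueError(f"{path}:{lineno}: BED needs >= 3 columns")
            chrom, start, end = parts[0], int(parts[1]), int(parts[2])
            if start < 0:
                raise ValueError(f"{path}:{lineno}: negative coordinate")
            if start >= end:
                raise ValueError(f"{path}:{lineno}: start >= end")
            name = parts[3] if len(parts) > 3 else "."
            score = float(parts[4]) if len(parts) > 4 else 0.0
            strand = parts[5] if len(parts) > 5 else "."
            rows.append((chrom, start, end, name, score, strand))
    return pd.DataFrame(rows, columns=BED_COLUMNS)


def _fmt_score(x) -> str:
    if isinstance(x, (int, np.integer)) or float(x).is_integer():
        return str(int(x))
    return f"{float(x):.6g}"


def write_bed(df: pd.DataFrame, path) -> None:
    with open(path, "w") as fh:
        for row in df.itertuples(index=False):
            name = getattr(row, "name", ".")
            score = getattr(row, "score", 0)
            strand = getattr(row, "strand", ".")
            fh.write(
                f"{row.chrom}\t{int(row.start)}\t{int(row.end)}\t{name}"
                f"\t{_fmt_score(score)}\t{strand}\n"
            )


def write_bedgraph(track, path) -> None:
    """bedGraph of a genome track; runs of equal values are collapsed and
    NaN (non-ACGT) slots are omitted."""
    values = track.values
    with open(path, "w") as fh:
        fh.write(f'track type=bedGraph name="{track.contig}_genomescape"\n')
        i, n = 0, len(values)
        while i < n:
            if np.isnan(values[i]):
                i += 1
                continue
            j = i + 1
            while j < n and not np.isnan(values[j]) and values[j] == values[i]:
                j += 1
            fh.write(f"{track.contig}\t{i}\t{j}\t{_fmt_score(values[i])}\n")
            i = j
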