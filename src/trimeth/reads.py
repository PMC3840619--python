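"""Read containers and sequencing-read format I/O.

Supported input formats: FASTQ, FASTA, Illumina qseq (tab-separated,
sequence in field 9, '.' meaning N) and raw one-sequence-per-line text.
"""

from __future__ import annotations

import gzip
import logging
from dataclasses import dataclass, replace
from pathlib import Path
from typing import IO, Iterator

from Bio import SeqIO

log = logging.getLogger(__name__)

_CLEAN = str.maketrans({c: "N" for c in "BDEFHIJKLMOPQRSUVWXYZ."})


def _normalize(seq: str) -> str:
    """Uppercase and collapse anything outside ACGT to N."""
    return seq.upper().translate(_CLEAN)


@dataclass
class Read:
    """A sequencing read (optionally one mate of a pair)."""

    id: str
    seq: str
    qual: str | None = None
    mate: int | None = None
    #: original (pre-conversion) sequence, carried by converted copies so
    #: mismatches can be recounted on real letters
    orig_seq: str | None = None

    def __post_init__(self):
        if self.qual is not None and len(self.qual) != len(self.seq):
            raise ValueError(
                f"read {self.id!r}: quality length {len(self.qual)} != "
                f"sequence length {len(self.seq)}"
            )

    def __len__(self) -> int:
        return len(self.seq)

    def truncated(self, n: int) -> "Read":
        """Copy truncated to the first ``n`` bases (quality trimmed along)."""
        return replace(
            self, seq=self.seq[:n], qual=self.qual[:n] if self.qual else None
        )


def _open_text(path: str | Path) -> IO[str]:
    path = Path(path)
    if path.suffix == ".gz":
        return gzip.open(path, "rt")
    return open(path)


def sniff_format(path: str | Path) -> str:
    """Guess the read format from the file extension, else the first byte."""
    name = Path(path).name.lower()
    if name.endswith(".gz"):
        name = name[:-3]
    for fmt, exts in {
        "fastq": (".fastq", ".fq"),
        "fasta": (".fasta", ".fa", ".fna"),
        "qseq": (".qseq",),
        "raw": (".seq", ".txt", ".raw"),
    }.items():
        if name.endswith(exts):
            return fmt
    with _open_text(path) as fh:
        first = fh.read(1)
    if first == "@":
        return "fastq"
    if first == ">":
        return "fasta"
    return "raw"


def read_reads(path: str | Path, fmt: str = "auto") -> Iterator[Read]:
    """Stream reads from any supported format, sequences normalized to
    uppercase ACGTN."""
    if fmt == "auto":
        fmt = sniff_format(path)
    if fmt in ("fastq", "fasta"):
        with _open_text(path) as fh:
            for rec in SeqIO.parse(fh, fmt):
                qual = None
                if fmt == "fastq":
                    qual = "".join(
                        chr(q + 33) for q in rec.letter_annotations["phred_quality"]
                    )
                yield Read(id=rec.id, seq=_normalize(str(rec.seq)), qual=qual)
    elif fmt == "qseq":
        with _open_text(path) as fh:
            for i, line in enumerate(fh):
                fields = line.rstrip("\n").split("\t")
                if len(fields) < 10:
                    raise ValueError(
                        f"{path}: qseq line {i + 1} has {len(fields)} fields, "
                        f"expected >= 10"
                    )
                rid = "_".join(fields[0:6])
                yield Read(id=rid, seq=_normalize(fields[8]), qual=fields[9])
    elif fmt == "raw":
        with _open_text(path) as fh:
            for i, line in enumerate(fh):
                seq = line.strip()
                if seq:
                    yield Read(id=f"seq_{i + 1}", seq=_normalize(seq))
    else:
        raise ValueError(f"unknown read format: {fmt!r}")


def write_fastq(reads, path: str | Path) -> None:
    path = Path(path)
    opener = gzip.open if path.suffix == ".gz" else open
    with opener(path, "wt") as fh:
        for read in reads:
            qual = read.qual or "I" * len(read.seq)
            fh.write(f"@{read.id}\n{read.seq}\n+\n{qual}\n")
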