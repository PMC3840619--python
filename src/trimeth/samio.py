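"""SAM text output and re-parsing of alignment records.

Reverse-placed reads (tags C_BS and C_BS_RC) are stored reverse-complemented
in SEQ with the CIGAR reversed, per SAM convention; the XM methylation
string stays in the read's native orientation.  Tags written per record:

====  =============================================
XO:Z  bisulfite strand tag (W_BS/C_BS/W_BS_RC/C_BS_RC)
XM:Z  per-read methylation string
NM:i  bisulfite-aware mismatch count
XS:i  1 when the read is densely unconverted (default filter thresholds)
ZS:i  three-letter alignment score
ZM:i  three-letter mismatch count
====  =============================================
"""

from __future__ import annotations

from pathlib import Path
from typing import Iterable

import pysam

from .align import IS_REVERSE, AlignmentHit, AlignmentRecord
from .genome import ReferenceGenome, revcomp
from .reads import Read

_CIGAR_OP = {0: "M", 1: "I", 2: "D", 4: "S"}
_OP_CODE = {v: k for k, v in _CIGAR_OP.items()}


def _cigar_string(ops, reverse: bool) -> str:
    seq = reversed(ops) if reverse else ops
    return "".join(f"{n}{op}" for op, n in seq) or "*"


def write_sam(
    records: Iterable[AlignmentRecord],
    genome: ReferenceGenome,
    path: str | Path,
    command_line: str = "",
    include_unmapped: bool = False,
) -> None:
    """Write alignment records as SAM text.

    Unique records get full coordinates; multiple/unmapped records are only
    written (as flag-4 lines) when ``include_unmapped`` is set.
    """
    from .methcall import classify_conversion

    with open(path, "w") as fh:
        fh.write("@HD\tVN:1.6\tSO:unsorted\n")
        for name in genome.chrom_names:
            fh.write(f"@SQ\tSN:{name}\tLN:{genome.lengths[name]}\n")
        cl = f"\tCL:{command_line}" if command_line else ""
        fh.write(f"@PG\tID:trimeth\tPN:trimeth{cl}\n")
        for rec in records:
            read = rec.read
            if rec.status != "unique" or rec.hit is None:
                if include_unmapped:
                    flag = 4
                    if read.mate == 1:
                        flag |= 0x1 | 0x40
                    elif read.mate == 2:
                        flag |= 0x1 | 0x80
                    qual = read.qual or "*"
                    fh.write(
                        f"{read.id}\t{flag}\t*\t0\t0\t*\t*\t0\t0\t{read.seq}\t{qual}"
                        f"\tYF:Z:{rec.reason or rec.status}\n"
                    )
                continue
            hit = rec.hit
            reverse = IS_REVERSE[hit.tag]
            flag = 16 if reverse else 0
            if read.mate == 1:
                flag |= 0x1 | 0x2 | 0x40 | (0 if reverse else 0x20)
            elif read.mate == 2:
                flag |= 0x1 | 0x2 | 0x80 | (0 if reverse else 0x20)
            seq = revcomp(read.seq) if reverse else read.seq
            qual = (read.qual[::-1] if reverse else read.qual) if read.qual else "*"
            xs = 1 if classify_conversion(rec.meth_string or "") == "dense" else 0
            fh.write(
                f"{read.id}\t{flag}\t{hit.chrom}\t{hit.pos + 1}\t255\t"
                f"{_cigar_string(hit.ops, reverse)}\t*\t0\t0\t{seq}\t{qual}\t"
                f"XO:Z:{hit.tag}\tXM:Z:{rec.meth_string}\tNM:i:{rec.bs_mismatches}\t"
                f"XS:i:{xs}\tZS:i:{hit.score}\tZM:i:{hit.three_letter_mismatches}\n"
            )


def read_sam(path: str | Path) -> list[AlignmentRecord]:
    """Re-parse a SAM file written by :func:`write_sam` into records."""
    records: list[AlignmentRecord] = []
    with pysam.AlignmentFile(str(path), "r", check_sq=False) as sam:
        for seg in sam:
            mate = 1 if seg.is_read1 else (2 if seg.is_read2 else None)
            if seg.is_unmapped:
                reason = seg.get_tag("YF") if seg.has_tag("YF") else None
                records.append(
                    AlignmentRecord(
                        read=Read(
                            id=seg.query_name,
                            seq=seg.query_sequence or "",
                            qual=None,
                            mate=mate,
                        ),
                        status="multiple" if reason == "multiple" else "unmapped",
                        reason=reason,
                    )
                )
                continue
            tag = seg.get_tag("XO")
            reverse = IS_REVERSE[tag]
            ops = tuple(
                (_CIGAR_OP[code], n) for code, n in (seg.cigartuples or ())
            )
            if reverse:
                ops = tuple(reversed(ops))
            seq = seg.query_sequence
            qual = (
                pysam.qualities_to_qualitystring(seg.query_qualities)
                if seg.query_qualities is not None
                else None
            )
            if reverse:
                seq = revcomp(seq)
                qual = qual[::-1] if qual else None
            hit = AlignmentHit(
                read_id=seg.query_name,
                chrom=seg.reference_name,
                pos=seg.reference_start,
                tag=tag,
                ops=ops,
                score=int(seg.get_tag("ZS")) if seg.has_tag("ZS") else 0,
                three_letter_mismatches=int(seg.get_tag("ZM")) if seg.has_tag("ZM") else 0,
            )
            records.append(
                AlignmentRecord(
                    read=Read(id=seg.query_name, seq=seq, qual=qual, mate=mate),
                    status="unique",
                    hit=hit,
                    bs_mismatches=int(seg.get_tag("NM")),
                    meth_string=seg.get_tag("XM"),
                )
            )
    return records
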