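"""Pileup of unique alignments and per-cytosine methylation calling.

Every uniquely aligned read contributes its original bases to a per-position
pileup, kept separately for the two bisulfite origin strands: a cytosine on
the Watson strand is read out by W_BS (directly) and C_BS_RC (as its
complement) reads, a Crick cytosine by C_BS and W_BS_RC reads.  Counts are
stored in the origin strand's own letters, so a methylated cytosine is
always a C count and a converted one a T count, regardless of which physical
strand was sequenced.

At each genomic cytosine the methylation level is ``mC / (mC + uC)`` where
mC is the retained-C count and uC the converted-T count on the cytosine's
own strand; other bases (sequencing errors) are excluded from coverage.
Cytosines are stratified by context — CG, CHG or CHH with H in {A,C,T} —
read 5'->3' on the cytosine's strand.

Incomplete bisulfite conversion inflates apparent methylation.  Reads in
which unconverted non-CpG cytosines are *densely* distributed are almost
always conversion failures of a whole molecule (e.g. through secondary
structure) rather than genuine methylation, while sporadic unconverted sites
may be real or random failures.  :func:`classify_conversion` separates the
two groups from the per-read methylation string and the pileup can drop the
dense group on request.

Output formats (tab-separated, no header, 1-based positions):

CGmap     chrom, nucleotide (C = Watson cytosine, G = Crick cytosine), pos,
          context, dinucleotide, level, mC, coverage
ATCGmap   chrom, reference nucleotide, pos, context, dinucleotide,
          Watson A/T/C/G counts, Crick A/T/C/G counts, level or "na"
WIG       variableStep, one "<pos> <level>" line per covered cytosine
"""

from __future__ import annotations

import gzip
import logging
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Iterator

from .align import ORIGIN_STRAND, IS_REVERSE, AlignmentRecord, _walk
from .genome import ReferenceGenome, complement

log = logging.getLogger(__name__)

_BASES = "ATCG"
_BASE_IDX = {b: i for i, b in enumerate(_BASES)}


@dataclass
class ConversionFilterParams:
    """Thresholds for the dense-unconverted-read filter (off by default)."""

    min_unconverted_ch: int = 5
    min_unconverted_fraction: float = 0.5
    enabled: bool = False


def classify_conversion(meth_string: str, params: ConversionFilterParams | None = None) -> str:
    """Classify a read as clean / sporadic / dense from its methylation string.

    ``u`` counts unconverted non-CpG cytosines (X, H); ``t`` counts all
    non-CpG cytosine observations (X, x, H, h).  A read is *dense* when
    ``u >= min_unconverted_ch`` and ``u/t >= min_unconverted_fraction``,
    *clean* when u == 0 (or the read covers no CH site), else *sporadic*.
    """
    params = params or ConversionFilterParams()
    u = sum(meth_string.count(c) for c in "XH")
    t = u + sum(meth_string.count(c) for c in "xh")
    if t == 0 or u == 0:
        return "clean"
    if u >= params.min_unconverted_ch and u / t >= params.min_unconverted_fraction:
        return "dense"
    return "sporadic"


class SiteCounts:
    """Per-position A/T/C/G pileup counts split by bisulfite origin strand.

    Counts for Crick-origin reads are stored in Crick-strand letters (a
    methylated Crick cytosine is a C count even though the Watson reference
    shows G at that position).
    """

    def __init__(self):
        self._counts: dict[str, dict[int, list[int]]] = {}
        self.n_reads = 0
        self.n_filtered = 0

    def add(self, chrom: str, pos: int, origin: str, base: str) -> None:
        if base not in _BASE_IDX:
            return  # N observations carry no base information
        row = self._counts.setdefault(chrom, {}).setdefault(pos, [0] * 8)
        offset = 0 if origin == "watson" else 4
        row[offset + _BASE_IDX[base]] += 1

    def get(self, chrom: str, pos: int) -> tuple[tuple[int, int, int, int], tuple[int, int, int, int]]:
        row = self._counts.get(chrom, {}).get(pos, [0] * 8)
        return tuple(row[:4]), tuple(row[4:])

    def positions(self, chrom: str) -> list[int]:
        return sorted(self._counts.get(chrom, {}))

    def chroms(self) -> list[str]:
        return list(self._counts)


def pileup(
    records: Iterable[AlignmentRecord],
    genome: ReferenceGenome,
    filter_params: ConversionFilterParams | None = None,
) -> SiteCounts:
    """Accumulate the pileup from unique alignments.

    When the conversion filter is enabled, dense reads are excluded (their
    records are marked ``filtered`` and counted in ``SiteCounts.n_filtered``).
    Overlapping columns of a mate pair are counted once, mate 1 winning.
    """
    filter_params = filter_params or ConversionFilterParams()
    counts = SiteCounts()
    mate1_span: dict[str, tuple[str, int, int]] = {}
    for rec in records:
        if rec.status != "unique" or rec.hit is None:
            continue
        hit = rec.hit
        if hit.pos < 0 or hit.pos + hit.ref_span > genome.lengths[hit.chrom]:
            raise ValueError(
                f"alignment of {hit.read_id!r} at {hit.chrom}:{hit.pos} lies "
                f"outside the genome — corrupt input"
            )
        if filter_params.enabled and rec.meth_string is not None:
            if classify_conversion(rec.meth_string, filter_params) == "dense":
                rec.status = "filtered"
                counts.n_filtered += 1
                continue
        skip: tuple[int, int] | None = None
        if rec.read.mate == 1:
            mate1_span[hit.read_id] = (hit.chrom, hit.pos, hit.pos + hit.ref_span)
        elif rec.read.mate == 2:
            prev = mate1_span.get(hit.read_id)
            if prev and prev[0] == hit.chrom:
                skip = (prev[1], prev[2])
        origin = ORIGIN_STRAND[hit.tag]
        # native letters match the origin-strand orientation for W_BS/C_BS;
        # the _RC tags observe the complement of the origin strand
        needs_complement = hit.tag.endswith("_RC")
        reverse = IS_REVERSE[hit.tag]
        span = hit.ref_span
        for kind, rb, g in _walk(hit, rec.read.seq):
            if kind != "M":
                continue
            w = hit.pos + span - 1 - g if reverse else hit.pos + g
            if skip and skip[0] <= w < skip[1]:
                continue
            counts.add(hit.chrom, w, origin, complement(rb) if needs_complement else rb)
        counts.n_reads += 1
    return counts


def context_of(
    genome: ReferenceGenome, chrom: str, pos: int, strand: str
) -> tuple[str, str] | None:
    """Cytosine context at a position, read 5'->3' on the given strand.

    Returns (context, dinucleotide) with context in {CG, CHG, CHH}, or None
    when the needed neighbors run off the chromosome or contain N.  The
    position must hold C on the Watson strand (``strand='watson'``) or G
    (``strand='crick'``, i.e. a Crick-strand cytosine).
    """
    seq = genome[chrom]
    if strand == "watson":
        if seq[pos] != "C":
            raise ValueError(f"{chrom}:{pos} is not a Watson-strand cytosine")
        n1 = seq[pos + 1] if pos + 1 < len(seq) else None
        n2 = seq[pos + 2] if pos + 2 < len(seq) else None
    elif strand == "crick":
        if seq[pos] != "G":
            raise ValueError(f"{chrom}:{pos} is not a Crick-strand cytosine")
        n1 = complement(seq[pos - 1]) if pos >= 1 else None
        n2 = complement(seq[pos - 2]) if pos >= 2 else None
    else:
        raise ValueError(f"unknown strand {strand!r}")
    if n1 is None or n1 == "N":
        return None
    dinuc = "C" + n1
    if n1 == "G":
        return "CG", dinuc
    if n2 is None or n2 == "N":
        return None
    return ("CHG" if n2 == "G" else "CHH"), dinuc


@dataclass(frozen=True)
class CGmapRecord:
    """One cytosine row of a CGmap file (``pos`` is 1-based)."""

    chrom: str
    nucleotide: str  # C = cytosine on Watson, G = cytosine on Crick
    pos: int
    context: str
    dinucleotide: str
    level: float
    mc: int
    coverage: int

    def line(self) -> str:
        return (
            f"{self.chrom}\t{self.nucleotide}\t{self.pos}\t{self.context}\t"
            f"{self.dinucleotide}\t{self.level!r}\t{self.mc}\t{self.coverage}"
        )

    @classmethod
    def parse(cls, line: str) -> "CGmapRecord":
        f = line.rstrip("\n").split("\t")
        return cls(f[0], f[1], int(f[2]), f[3], f[4], float(f[5]), int(f[6]), int(f[7]))


@dataclass(frozen=True)
class ATCGmapRecord:
    """One covered-position row of an ATCGmap file (``pos`` is 1-based)."""

    chrom: str
    nucleotide: str
    pos: int
    context: str
    dinucleotide: str
    watson: tuple[int, int, int, int]  # A, T, C, G
    crick: tuple[int, int, int, int]
    level: float | None

    def line(self) -> str:
        lev = "na" if self.level is None else repr(self.level)
        w = "\t".join(map(str, self.watson))
        c = "\t".join(map(str, self.crick))
        return (
            f"{self.chrom}\t{self.nucleotide}\t{self.pos}\t{self.context}\t"
            f"{self.dinucleotide}\t{w}\t{c}\t{lev}"
        )

    @classmethod
    def parse(cls, line: str) -> "ATCGmapRecord":
        f = line.rstrip("\n").split("\t")
        return cls(
            f[0], f[1], int(f[2]), f[3], f[4],
            tuple(int(x) for x in f[5:9]),
            tuple(int(x) for x in f[9:13]),
            None if f[13] == "na" else float(f[13]),
        )


def _cyt_level(watson_row, crick_row, ref_base):
    """(mC, coverage) on the cytosine's own strand, or None for non-cytosines."""
    if ref_base == "C":
        mc, cov = watson_row[2], watson_row[2] + watson_row[1]
    elif ref_base == "G":
        mc, cov = crick_row[2], crick_row[2] + crick_row[1]
    else:
        return None
    return mc, cov


def emit_cgmap(counts: SiteCounts, genome: ReferenceGenome) -> Iterator[CGmapRecord]:
    """CGmap rows for every genomic cytosine with C/T coverage >= 1.

    Sorted by chromosome (genome order) then position.  Cytosines whose
    context cannot be determined (chromosome edge or neighboring N) are not
    emitted — the context-free counts remain visible in the ATCGmap.
    """
    for chrom in genome.chrom_names:
        seq = genome[chrom]
        for pos in counts.positions(chrom):
            ref = seq[pos]
            if ref not in "CG":
                continue
            w, c = counts.get(chrom, pos)
            mc_cov = _cyt_level(w, c, ref)
            mc, cov = mc_cov
            if cov < 1:
                continue
            ctx = context_of(genome, chrom, pos, "watson" if ref == "C" else "crick")
            if ctx is None:
                continue
            yield CGmapRecord(
                chrom=chrom,
                nucleotide=ref,
                pos=pos + 1,
                context=ctx[0],
                dinucleotide=ctx[1],
                level=mc / cov,
                mc=mc,
                coverage=cov,
            )


def emit_atcgmap(counts: SiteCounts, genome: ReferenceGenome) -> Iterator[ATCGmapRecord]:
    """ATCGmap rows for every covered position, both strands' counts."""
    for chrom in genome.chrom_names:
        seq = genome[chrom]
        for pos in counts.positions(chrom):
            ref = seq[pos]
            w, c = counts.get(chrom, pos)
            if ref in "CG":
                ctx = context_of(genome, chrom, pos, "watson" if ref == "C" else "crick")
                context, dinuc = ctx if ctx else ("--", "--")
                mc_cov = _cyt_level(w, c, ref)
                level = mc_cov[0] / mc_cov[1] if mc_cov[1] >= 1 else None
            else:
                context, dinuc = "--", "--"
                level = None
            yield ATCGmapRecord(
                chrom=chrom,
                nucleotide=ref,
                pos=pos + 1,
                context=context,
                dinucleotide=dinuc,
                watson=w,
                crick=c,
                level=level,
            )


def _open_write(path: str | Path):
    path = Path(path)
    return gzip.open(path, "wt") if path.suffix == ".gz" else open(path, "w")


def _open_read(path: str | Path):
    path = Path(path)
    return gzip.open(path, "rt") if path.suffix == ".gz" else open(path)


def write_cgmap(records: Iterable[CGmapRecord], path: str | Path) -> None:
    with _open_write(path) as fh:
        for rec in records:
            fh.write(rec.line() + "\n")


def read_cgmap(path: str | Path) -> list[CGmapRecord]:
    with _open_read(path) as fh:
        return [CGmapRecord.parse(line) for line in fh if line.strip()]


def write_atcgmap(records: Iterable[ATCGmapRecord], path: str | Path) -> None:
    with _open_write(path) as fh:
        for rec in records:
            fh.write(rec.line() + "\n")


def read_atcgmap(path: str | Path) -> list[ATCGmapRecord]:
    with _open_read(path) as fh:
        return [ATCGmapRecord.parse(line) for line in fh if line.strip()]


def emit_wig(records: Iterable[CGmapRecord], min_coverage: int = 1) -> str:
    """variableStep WIG text (span=1, 4-decimal levels) from sorted CGmap
    records.  Unsorted input raises."""
    out = ["track type=wiggle_0"]
    cur_chrom = None
    last_pos = -1
    seen: set[str] = set()
    for rec in records:
        if rec.coverage < min_coverage:
            continue
        if rec.chrom != cur_chrom:
            if rec.chrom in seen:
                raise ValueError("CGmap records are not sorted by chromosome")
            seen.add(rec.chrom)
            cur_chrom = rec.chrom
            last_pos = -1
            out.append(f"variableStep chrom={rec.chrom} span=1")
        if rec.pos <= last_pos:
            raise ValueError(f"CGmap records are not position-sorted at {rec.chrom}:{rec.pos}")
        last_pos = rec.pos
        out.append(f"{rec.pos} {rec.level:.4f}")
    return "\n".join(out) + "\n"


def write_wig(records: Iterable[CGmapRecord], path: str | Path, min_coverage: int = 1) -> None:
    with _open_write(path) as fh:
        fh.write(emit_wig(records, min_coverage=min_coverage))


def read_wig(path: str | Path) -> dict[str, list[tuple[int, float]]]:
    """Parse a variableStep WIG back to {chrom: [(pos, level), ...]}."""
    tracks: dict[str, list[tuple[int, float]]] = {}
    cur: list[tuple[int, float]] | None = None
    with _open_read(path) as fh:
        for line in fh:
            line = line.strip()
            if not line or line.startswith("track"):
                continue
            if line.startswith("variableStep"):
                fields = dict(kv.split("=") for kv in line.split()[1:])
                cur = tracks.setdefault(fields["chrom"], [])
                continue
            if cur is None:
                raise ValueError("WIG data before any variableStep header")
            pos, level = line.split()
            cur.append((int(pos), float(level)))
    return tracks


def pooled_levels(records: Iterable[CGmapRecord]) -> dict[str, tuple[int, int]]:
    """Pooled (sum mC, sum coverage) per context — convenience for QC."""
    pools: dict[str, list[int]] = {}
    for rec in records:
        p = pools.setdefault(rec.context, [0, 0])
        p[0] += rec.mc
        p[1] += rec.coverage
    return {k: (v[0], v[1]) for k, v in pools.items()}
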