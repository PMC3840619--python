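"""Built-in three-letter bisulfite read aligner.

The search runs in the collapsed (three-letter) alphabet: the C->T converted
read is probed against the W_C2T and C_C2T index instances and, for
non-directional libraries, the G->A converted read against W_G2A and C_G2A.
A hit on an instance determines the read's bisulfite strand tag:

=========  ==========  ==================  ===========================
tag        instance    placement (Watson)  methylation information
=========  ==========  ==================  ===========================
W_BS       W_C2T       forward             Watson cytosines (C vs T)
C_BS       C_C2T       reverse             Crick cytosines  (C vs T)
W_BS_RC    W_G2A       forward             Crick cytosines  (G vs A)
C_BS_RC    C_G2A       reverse             Watson cytosines (G vs A)
=========  ==========  ==================  ===========================

The _RC tags are the reverse complements of the two converted original
strands and only occur in non-directional libraries.

Candidate hits from all searched instances are pooled; a read is reported
only when a single placement attains the best score (unique best hit).  The
winning hit is then re-examined on the *original* letters: a read T over a
genome C (or read A over genome G for the _RC tags) is a silent bisulfite
conversion, everything else that differs is a mismatch — in particular a
read C over a genome T, which the three-letter search cannot see.  Reads
whose recounted mismatch total exceeds ``max_mismatches`` are rejected.

Search modes
------------
``end2end``
    Ungapped, full read.  Implemented with pigeonhole seeding: the read is
    split into ``max_mismatches + 1`` disjoint segments, so any placement
    within the mismatch radius matches at least one segment exactly and is
    found through the k-mer index.  Exhaustive within the radius, therefore
    optimal for the unique-best decision.
``end2end_gapped``
    Affine-gap alignment consuming the whole read, computed by full dynamic
    programming against every reference position (exact; intended for
    desk-scale genomes).
``local``
    Smith-Waterman with soft-clipped read ends, reported only when the score
    reaches ``min_local_score``; also full dynamic programming.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, replace
from typing import Sequence

import numpy as np

from .genome import IndexBundle, IndexInstance, ReferenceGenome, convert_sequence, revcomp
from .reads import Read

log = logging.getLogger(__name__)

# ---------------------------------------------------------------------------
# strand-tag bookkeeping

READ_TAGS = ("W_BS", "C_BS", "W_BS_RC", "C_BS_RC")

TAG_OF_INSTANCE = {"W_C2T": "W_BS", "C_C2T": "C_BS", "W_G2A": "W_BS_RC", "C_G2A": "C_BS_RC"}
INSTANCE_OF_TAG = {v: k for k, v in TAG_OF_INSTANCE.items()}
#: conversion applied to the read before probing the tag's instance
READ_RULE = {"W_BS": "C2T", "C_BS": "C2T", "W_BS_RC": "G2A", "C_BS_RC": "G2A"}
#: True when the hit is placed on the reverse strand in Watson coordinates
IS_REVERSE = {"W_BS": False, "C_BS": True, "W_BS_RC": False, "C_BS_RC": True}
#: the strand whose cytosines the read reports (= its bisulfite origin)
ORIGIN_STRAND = {"W_BS": "watson", "C_BS": "crick", "W_BS_RC": "crick", "C_BS_RC": "watson"}
#: genome base that is a cytosine site in the tag-oriented reference slice
CYTOSINE_BASE = {"W_BS": "C", "C_BS": "C", "W_BS_RC": "G", "C_BS_RC": "G"}
#: (read base, genome base) pair that is a silent bisulfite conversion
CONVERSION = {"W_BS": ("T", "C"), "C_BS": ("T", "C"), "W_BS_RC": ("A", "G"), "C_BS_RC": ("A", "G")}
#: tag of the reverse complement of a read with a given tag
RC_TAG = {"W_BS": "C_BS_RC", "C_BS": "W_BS_RC", "W_BS_RC": "C_BS", "C_BS_RC": "W_BS"}
#: tag expected for the second mate of a pair whose first mate has the key tag
MATE_TAG = RC_TAG

_CONTEXT_CHAR = {"CG": "Z", "CHG": "X", "CHH": "H"}


@dataclass
class AlignParams:
    """Alignment parameters.

    Scores are simple, auditable integers: end-to-end pays ``-6`` per
    mismatch; gapped modes add an affine gap of length L costing
    ``gap_open + L * gap_extend``; local mode additionally rewards matches
    with ``+2`` and requires the score to reach :meth:`min_local_score`
    (half of the best achievable score for reads of at least 20 bp).
    Qualities play no role in scoring.
    """

    mode: str = "end2end"
    max_mismatches: int = 5
    min_read_length: int = 20
    mismatch_penalty: int = 6
    gap_open: int = 5
    gap_extend: int = 3
    match_bonus: int = 2
    insert_min: int = 0
    insert_max: int = 1000

    def min_local_score(self, read_length: int) -> int:
        return max(20, read_length)


@dataclass(frozen=True)
class AlignmentHit:
    """A candidate placement of a read.

    ``pos`` is the 0-based Watson-strand coordinate of the leftmost aligned
    reference base.  ``ops`` is a CIGAR-like tuple of ``(op, length)`` in the
    read's native orientation with op in {M, I, D, S}; S only at the ends.
    ``score`` and ``three_letter_mismatches`` refer to the collapsed-alphabet
    search.
    """

    read_id: str
    chrom: str
    pos: int
    tag: str
    ops: tuple
    score: int
    three_letter_mismatches: int

    @property
    def ref_span(self) -> int:
        return sum(n for op, n in self.ops if op in "MD")

    def _clips(self) -> tuple[int, int]:
        """(Watson-left, Watson-right) soft-clip lengths."""
        lead = self.ops[0][1] if self.ops and self.ops[0][0] == "S" else 0
        trail = self.ops[-1][1] if self.ops and self.ops[-1][0] == "S" else 0
        if IS_REVERSE[self.tag]:
            return trail, lead
        return lead, trail

    @property
    def inferred_start(self) -> int:
        """Watson-leftmost coordinate of the full read, clips included."""
        return self.pos - self._clips()[0]

    @property
    def inferred_end(self) -> int:
        """Watson-rightmost (exclusive) coordinate, clips included."""
        return self.pos + self.ref_span + self._clips()[1]


@dataclass
class AlignmentRecord:
    """The final verdict for one read."""

    read: Read
    status: str  # unique | multiple | unmapped | filtered
    hit: AlignmentHit | None = None
    bs_mismatches: int | None = None
    meth_string: str | None = None
    reason: str | None = None


# ---------------------------------------------------------------------------
# read conversion

def convert_read(read: Read, rule: str) -> Read:
    """Three-letter copy of a read; the original letters travel along in
    ``orig_seq`` for the post-hoc mismatch recount."""
    return replace(
        read,
        seq=convert_sequence(read.seq, rule),
        orig_seq=read.orig_seq if read.orig_seq is not None else read.seq,
    )


# ---------------------------------------------------------------------------
# encoded chromosome text + k-mer positional index

_CODE = np.full(256, 4, dtype=np.uint8)
for _i, _b in enumerate("ACGT"):
    _CODE[ord(_b)] = _i

_SEED_KS = (16, 12, 8, 4, 3, 2, 1)


def _encode(seq: str) -> np.ndarray:
    return _CODE[np.frombuffer(seq.encode(), dtype=np.uint8)]


class _ChromSearch:
    """Encoded chromosome with lazily built sorted k-mer position tables.

    k-mers containing N are never indexed, which keeps masked
    reduced-representation regions out of the search space entirely.
    """

    def __init__(self, seq: str):
        self.codes = _encode(seq)
        self.n = len(seq)
        self._kmer: dict[int, tuple[np.ndarray, np.ndarray]] = {}

    def kmer_index(self, k: int) -> tuple[np.ndarray, np.ndarray]:
        if k not in self._kmer:
            n = self.n - k + 1
            if n <= 0:
                self._kmer[k] = (np.empty(0, np.int64), np.empty(0, np.int64))
            else:
                codes = self.codes.astype(np.int64)
                h = np.zeros(n, np.int64)
                for j in range(k):
                    h = h * 5 + codes[j : j + n]
                cs = np.concatenate(([0], np.cumsum(self.codes == 4)))
                n_count = cs[k:] - cs[:-k]
                pos = np.nonzero(n_count == 0)[0].astype(np.int64)
                hv = h[pos]
                order = np.argsort(hv, kind="stable")
                self._kmer[k] = (hv[order], pos[order])
        return self._kmer[k]

    def lookup(self, k: int, kmer_codes: np.ndarray) -> np.ndarray:
        if (kmer_codes == 4).any():
            return np.empty(0, np.int64)
        h = 0
        for v in kmer_codes:
            h = h * 5 + int(v)
        hs, ps = self.kmer_index(k)
        lo = np.searchsorted(hs, h, side="left")
        hi = np.searchsorted(hs, h, side="right")
        return ps[lo:hi]


def _chrom_search(instance: IndexInstance, chrom: str) -> _ChromSearch:
    cache = instance._search_cache
    if chrom not in cache:
        cache[chrom] = _ChromSearch(instance.converted_sequences[chrom])
    return cache[chrom]


# ---------------------------------------------------------------------------
# end-to-end (ungapped) search

_VERIFY_CHUNK = 200_000


def _end2end_chrom(cs: _ChromSearch, rcodes: np.ndarray, max_mm: int) -> list[tuple[int, int]]:
    """All (offset, mismatches) placements with mismatches <= max_mm."""
    L = len(rcodes)
    G = cs.n
    if G < L:
        return []
    n_seg = max_mm + 1
    base = L // n_seg
    if base >= 1:
        k = next(kk for kk in _SEED_KS if kk <= base)
        cands = []
        for i in range(n_seg):
            off = i * base
            hits = cs.lookup(k, rcodes[off : off + k])
            if hits.size:
                cands.append(hits - off)
        if not cands:
            return []
        cand = np.unique(np.concatenate(cands))
        cand = cand[(cand >= 0) & (cand <= G - L)]
    else:
        # mismatch allowance exceeds read length: every offset qualifies
        cand = np.arange(G - L + 1, dtype=np.int64)
    if cand.size == 0:
        return []
    read_n = rcodes == 4
    ar = np.arange(L)
    out: list[tuple[int, int]] = []
    for s in range(0, cand.size, _VERIFY_CHUNK):
        c = cand[s : s + _VERIFY_CHUNK]
        win = cs.codes[c[:, None] + ar]
        mm = ((win != rcodes) | (win == 4) | read_n).sum(axis=1)
        keep = np.nonzero(mm <= max_mm)[0]
        out.extend(zip(c[keep].tolist(), mm[keep].tolist()))
    return out


# ---------------------------------------------------------------------------
# gapped / local search: full affine dynamic programming

_NEG = -1e15


def _dp_forward(gcodes: np.ndarray, rcodes: np.ndarray, params: AlignParams, local: bool):
    """Forward pass of affine-gap DP over a whole chromosome.

    Rows are read positions, columns reference positions; the horizontal
    (deletion) state is resolved exactly with a running-maximum scan, which
    is valid because gap_open >= 0 makes gap chains through already-gapped
    cells dominated.  Returns, per reference end column, the best attainable
    score (``local``: over all read rows; otherwise: full read consumed).
    """
    G = len(gcodes)
    L = len(rcodes)
    match = float(params.match_bonus if local else 0)
    mis = float(-params.mismatch_penalty)
    go, ge = float(params.gap_open), float(params.gap_extend)
    gn4 = gcodes != 4

    H = np.zeros(G + 1)
    F = np.full(G + 1, _NEG)
    jdrift = ge * np.arange(G + 1)
    if local:
        col_best = np.zeros(G + 1)
        col_row = np.zeros(G + 1, np.int32)
    for i in range(1, L + 1):
        rb = rcodes[i - 1]
        sub = np.where((gcodes == rb) & gn4 & (rb != 4), match, mis)
        diag = H[:-1] + sub
        F = np.maximum(H - go - ge, F - ge)
        Hn = np.empty(G + 1)
        Hn[0] = 0.0 if local else _NEG
        Hn[1:] = np.maximum(diag, F[1:])
        if local:
            np.maximum(Hn, 0.0, out=Hn)
        # deletion state: E[j] = max_{j0<j} H[j0] - go - ge*(j-j0)
        a = Hn - go + jdrift
        m = np.maximum.accumulate(a)
        e = m[:-1] - jdrift[1:]
        Hn[1:] = np.maximum(Hn[1:], e)
        H = Hn
        if local:
            better = H > col_best
            col_best[better] = H[better]
            col_row[better] = i
    if local:
        return col_best, col_row
    return H, None


def _dp_traceback(
    gcodes: np.ndarray,
    rcodes: np.ndarray,
    params: AlignParams,
    local: bool,
    end_j: int,
    expect_score: float,
):
    """Exact small-window DP with traceback for one end column.

    Returns (start_j, ops, three_letter_mismatches) or None if the score
    cannot be reproduced in the window (should not happen: the window covers
    the longest alignment that can end at ``end_j``).
    """
    L = len(rcodes)
    match = params.match_bonus if local else 0
    mis = -params.mismatch_penalty
    go, ge = params.gap_open, params.gap_extend
    # deletions are paid for by matches; bound their number generously
    max_del = L + 8 + (match * L) // max(ge, 1)
    w0 = max(0, end_j - L - max_del)
    g = gcodes[w0:end_j]
    W = len(g)
    NEG = -(10 ** 9)

    H = [[0] * (W + 1) for _ in range(L + 1)]
    E = [[NEG] * (W + 1) for _ in range(L + 1)]
    F = [[NEG] * (W + 1) for _ in range(L + 1)]
    if not local:
        for i in range(1, L + 1):
            H[i][0] = NEG
    for i in range(1, L + 1):
        hi, hp = H[i], H[i - 1]
        ei, fi, fp = E[i], F[i], F[i - 1]
        rb = rcodes[i - 1]
        for j in range(1, W + 1):
            gb = g[j - 1]
            s = match if (gb == rb and gb != 4 and rb != 4) else mis
            d = hp[j - 1] + s
            ei[j] = max(hi[j - 1] - go - ge, ei[j - 1] - ge)
            fi[j] = max(hp[j] - go - ge, fp[j] - ge)
            best = max(d, ei[j], fi[j])
            if local:
                best = max(best, 0)
            hi[j] = best

    if local:
        i = max(range(L + 1), key=lambda r: H[r][W])
    else:
        i = L
    if H[i][W] != int(expect_score):
        return None
    end_i = i
    j = W
    ops_rev: list[str] = []
    mm3 = 0
    state = "H"
    while i > 0 or (not local and j > 0 and state != "H"):
        if state == "H":
            if local and H[i][j] == 0:
                break
            if not local and i == 0:
                break
            gb = g[j - 1] if j > 0 else None
            rb = rcodes[i - 1] if i > 0 else None
            if (
                i > 0
                and j > 0
                and H[i][j]
                == H[i - 1][j - 1]
                + (match if (gb == rb and gb != 4 and rb != 4) else mis)
            ):
                if not (gb == rb and gb != 4 and rb != 4):
                    mm3 += 1
                ops_rev.append("M")
                i -= 1
                j -= 1
            elif j > 0 and H[i][j] == E[i][j]:
                state = "E"
            elif i > 0 and H[i][j] == F[i][j]:
                state = "F"
            else:  # pragma: no cover - defensive
                raise AssertionError("traceback lost")
        elif state == "E":
            ops_rev.append("D")
            if E[i][j] == E[i][j - 1] - ge:
                j -= 1
            else:
                j -= 1
                state = "H"
        else:  # F
            ops_rev.append("I")
            if F[i][j] == F[i - 1][j] - ge:
                i -= 1
            else:
                i -= 1
                state = "H"
    start_i, start_j = i, j

    ops: list[tuple[str, int]] = []
    if local and start_i > 0:
        ops.append(("S", start_i))
    for op in reversed(ops_rev):
        if ops and ops[-1][0] == op:
            ops[-1] = (op, ops[-1][1] + 1)
        else:
            ops.append((op, 1))
    if local and end_i < L:
        ops.append(("S", L - end_i))
    return w0 + start_j, tuple(ops), mm3


def _dp_chrom(
    cs: _ChromSearch, rcodes: np.ndarray, params: AlignParams, local: bool, limit: int
) -> list[tuple[int, int, tuple, int]]:
    """Best placements by DP on one chromosome.

    Returns up to ``limit`` tuples (start_offset, score, ops, mm3), covering
    all placements tied at the best score (capped) plus the best placements
    at the runner-up score.
    """
    col_scores, _ = _dp_forward(cs.codes, rcodes, params, local)
    finite = col_scores > _NEG / 2
    if not finite.any():
        return []
    best = col_scores[finite].max()
    if local and best < params.min_local_score(len(rcodes)):
        return []
    if not local and best <= _NEG / 2:
        return []
    ends_best = np.nonzero(col_scores == best)[0]
    lower = col_scores[finite & (col_scores < best)]
    ends: list[tuple[int, float]] = [(int(j), float(best)) for j in ends_best[:limit]]
    if lower.size and len(ends) < limit:
        second = lower.max()
        if not local or second >= params.min_local_score(len(rcodes)):
            for j in np.nonzero(col_scores == second)[0][: limit - len(ends)]:
                ends.append((int(j), float(second)))
    out = []
    seen_starts = set()
    for j, score in ends:
        tb = _dp_traceback(cs.codes, rcodes, params, local, j, score)
        if tb is None:  # pragma: no cover - defensive
            continue
        start, ops, mm3 = tb
        if start in seen_starts:
            continue
        seen_starts.add(start)
        out.append((start, int(score), ops, mm3))
    return out


# ---------------------------------------------------------------------------
# per-instance search

def _search_all(
    conv_read: Read, instance: IndexInstance, mode: str, params: AlignParams, limit: int
) -> list[AlignmentHit]:
    """Hits of a converted read on one instance, best first, up to ``limit``."""
    rcodes = _encode(conv_read.seq)
    L = len(rcodes)
    tag = TAG_OF_INSTANCE[instance.tag]
    results = []  # (sort_key, hit fields)
    for chrom in instance.converted_sequences:
        cs = _chrom_search(instance, chrom)
        if mode == "end2end":
            for off, mm in _end2end_chrom(cs, rcodes, params.max_mismatches):
                score = -params.mismatch_penalty * mm
                results.append((-score, off, chrom, (("M", L),), mm, off + L))
        elif mode in ("end2end_gapped", "local"):
            for start, score, ops, mm3 in _dp_chrom(
                cs, rcodes, params, mode == "local", max(limit, 4)
            ):
                span = sum(n for op, n in ops if op in "MD")
                results.append((-score, start, chrom, ops, mm3, start + span))
        else:
            raise ValueError(f"unknown alignment mode: {mode!r}")
    results.sort(key=lambda r: (r[0], r[1], r[2]))
    hits = []
    for neg_score, off, chrom, ops, mm3, ref_end in results[:limit]:
        chrom_len = len(instance.converted_sequences[chrom])
        span = ref_end - off
        pos = chrom_len - ref_end if instance.is_crick else off
        hits.append(
            AlignmentHit(
                read_id=conv_read.id,
                chrom=chrom,
                pos=pos,
                tag=tag,
                ops=ops,
                score=-neg_score,
                three_letter_mismatches=mm3,
            )
        )
    return hits


def search_instance(
    conv_read: Read, instance: IndexInstance, mode: str = "end2end", params: AlignParams | None = None
) -> list[AlignmentHit]:
    """Best and second-best hits of a converted read on one index instance.

    Ties are ordered by lower coordinate, then chromosome name, so the two
    reported hits are deterministic.  Reads shorter than
    ``params.min_read_length`` yield no hits.
    """
    params = params or AlignParams()
    if len(conv_read) < params.min_read_length:
        return []
    return _search_all(conv_read, instance, mode, params, limit=2)


# ---------------------------------------------------------------------------
# recount on original letters + per-read methylation string

def _tag_slice(hit: AlignmentHit, genome: ReferenceGenome) -> str:
    """Reference slice under the hit, in the tag's orientation."""
    s = genome[hit.chrom][hit.pos : hit.pos + hit.ref_span]
    return revcomp(s) if IS_REVERSE[hit.tag] else s


def _walk(hit: AlignmentHit, original_read: str):
    """Yield (kind, read_base, ref_offset) over the hit's columns.

    kind is 'M' (aligned column), 'D' (reference-only column, read base
    None) — insertions and clips advance the read silently.  ``ref_offset``
    counts along the tag-oriented reference slice.
    """
    i = 0
    g = 0
    for op, n in hit.ops:
        if op in ("S", "I"):
            i += n
        elif op == "M":
            for _ in range(n):
                yield "M", original_read[i], g
                i += 1
                g += 1
        elif op == "D":
            for _ in range(n):
                yield "D", None, g
                g += 1
        else:  # pragma: no cover
            raise ValueError(f"bad op {op!r}")


def recount_mismatches(hit: AlignmentHit, original_read: str, genome: ReferenceGenome) -> int:
    """Bisulfite-aware mismatch count on the original letters.

    Silent conversions (read T over genome C for the C2T tags, read A over
    genome G for the G2A tags, genome taken in the tag's orientation) are
    not mismatches; the reverse direction (read C over genome T) is, and N
    on either side always is.  Gap columns count zero — they are penalized
    through the alignment score instead.
    """
    gslice = _tag_slice(hit, genome)
    conv_read_base, conv_genome_base = CONVERSION[hit.tag]
    mm = 0
    for kind, rb, g in _walk(hit, original_read):
        if kind != "M":
            continue
        gb = gslice[g]
        if rb == gb and rb != "N":
            continue
        if rb == conv_read_base and gb == conv_genome_base:
            continue
        mm += 1
    return mm


def methylation_string(hit: AlignmentHit, original_read: str, genome: ReferenceGenome) -> str:
    """Per-read methylation calls, one character per aligned reference column
    (tag orientation): Z/z for CpG, X/x for CHG, H/h for CHH (upper =
    methylated, i.e. the cytosine escaped conversion), '.' elsewhere."""
    from .methcall import context_of  # deferred: methcall imports this module

    gslice = _tag_slice(hit, genome)
    tag = hit.tag
    cyt = CYTOSINE_BASE[tag]
    strand = ORIGIN_STRAND[tag]
    conv_read_base, _ = CONVERSION[tag]
    retained = "C" if cyt == "C" else "G"
    span = hit.ref_span
    out = []
    for kind, rb, g in _walk(hit, original_read):
        if kind != "M":
            out.append(".")
            continue
        if gslice[g] != cyt:
            out.append(".")
            continue
        if IS_REVERSE[tag]:
            w = hit.pos + span - 1 - g
        else:
            w = hit.pos + g
        ctx = context_of(genome, hit.chrom, w, strand)
        if ctx is None or (rb != retained and rb != conv_read_base):
            out.append(".")
            continue
        ch = _CONTEXT_CHAR[ctx[0]]
        out.append(ch if rb == retained else ch.lower())
    return "".join(out)


# ---------------------------------------------------------------------------
# whole-read alignment

def _searched_tags(directional: bool) -> list[str]:
    return ["W_BS", "C_BS"] if directional else list(READ_TAGS)


def _pool_hits(
    read: Read, bundle: IndexBundle, tags: Sequence[str], mode: str, params: AlignParams, limit: int
) -> list[AlignmentHit]:
    conv = {}
    hits: list[AlignmentHit] = []
    for tag in tags:
        rule = READ_RULE[tag]
        if rule not in conv:
            conv[rule] = convert_read(read, rule)
        hits.extend(
            _search_all(conv[rule], bundle[INSTANCE_OF_TAG[tag]], mode, params, limit)
        )
    return hits


def _finalize(read: Read, hit: AlignmentHit, bundle: IndexBundle, params: AlignParams) -> AlignmentRecord:
    bs_mm = recount_mismatches(hit, read.seq, bundle.align_genome)
    if bs_mm > params.max_mismatches:
        return AlignmentRecord(read=read, status="unmapped", reason="mismatch", hit=None)
    meth = methylation_string(hit, read.seq, bundle.genome)
    return AlignmentRecord(
        read=read, status="unique", hit=hit, bs_mismatches=bs_mm, meth_string=meth
    )


def align_read(
    read: Read,
    bundle: IndexBundle,
    directional: bool = True,
    mode: str = "end2end",
    params: AlignParams | None = None,
) -> AlignmentRecord:
    """Align one read: pool instance hits, keep the unique best placement,
    recount mismatches on original letters, attach the methylation string.

    Every read produces a record; failures carry a ``reason``
    (too_short / no_hit / multiple / mismatch).
    """
    params = params or AlignParams(mode=mode)
    if len(read) < params.min_read_length:
        return AlignmentRecord(read=read, status="unmapped", reason="too_short")
    hits = _pool_hits(read, bundle, _searched_tags(directional), mode, params, limit=2)
    if not hits:
        return AlignmentRecord(read=read, status="unmapped", reason="no_hit")
    best = max(h.score for h in hits)
    top = [h for h in hits if h.score == best]
    placements = {(h.chrom, h.pos, h.tag) for h in top}
    if len(placements) > 1:
        return AlignmentRecord(read=read, status="multiple", reason="multiple")
    return _finalize(read, top[0], bundle, params)


def align_pair(
    read1: Read,
    read2: Read,
    bundle: IndexBundle,
    directional: bool = True,
    mode: str = "end2end",
    params: AlignParams | None = None,
    max_hits_per_instance: int = 50,
) -> tuple[AlignmentRecord, AlignmentRecord]:
    """Align a mate pair with inner (FR) orientation on one bisulfite strand.

    Mate 1 is searched like a single read; mate 2 must land on the reverse
    complement tag of the same strand, on the same chromosome, with the
    fragment span inside ``[insert_min, insert_max]``.  The best-scoring
    concordant pair wins; a tie at the best pair score makes both mates
    multiple, and no concordant combination leaves both unmapped.
    """
    params = params or AlignParams(mode=mode)
    r1 = replace(read1, mate=1)
    r2 = replace(read2, mate=2)
    for r in (r1, r2):
        if len(r) < params.min_read_length:
            return (
                AlignmentRecord(read=r1, status="unmapped", reason="too_short"),
                AlignmentRecord(read=r2, status="unmapped", reason="too_short"),
            )
    tags1 = _searched_tags(directional)
    tags2 = [MATE_TAG[t] for t in tags1]
    hits1 = _pool_hits(r1, bundle, tags1, mode, params, max_hits_per_instance)
    hits2 = _pool_hits(r2, bundle, tags2, mode, params, max_hits_per_instance)

    pairs = []
    by_tag2: dict[tuple[str, str], list[AlignmentHit]] = {}
    for h in hits2:
        by_tag2.setdefault((h.tag, h.chrom), []).append(h)
    for h1 in hits1:
        for h2 in by_tag2.get((MATE_TAG[h1.tag], h1.chrom), []):
            fwd, rev = (h1, h2) if not IS_REVERSE[h1.tag] else (h2, h1)
            if rev.pos + rev.ref_span <= fwd.pos:
                continue  # wrong relative orientation
            insert = (rev.pos + rev.ref_span) - fwd.pos
            if not params.insert_min <= insert <= params.insert_max:
                continue
            pairs.append((h1.score + h2.score, h1, h2))
    if not pairs:
        return (
            AlignmentRecord(read=r1, status="unmapped", reason="discordant"),
            AlignmentRecord(read=r2, status="unmapped", reason="discordant"),
        )
    best = max(p[0] for p in pairs)
    top = [p for p in pairs if p[0] == best]
    placements = {
        (p[1].chrom, p[1].pos, p[1].tag, p[2].pos, p[2].tag) for p in top
    }
    if len(placements) > 1:
        return (
            AlignmentRecord(read=r1, status="multiple", reason="multiple"),
            AlignmentRecord(read=r2, status="multiple", reason="multiple"),
        )
    _, h1, h2 = top[0]
    rec1 = _finalize(r1, h1, bundle, params)
    rec2 = _finalize(r2, h2, bundle, params)
    if rec1.status != "unique" or rec2.status != "unique":
        reason = rec1.reason or rec2.reason
        return (
            AlignmentRecord(read=r1, status="unmapped", reason=reason),
            AlignmentRecord(read=r2, status="unmapped", reason=reason),
        )
    return rec1, rec2
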