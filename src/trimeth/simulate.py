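"""Bisulfite read simulator with ground truth.

Generates a synthetic reference (i.i.d. bases at a chosen GC fraction),
assigns each cytosine a methylation state by context, and emits bisulfite
reads mirroring the laboratory protocol:

* conversion — a methylated cytosine is always retained as C; an
  unmethylated cytosine is converted to T except with probability
  ``conversion_failure`` (the incomplete-conversion rate, 1% in the
  error-containing regime);
* WGBS — uniform random origin on either strand (directional libraries
  produce only the two converted original strands; non-directional ones add
  their reverse complements);
* RRBS — reads start at the 5' cut ends of size-selected digestion
  fragments, in both orientations; when the fragment is shorter than the
  read length the 3' adapter is sequenced into and appended;
* sequencing errors — per-cycle substitution to a uniformly chosen other
  base, rates given by ``error_profile`` (``None`` = error-free).

Every read carries a truth record (origin interval, strand tag, per-cytosine
states) so mappability and accuracy can be measured exactly.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable

import numpy as np

from .align import RC_TAG, _encode
from .digest import RRGenome
from .genome import ReferenceGenome
from .reads import Read
from .trim import DEFAULT_ADAPTER

_DECODE = np.frombuffer(b"ACGTN", dtype=np.uint8)
_COMP_CODE = np.array([3, 2, 1, 0, 4], dtype=np.uint8)
_A, _C, _G, _T, _N = 0, 1, 2, 3, 4


def _decode(codes: np.ndarray) -> str:
    return _DECODE[codes].tobytes().decode()


def ramp_error_profile(read_length: int) -> np.ndarray:
    """Per-cycle substitution rates rising linearly 0.1% -> 1%, a stand-in
    for an empirically measured cycle-error distribution."""
    return np.linspace(0.001, 0.01, read_length)


@dataclass
class RRBSSimParams:
    """Reduced-representation mode for the simulator (fragment-anchored
    reads; bounds follow the classic MspI size-selection window used for
    simulation, 40-250 bp)."""

    enzymes: tuple[str, ...] = ("C'CGG",)
    low: int = 40
    high: int = 250
    adapter: str = DEFAULT_ADAPTER
    add_adapter: bool = True


@dataclass
class SimParams:
    genome_length: int = 1_000_000
    gc_fraction: float = 0.5
    meth_levels: dict = field(
        default_factory=lambda: {"CG": 0.7, "CHG": 0.02, "CHH": 0.02}
    )
    conversion_failure: float = 0.01
    error_profile: np.ndarray | None = None  # None = error-free sequencing
    read_length: int = 100
    n_reads: int = 10_000
    directional: bool = True
    paired: bool = False
    pe_insert_range: tuple[int, int] = (150, 400)
    rrbs: RRBSSimParams | None = None
    seed: int = 0

    @classmethod
    def error_free(cls, **kw) -> "SimParams":
        """Faithful conversion, no sequencing errors."""
        kw.setdefault("conversion_failure", 0.0)
        kw.setdefault("error_profile", None)
        return cls(**kw)

    @classmethod
    def error_containing(cls, **kw) -> "SimParams":
        """1% conversion failure plus the per-cycle error ramp."""
        kw.setdefault("conversion_failure", 0.01)
        params = cls(**kw)
        if params.error_profile is None:
            params.error_profile = ramp_error_profile(params.read_length)
        return params


@dataclass(frozen=True)
class TruthRecord:
    """Ground truth for one simulated read.

    ``start``/``end`` delimit the genomic bases the read covers (Watson,
    0-based half-open), before any adapter appending.  ``meth_states`` is a
    '1'/'0' string over the cytosines of the molecule strand, 5'->3'.
    """

    read_id: str
    chrom: str
    start: int
    end: int
    tag: str
    fragment_length: int
    meth_states: str = ""


def generate_genome(length: int, gc_fraction: float = 0.5, seed: int = 0) -> ReferenceGenome:
    """Single-chromosome i.i.d. genome with P(G)=P(C)=gc/2."""
    if length < 1000:
        raise ValueError("genome length must be >= 1000")
    rng = np.random.default_rng(seed)
    gc = gc_fraction
    probs = [(1 - gc) / 2, gc / 2, gc / 2, (1 - gc) / 2]  # A C G T
    codes = rng.choice(4, size=length, p=probs).astype(np.uint8)
    return ReferenceGenome({"chrSim": _decode(codes)})


@dataclass
class MethylationStates:
    """Per-chromosome boolean methylation state arrays, indexed by Watson
    coordinate: ``watson`` is meaningful at C positions, ``crick`` at G
    positions (the Crick-strand cytosines)."""

    watson: dict[str, np.ndarray]
    crick: dict[str, np.ndarray]


def _context_levels(codes: np.ndarray, crick: bool, levels: dict[str, float]) -> np.ndarray:
    """Methylation probability per position for one strand's cytosines."""
    n = len(codes)
    if crick:
        c = _COMP_CODE[codes][::-1]
    else:
        c = codes
    n1 = np.full(n, _N, np.uint8)
    n1[:-1] = c[1:]
    n2 = np.full(n, _N, np.uint8)
    n2[:-2] = c[2:]
    is_h = lambda x: (x == _A) | (x == _C) | (x == _T)
    p = np.zeros(n)
    p[n1 == _G] = levels.get("CG", 0.0)
    p[is_h(n1) & (n2 == _G)] = levels.get("CHG", 0.0)
    p[is_h(n1) & is_h(n2)] = levels.get("CHH", 0.0)
    p[c != _C] = 0.0
    if crick:
        p = p[::-1]
    return p


def assign_methylation(
    genome: ReferenceGenome, meth_levels: dict[str, float], seed: int = 0
) -> MethylationStates:
    """Independently methylate every cytosine with its context probability.

    Cytosines whose context is undeterminable (chromosome edge, N neighbor)
    stay unmethylated.
    """
    rng = np.random.default_rng(seed)
    watson: dict[str, np.ndarray] = {}
    crick: dict[str, np.ndarray] = {}
    for chrom in genome.chrom_names:
        codes = _encode(genome[chrom])
        pw = _context_levels(codes, crick=False, levels=meth_levels)
        pc = _context_levels(codes, crick=True, levels=meth_levels)
        watson[chrom] = rng.random(len(codes)) < pw
        crick[chrom] = rng.random(len(codes)) < pc
    return MethylationStates(watson=watson, crick=crick)


def _convert_molecule(
    codes: np.ndarray,
    meth: np.ndarray,
    failure: float,
    rng: np.random.Generator,
) -> tuple[np.ndarray, str]:
    """Bisulfite-convert a molecule-strand slice; returns (converted codes,
    '1'/'0' truth string over its cytosines)."""
    out = codes.copy()
    c_idx = np.nonzero(codes == _C)[0]
    if c_idx.size == 0:
        return out, ""
    m = meth[c_idx]
    escaped = rng.random(c_idx.size) < failure
    retained = m | escaped
    out[c_idx[~retained]] = _T
    return out, "".join("1" if x else "0" for x in m)


def _apply_errors(codes: np.ndarray, profile: np.ndarray | None, rng: np.random.Generator) -> np.ndarray:
    if profile is None:
        return codes
    L = len(codes)
    hit = rng.random(L) < profile[:L]
    idx = np.nonzero(hit & (codes != _N))[0]
    if idx.size:
        codes = codes.copy()
        codes[idx] = (codes[idx] + rng.integers(1, 4, idx.size)) % 4
    return codes


def simulate_reads(
    genome: ReferenceGenome,
    states: MethylationStates,
    params: SimParams,
    rr: RRGenome | None = None,
) -> tuple[list[Read], list[TruthRecord]]:
    """Simulate a read set with truth records.

    RRBS mode (``params.rrbs`` set) requires the matching pre-computed
    :class:`~trimeth.digest.RRGenome`; reads start at fragment 5' cut ends
    on both strands and never cross fragment boundaries.
    """
    rng = np.random.default_rng(params.seed)
    if params.rrbs is not None:
        if rr is None:
            raise ValueError("RRBS simulation requires the pre-computed RRGenome")
        if tuple(rr.size_range) != (params.rrbs.low, params.rrbs.high):
            raise ValueError(
                f"RRGenome size range {rr.size_range} does not match simulator "
                f"parameters ({params.rrbs.low}, {params.rrbs.high})"
            )
        if not rr.selected:
            raise ValueError("no selected fragments to simulate RRBS reads from")
    if params.paired and params.rrbs is not None:
        raise ValueError("paired-end simulation is whole-genome only")
    if params.paired and params.pe_insert_range[0] < params.read_length:
        raise ValueError("paired-end insert range must be >= read length")

    chrom_codes = {c: _encode(genome[c]) for c in genome.chrom_names}
    chroms = genome.chrom_names
    lengths = genome.lengths
    reads: list[Read] = []
    truths: list[TruthRecord] = []
    rl = params.read_length

    def molecule(chrom: str, s: int, e: int, crick: bool) -> tuple[np.ndarray, str]:
        """Converted molecule-strand codes over Watson interval [s, e)."""
        codes = chrom_codes[chrom][s:e]
        if crick:
            codes = _COMP_CODE[codes][::-1]
            meth = states.crick[chrom][s:e][::-1]
        else:
            meth = states.watson[chrom][s:e]
        return _convert_molecule(codes, meth, params.conversion_failure, rng)

    def emit(i, chrom, start, end, tag, frag_len, mol_codes, meth_str, adapter=""):
        core = mol_codes
        if not params.directional and rng.random() < 0.5:
            core = _COMP_CODE[core][::-1]
            tag = RC_TAG[tag]
        seq_codes = core
        if adapter:
            seq_codes = np.concatenate([core, _encode(adapter)])
        seq_codes = _apply_errors(seq_codes, params.error_profile, rng)
        seq = _decode(seq_codes)
        rid = f"r{i}"
        reads.append(Read(id=rid, seq=seq, qual="I" * len(seq)))
        truths.append(
            TruthRecord(
                read_id=rid,
                chrom=chrom,
                start=start,
                end=end,
                tag=tag,
                fragment_length=frag_len,
                meth_states=meth_str,
            )
        )

    if params.paired:
        lo, hi = params.pe_insert_range
        for i in range(params.n_reads):
            chrom = chroms[int(rng.integers(len(chroms)))]
            flen = int(rng.integers(lo, hi + 1))
            flen = min(flen, lengths[chrom])
            s = int(rng.integers(0, lengths[chrom] - flen + 1))
            e = s + flen
            crick = bool(rng.integers(2))
            mol, meth_str = molecule(chrom, s, e, crick)
            m1, m2 = mol[:rl], _COMP_CODE[mol[-rl:]][::-1]
            if crick:
                t1, i1 = "C_BS", (e - rl, e)
                t2, i2 = "W_BS_RC", (s, s + rl)
            else:
                t1, i1 = "W_BS", (s, s + rl)
                t2, i2 = "C_BS_RC", (e - rl, e)
            rid = f"r{i}"
            for mate, (mseq, tag, iv) in enumerate(((m1, t1, i1), (m2, t2, i2)), 1):
                mseq = _apply_errors(mseq, params.error_profile, rng)
                reads.append(
                    Read(id=rid, seq=_decode(mseq), qual="I" * rl, mate=mate)
                )
                truths.append(
                    TruthRecord(
                        read_id=rid,
                        chrom=chrom,
                        start=iv[0],
                        end=iv[1],
                        tag=tag,
                        fragment_length=flen,
                        meth_states="",
                    )
                )
        return reads, truths

    if params.rrbs is None:
        for i in range(params.n_reads):
            chrom = chroms[int(rng.integers(len(chroms)))]
            s = int(rng.integers(0, lengths[chrom] - rl + 1))
            e = s + rl
            crick = bool(rng.integers(2))
            mol, meth_str = molecule(chrom, s, e, crick)
            emit(i, chrom, s, e, "C_BS" if crick else "W_BS", rl, mol, meth_str)
    else:
        frags = rr.selected
        adapter = params.rrbs.adapter if params.rrbs.add_adapter else ""
        for i in range(params.n_reads):
            frag = frags[int(rng.integers(len(frags)))]
            flen = frag.length
            crick = bool(rng.integers(2))
            n = min(rl, flen)
            if crick:
                s, e = frag.end - n, frag.end
            else:
                s, e = frag.start, frag.start + n
            mol, meth_str = molecule(frag.chrom, s, e, crick)
            ad = adapter[: rl - n] if flen < rl else ""
            emit(i, frag.chrom, s, e, "C_BS" if crick else "W_BS", flen, mol, meth_str, ad)
    return reads, truths


# ---------------------------------------------------------------------------
# truth file I/O (tab-separated)

def write_truth(truths: Iterable[TruthRecord], path: str | Path) -> None:
    with open(path, "w") as fh:
        for t in truths:
            fh.write(
                f"{t.read_id}\t{t.chrom}\t{t.start}\t{t.end}\t{t.tag}\t"
                f"{t.fragment_length}\t{t.meth_states}\n"
            )


def read_truth(path: str | Path) -> list[TruthRecord]:
    out = []
    with open(path) as fh:
        for line in fh:
            f = line.rstrip("\n").split("\t")
            out.append(
                TruthRecord(f[0], f[1], int(f[2]), int(f[3]), f[4], int(f[5]),
                            f[6] if len(f) > 6 else "")
            )
    return out
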