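"""Reference genomes, three-letter conversion and alignment index bundles.

Bisulfite treatment deaminates unmethylated cytosine to uracil, which is
sequenced as thymine, while 5-methylcytosine is protected.  A bisulfite read
therefore differs from its genomic origin by an unknown subset of C->T
changes (or G->A changes when the complementary strand of the converted
molecule is sequenced).  The classic three-letter strategy removes this
asymmetry before the search: both the reads and the genome are collapsed
(C->T or G->A), so that conversion events are invisible during matching and
are only re-examined afterwards on the original letters.

Because the two genomic strands convert independently, four converted copies
of the reference are needed in the general (non-directional) case:

======  ===========================================  =====================
tag     text                                         read it is probed with
======  ===========================================  =====================
W_C2T   C->T collapse of the Watson strand           C->T converted read
C_C2T   C->T collapse of the Crick strand (revcomp)  C->T converted read
W_G2A   G->A collapse of the Watson strand           G->A converted read
C_G2A   G->A collapse of the Crick strand            G->A converted read
======  ===========================================  =====================

Directional libraries only produce reads from the two original converted
strands, so only W_C2T and C_C2T are searched for them.

Coordinates are 0-based half-open on the Watson strand everywhere inside the
package; 1-based coordinates appear only at the file-format boundary (SAM,
CGmap, ATCGmap, WIG).
"""

from __future__ import annotations

import hashlib
import json
import logging
import re
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterator, Mapping, Sequence

from Bio import SeqIO

log = logging.getLogger(__name__)

VALID_BASES = frozenset("ACGTN")

_COMP = str.maketrans("ACGTN", "TGCAN")
_C2T = str.maketrans("C", "T")
_G2A = str.maketrans("G", "A")
_NON_BASE = re.compile(r"[^ACGTN]")

#: the four index instance tags
INSTANCE_TAGS = ("W_C2T", "C_C2T", "W_G2A", "C_G2A")
#: instances searched for directional libraries
DIRECTIONAL_TAGS = ("W_C2T", "C_C2T")


def complement(seq: str) -> str:
    """Base-wise complement (N stays N)."""
    return seq.translate(_COMP)


def revcomp(seq: str) -> str:
    """Reverse complement."""
    return seq.translate(_COMP)[::-1]


def convert_sequence(seq: str, rule: str) -> str:
    """Collapse a sequence to the three-letter alphabet.

    ``C2T`` replaces every C with T; ``G2A`` replaces every G with A.  Length
    and all other characters (including N) are preserved.
    """
    if rule == "C2T":
        return seq.translate(_C2T)
    if rule == "G2A":
        return seq.translate(_G2A)
    raise ValueError(f"unknown conversion rule: {rule!r} (expected 'C2T' or 'G2A')")


class FastaFormatError(ValueError):
    """Raised for malformed FASTA input."""


class ReferenceGenome:
    """Named chromosome sequences over {A,C,G,T,N}.

    The coordinate authority for every downstream record.  Sequences are
    stored uppercase; insertion order of chromosomes is preserved.
    """

    def __init__(self, sequences: Mapping[str, str]):
        if not sequences:
            raise ValueError("genome must contain at least one chromosome")
        self._seqs: dict[str, str] = {}
        for name, seq in sequences.items():
            if not name:
                raise ValueError("empty chromosome name")
            if name in self._seqs:
                raise ValueError(f"duplicate chromosome name: {name!r}")
            seq = seq.upper()
            if not seq:
                raise ValueError(f"chromosome {name!r} has an empty sequence")
            bad = set(seq) - VALID_BASES
            if bad:
                raise ValueError(
                    f"chromosome {name!r} contains invalid characters: {sorted(bad)}"
                )
            self._seqs[name] = seq

    @property
    def chrom_names(self) -> list[str]:
        return list(self._seqs)

    @property
    def sequences(self) -> dict[str, str]:
        return dict(self._seqs)

    @property
    def lengths(self) -> dict[str, int]:
        return {n: len(s) for n, s in self._seqs.items()}

    def __getitem__(self, name: str) -> str:
        return self._seqs[name]

    def __contains__(self, name: str) -> bool:
        return name in self._seqs

    def __iter__(self) -> Iterator[str]:
        return iter(self._seqs)

    def __eq__(self, other) -> bool:
        return isinstance(other, ReferenceGenome) and self._seqs == other._seqs

    def checksum(self) -> str:
        """MD5 over the normalized FASTA rendering; used to pair indexes
        with the genome they were built from."""
        h = hashlib.md5()
        for name, seq in self._seqs.items():
            h.update(f">{name}\n{seq}\n".encode())
        return h.hexdigest()


def read_fasta(path: str | Path) -> ReferenceGenome:
    """Read a (possibly line-wrapped, mixed-case) FASTA file.

    Characters outside {A,C,G,T,N} are replaced by N with a logged warning.
    An empty file, or sequence text appearing before any header, is a
    :class:`FastaFormatError` naming the offending line.
    """
    path = Path(path)
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            stripped = line.strip()
            if not stripped:
                continue
            if not stripped.startswith(">"):
                raise FastaFormatError(
                    f"{path}: line {lineno}: sequence data before the first "
                    f"'>' header"
                )
            break
        else:
            raise FastaFormatError(f"{path}: empty FASTA file")

    seqs: dict[str, str] = {}
    replaced = 0
    for rec in SeqIO.parse(str(path), "fasta"):
        seq = str(rec.seq).upper()
        cleaned, n_sub = _NON_BASE.subn("N", seq)
        replaced += n_sub
        seqs[rec.id] = cleaned
    if replaced:
        log.warning(
            "%s: replaced %d non-ACGTN characters by N", path, replaced
        )
    return ReferenceGenome(seqs)


def write_fasta(genome: ReferenceGenome, path: str | Path, width: int = 60) -> None:
    """Write a genome as wrapped FASTA."""
    with open(path, "w") as fh:
        for name in genome.chrom_names:
            fh.write(f">{name}\n")
            seq = genome[name]
            for i in range(0, len(seq), width):
                fh.write(seq[i : i + width] + "\n")


@dataclass(eq=False)
class IndexInstance:
    """One converted copy of the reference.

    ``converted_sequences`` for the Crick-derived instances hold the
    reverse-complemented text; hit positions are mapped back to Watson
    coordinates at report time so that the Watson strand stays the single
    coordinate authority.
    """

    tag: str
    converted_sequences: dict[str, str]
    source: "ReferenceGenome"
    # lazy per-chromosome search structures, owned by the aligner
    _search_cache: dict = field(default_factory=dict, repr=False)

    @property
    def is_crick(self) -> bool:
        """True when the text is the reverse complement of Watson."""
        return self.tag.startswith("C_")


@dataclass(eq=False)
class IndexBundle:
    """The four converted index instances plus provenance.

    ``genome`` is the original (unmasked) reference — the coordinate and
    context authority.  ``align_genome`` is what hits are verified against:
    the masked copy for reduced-representation indexes, else ``genome``
    itself.  Masked N positions are never matchable, which is exactly what
    confines alignment to the selected fragments.
    """

    instances: dict[str, IndexInstance]
    genome: ReferenceGenome
    align_genome: ReferenceGenome
    is_rr: bool = False
    mask_intervals: list = field(default_factory=list)
    rr_params: dict | None = None

    @property
    def directional_instances(self) -> list[IndexInstance]:
        return [self.instances[t] for t in DIRECTIONAL_TAGS]

    def __getitem__(self, tag: str) -> IndexInstance:
        return self.instances[tag]


def build_index(genome, directional: bool = True) -> IndexBundle:
    """Build the four converted index instances from a genome.

    ``genome`` may be a :class:`ReferenceGenome` or an
    ``rr_digest.RRGenome``; for the latter the masked copy is converted, so
    regions outside the size-selected fragments can never be matched.  All
    four instances are always materialized; the ``directional`` choice of
    which to search is made at alignment time (the flag is retained for
    provenance).
    """
    from .digest import RRGenome  # local import to avoid a cycle

    if isinstance(genome, RRGenome):
        source = genome.source
        text = ReferenceGenome(genome.masked)
        is_rr = True
        mask_intervals = list(genome.selected)
        rr_params = {"low": genome.size_range[0], "high": genome.size_range[1]}
    else:
        source = genome
        text = genome
        is_rr = False
        mask_intervals = []
        rr_params = None

    instances = {}
    for tag in INSTANCE_TAGS:
        strand, rule = tag.split("_")
        conv = {}
        for name in text.chrom_names:
            seq = text[name] if strand == "W" else revcomp(text[name])
            conv[name] = convert_sequence(seq, rule)
        instances[tag] = IndexInstance(tag=tag, converted_sequences=conv, source=source)

    return IndexBundle(
        instances=instances,
        genome=source,
        align_genome=text,
        is_rr=is_rr,
        mask_intervals=mask_intervals,
        rr_params=rr_params,
    )


# ---------------------------------------------------------------------------
# index persistence

_PARAMS_FILE = "params.json"


def save_index(bundle: IndexBundle, directory: str | Path, directional: bool = True) -> None:
    """Persist an index bundle as a directory of plain-text files.

    Layout: ``genome.fa`` (original reference), ``masked.fa`` +
    ``fragments.bed`` for reduced-representation indexes, one FASTA per
    converted instance, and ``params.json`` holding the genome checksum and
    build parameters.  Reloading is byte-identical in behavior.
    """
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    write_fasta(bundle.genome, directory / "genome.fa")
    if bundle.is_rr:
        write_fasta(bundle.align_genome, directory / "masked.fa")
        with open(directory / "fragments.bed", "w") as fh:
            for k, frag in enumerate(bundle.mask_intervals):
                fh.write(
                    f"{frag.chrom}\t{frag.start}\t{frag.end}\tfrag{k}\t"
                    f"{frag.end - frag.start}\t+\n"
                )
    for tag, inst in bundle.instances.items():
        write_fasta(ReferenceGenome(inst.converted_sequences), directory / f"{tag}.fa")
    params = {
        "checksum": bundle.genome.checksum(),
        "directional": directional,
        "is_rr": bundle.is_rr,
        "rr_params": bundle.rr_params,
    }
    (directory / _PARAMS_FILE).write_text(json.dumps(params, indent=2) + "\n")


def load_index(directory: str | Path) -> IndexBundle:
    """Reload a persisted index directory (see :func:`save_index`)."""
    directory = Path(directory)
    params = json.loads((directory / _PARAMS_FILE).read_text())
    genome = read_fasta(directory / "genome.fa")
    if genome.checksum() != params["checksum"]:
        raise ValueError(
            f"{directory}: stored genome does not match recorded checksum"
        )
    is_rr = params["is_rr"]
    align_genome = read_fasta(directory / "masked.fa") if is_rr else genome
    mask_intervals = []
    if is_rr:
        from .digest import DigestFragment

        with open(directory / "fragments.bed") as fh:
            for line in fh:
                chrom, start, end, *_ = line.rstrip("\n").split("\t")
                mask_intervals.append(DigestFragment(chrom, int(start), int(end)))
    instances = {}
    for tag in INSTANCE_TAGS:
        conv = read_fasta(directory / f"{tag}.fa")
        instances[tag] = IndexInstance(
            tag=tag, converted_sequences=conv.sequences, source=genome
        )
    return IndexBundle(
        instances=instances,
        genome=genome,
        align_genome=align_genome,
        is_rr=is_rr,
        mask_intervals=mask_intervals,
        rr_params=params.get("rr_params"),
    )
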