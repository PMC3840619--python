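"""In-silico restriction digestion and reduced-representation genome masking.

RRBS libraries are produced by digesting genomic DNA with a restriction
enzyme (classically MspI, which cuts C'CGG) and size-selecting the resulting
fragments, so the sequenced reads can only originate from a small,
CpG-enriched subset of the genome.  Mapping such reads against the whole
genome wastes the search space and — worse — creates *pseudo-multiple hits*:
a read from a selected fragment whose equally good second match lies in a
region the library can never produce, causing spurious ambiguity.

This module reproduces the library structure in silico: cut every
chromosome at the enzyme sites, keep fragments whose length falls in the
size-selection window, and mask everything else with N.  Because N is never
matchable, building the alignment index from the masked text confines hits
to the true origin space of the library.
"""

from __future__ import annotations

import logging
import re
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Sequence

from .genome import ReferenceGenome

log = logging.getLogger(__name__)

_MARKERS = ("'", "-", "’")  # apostrophe, hyphen, typographic apostrophe


class CutSiteParseError(ValueError):
    pass


@dataclass(frozen=True)
class CutSiteSpec:
    """A recognition sequence with the cut position marked inside it.

    ``cut_offset`` is the 0-based index within ``recognition`` where the
    enzyme cuts, e.g. MspI C'CGG -> recognition CCGG, cut_offset 1.
    """

    recognition: str
    cut_offset: int

    def __post_init__(self):
        if not self.recognition:
            raise ValueError("empty recognition sequence")
        if set(self.recognition) - set("ACGT"):
            raise ValueError(f"recognition must be over ACGT: {self.recognition!r}")
        if not 0 <= self.cut_offset <= len(self.recognition):
            raise ValueError("cut_offset outside the recognition sequence")


def parse_cut_site(spec: str) -> CutSiteSpec:
    """Parse an enzyme specification like ``C'CGG`` (apostrophe or hyphen
    marks the cut)."""
    s = spec.strip().upper()
    marker_positions = [i for i, ch in enumerate(s) if ch in _MARKERS]
    if len(marker_positions) != 1:
        raise CutSiteParseError(
            f"cut-site spec {spec!r} must contain exactly one cut marker "
            f"(' or -), found {len(marker_positions)}"
        )
    offset = marker_positions[0]
    recognition = s[:offset] + s[offset + 1 :]
    if not recognition or set(recognition) - set("ACGT"):
        raise CutSiteParseError(
            f"cut-site spec {spec!r} must consist of A/C/G/T letters around "
            f"the cut marker"
        )
    return CutSiteSpec(recognition=recognition, cut_offset=offset)


@dataclass(frozen=True, order=True)
class DigestFragment:
    """A digestion fragment in 0-based half-open Watson coordinates."""

    chrom: str
    start: int
    end: int

    def __post_init__(self):
        if not 0 <= self.start < self.end:
            raise ValueError(f"invalid fragment interval [{self.start},{self.end})")

    @property
    def length(self) -> int:
        return self.end - self.start


def digest(genome: ReferenceGenome, enzymes: Sequence[CutSiteSpec]) -> list[DigestFragment]:
    """Cut every chromosome at the union of enzyme cut coordinates.

    Overlapping recognition occurrences all contribute cuts, and multiple
    enzymes are treated as a simultaneous double (or higher) digestion.  The
    returned fragments are sorted and tile each chromosome exactly; a
    chromosome without any site yields a single whole-chromosome fragment.
    """
    if not enzymes:
        raise ValueError("at least one enzyme is required")
    fragments: list[DigestFragment] = []
    for chrom in genome.chrom_names:
        seq = genome[chrom]
        cuts = {0, len(seq)}
        for enz in enzymes:
            # lookahead regex so overlapping occurrences are all found
            pat = re.compile(f"(?={re.escape(enz.recognition)})")
            for m in pat.finditer(seq):
                cut = m.start() + enz.cut_offset
                if 0 < cut < len(seq):
                    cuts.add(cut)
        coords = sorted(cuts)
        fragments.extend(
            DigestFragment(chrom, a, b) for a, b in zip(coords, coords[1:])
        )
    return fragments


@dataclass(eq=False)
class RRGenome:
    """A reference genome restricted to size-selected digestion fragments.

    ``masked`` equals the source text inside selected fragments and holds N
    everywhere else.
    """

    source: ReferenceGenome
    selected: list[DigestFragment]
    size_range: tuple[int, int]
    masked: dict[str, str]


def select_and_mask(
    genome: ReferenceGenome,
    fragments: Iterable[DigestFragment],
    low: int,
    high: int,
) -> RRGenome:
    """Size-select fragments (inclusive bounds) and mask the remainder.

    Fragments with ``low <= length <= high`` keep their source bases; every
    other position is replaced by N in the masked copy.
    """
    if not 0 < low <= high:
        raise ValueError(f"invalid size range [{low}, {high}]")
    selected = sorted(f for f in fragments if low <= f.length <= high)
    if not selected:
        log.warning(
            "size range [%d, %d] selected no fragments; the masked genome is "
            "entirely N",
            low,
            high,
        )
    masked = {}
    by_chrom: dict[str, list[DigestFragment]] = {}
    for frag in selected:
        by_chrom.setdefault(frag.chrom, []).append(frag)
    for chrom in genome.chrom_names:
        seq = genome[chrom]
        buf = ["N"] * len(seq)
        for frag in by_chrom.get(chrom, []):
            buf[frag.start : frag.end] = seq[frag.start : frag.end]
        masked[chrom] = "".join(buf)
    return RRGenome(
        source=genome, selected=selected, size_range=(low, high), masked=masked
    )


def write_bed(fragments: Sequence[DigestFragment], path: str | Path) -> None:
    """Emit selected fragments as 6-column BED for auditability."""
    with open(path, "w") as fh:
        for k, frag in enumerate(fragments):
            fh.write(
                f"{frag.chrom}\t{frag.start}\t{frag.end}\tfrag{k}\t"
                f"{frag.length}\t+\n"
            )
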