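"""Built-in 3' adapter removal.

RRBS fragments are frequently shorter than the read length, so the
sequencer runs into the ligated 3' adapter; those bases must be removed
before alignment (end-to-end alignment would otherwise count them as
mismatches).  The adapter is ligated after bisulfite conversion and is
therefore matched in plain four-letter space.

Matching uses leftmost semantics: the first read position where a prefix of
the adapter aligns against the read suffix within the mismatch tolerance
wins, trimming the longest possible tail — the convention of standard 3'
adapter trimmers.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Iterable, Iterator

from .reads import Read

log = logging.getLogger(__name__)

#: standard Illumina TruSeq read-1 adapter
DEFAULT_ADAPTER = "AGATCGGAAGAGCACACGTCTGAACTCCAGTCA"


@dataclass(frozen=True)
class AdapterSpec:
    sequence: str = DEFAULT_ADAPTER
    min_overlap: int = 3
    max_mismatch_rate: float = 0.1

    def __post_init__(self):
        if not self.sequence or set(self.sequence) - set("ACGT"):
            raise ValueError("adapter sequence must be non-empty over ACGT")
        if self.min_overlap < 1:
            raise ValueError("min_overlap must be >= 1")
        if not 0 <= self.max_mismatch_rate < 0.5:
            raise ValueError("max_mismatch_rate must be in [0, 0.5)")


def trim_adapter(read: Read, adapter: AdapterSpec | None = None) -> Read:
    """Truncate a read at the leftmost adapter match; unchanged if none.

    A match is a read suffix of length >= ``min_overlap`` agreeing with the
    adapter prefix at a mismatch rate <= ``max_mismatch_rate``.  The returned
    read may be empty; dropping short reads is the caller's (or
    :func:`trim_stream`'s) job.
    """
    adapter = adapter or AdapterSpec()
    seq = read.seq
    a = adapter.sequence
    L = len(seq)
    for i in range(0, L - adapter.min_overlap + 1):
        overlap = min(L - i, len(a))
        allowed = int(adapter.max_mismatch_rate * overlap)
        mm = 0
        for x, y in zip(seq[i : i + overlap], a):
            if x != y:
                mm += 1
                if mm > allowed:
                    break
        else:
            return read.truncated(i)
    return read


@dataclass
class TrimStats:
    n_reads: int = 0
    n_trimmed: int = 0
    n_dropped: int = 0


def trim_stream(
    reads: Iterable[Read],
    adapter: AdapterSpec | None = None,
    min_read_length: int = 20,
    stats: TrimStats | None = None,
) -> Iterator[Read]:
    """Trim a read stream, dropping reads left shorter than
    ``min_read_length`` (count logged and kept in ``stats``)."""
    adapter = adapter or AdapterSpec()
    stats = stats if stats is not None else TrimStats()
    for read in reads:
        stats.n_reads += 1
        trimmed = trim_adapter(read, adapter)
        if len(trimmed) < len(read):
            stats.n_trimmed += 1
        if len(trimmed) < min_read_length:
            stats.n_dropped += 1
            continue
        yield trimmed
    if stats.n_dropped:
        log.info(
            "adapter trimming dropped %d/%d reads shorter than %d bp",
            stats.n_dropped,
            stats.n_reads,
            min_read_length,
        )
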