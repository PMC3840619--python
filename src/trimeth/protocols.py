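"""Scaled-down simulation evaluation protocols.

Each protocol generates a seeded synthetic genome, simulates error-free
directional bisulfite reads, aligns them with the built-in aligner (up to 5
bisulfite-aware mismatches, end-to-end) and scores mappability/accuracy
against the simulation truth:

* WGBS — 100 bp single-end reads drawn uniformly from both strands of the
  whole genome.
* RRBS — reads anchored at the cut ends of MspI (C'CGG) fragments
  size-selected to 40-250 bp, aligned against the reduced-representation
  (masked) index; optionally the full pipeline variant where fragments
  shorter than the read length carry sequenced-through adapter and the
  built-in trimmer runs first.

All randomness derives from a single integer seed.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .align import AlignParams, align_read
from .digest import digest, parse_cut_site, select_and_mask
from .evaluate import EvalReport, evaluate
from .genome import build_index
from .simulate import (
    RRBSSimParams,
    SimParams,
    assign_methylation,
    generate_genome,
    simulate_reads,
)
from .trim import AdapterSpec, trim_stream

DEFAULT_METH = {"CG": 0.7, "CHG": 0.02, "CHH": 0.02}


def _sub_seeds(seed: int, n: int) -> list[int]:
    state = np.random.SeedSequence(seed).generate_state(n)
    return [int(s % (2**31)) for s in state]


@dataclass
class ProtocolResult:
    report: EvalReport
    n_reads: int

    @property
    def accuracy_percent(self) -> float:
        acc = self.report.accuracy
        return float("nan") if acc is None else round(100.0 * acc, 2)

    @property
    def mappability_percent(self) -> float:
        return round(100.0 * self.report.mappability, 2)


def wgbs_accuracy_protocol(
    seed: int,
    n_reads: int = 10_000,
    genome_length: int = 1_000_000,
    read_length: int = 100,
) -> ProtocolResult:
    """Error-free single-end WGBS simulation, end-to-end alignment."""
    s_genome, s_meth, s_reads = _sub_seeds(seed, 3)
    genome = generate_genome(genome_length, 0.5, s_genome)
    states = assign_methylation(genome, DEFAULT_METH, s_meth)
    bundle = build_index(genome)
    params = SimParams.error_free(
        genome_length=genome_length,
        read_length=read_length,
        n_reads=n_reads,
        meth_levels=DEFAULT_METH,
        seed=s_reads,
    )
    reads, truths = simulate_reads(genome, states, params)
    align_params = AlignParams(max_mismatches=5)
    records = [align_read(r, bundle, params=align_params) for r in reads]
    return ProtocolResult(report=evaluate(records, truths), n_reads=n_reads)


def rrbs_accuracy_protocol(
    seed: int,
    n_reads: int = 10_000,
    genome_length: int = 1_000_000,
    read_length: int = 100,
    low: int = 40,
    high: int = 250,
    with_adapter: bool = False,
) -> ProtocolResult:
    """Error-free RRBS simulation against the reduced-representation index.

    ``with_adapter`` runs the full pipeline: fragments shorter than the read
    length are sequenced into the 3' adapter and the built-in trimmer is
    applied before alignment.
    """
    s_genome, s_meth, s_reads = _sub_seeds(seed, 3)
    genome = generate_genome(genome_length, 0.5, s_genome)
    states = assign_methylation(genome, DEFAULT_METH, s_meth)
    fragments = digest(genome, [parse_cut_site("C'CGG")])
    rr = select_and_mask(genome, fragments, low, high)
    bundle = build_index(rr)
    params = SimParams.error_free(
        genome_length=genome_length,
        read_length=read_length,
        n_reads=n_reads,
        meth_levels=DEFAULT_METH,
        seed=s_reads,
        rrbs=RRBSSimParams(low=low, high=high, add_adapter=with_adapter),
    )
    reads, truths = simulate_reads(genome, states, params, rr)
    if with_adapter:
        reads = list(trim_stream(reads, AdapterSpec(), min_read_length=20))
    align_params = AlignParams(max_mismatches=5)
    records = [align_read(r, bundle, params=align_params) for r in reads]
    tmap = {t.read_id: t for t in truths}
    truth_used = [tmap[r.read.id] for r in records]
    return ProtocolResult(report=evaluate(records, truth_used), n_reads=n_reads)
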