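"""Mappability and accuracy evaluation against simulation truth.

Mappability is the fraction of reads with a unique best hit; accuracy is the
fraction of uniquely mapped reads placed at their true origin.  A placement
is judged correct when chromosome and bisulfite strand tag match the truth
and the read's 5' anchor coordinate is within ``tolerance`` of the true one.

The 5' anchor is the Watson-leftmost coordinate for forward-placed tags
(W_BS, W_BS_RC) and the Watson-rightmost for reverse-placed tags (C_BS,
C_BS_RC), with soft-clipped ends folded back in: a local alignment that
clips a contaminated 3' tail, or an adapter trim that shortens the read,
leaves the 5' anchor untouched and is still judged correct.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from typing import Iterable, Mapping

from .align import IS_REVERSE, AlignmentRecord
from .simulate import TruthRecord


@dataclass
class EvalReport:
    n_total: int
    n_unique: int
    n_multiple: int
    n_unmapped: int
    n_correct: int

    @property
    def mappability(self) -> float:
        return self.n_unique / self.n_total if self.n_total else 0.0

    @property
    def accuracy(self) -> float | None:
        """correct / unique; None (reported as "na") when nothing mapped."""
        return self.n_correct / self.n_unique if self.n_unique else None

    def to_dict(self) -> dict:
        acc = self.accuracy
        return {
            "n_total": self.n_total,
            "n_unique": self.n_unique,
            "n_multiple": self.n_multiple,
            "n_unmapped": self.n_unmapped,
            "n_correct": self.n_correct,
            "mappability": self.mappability,
            "accuracy": "na" if acc is None else acc,
        }

    def to_json(self) -> str:
        return json.dumps(self.to_dict(), indent=2)

    def summary(self) -> str:
        acc = self.accuracy
        return (
            f"reads: {self.n_total}  unique: {self.n_unique}  "
            f"multiple: {self.n_multiple}  unmapped: {self.n_unmapped}\n"
            f"mappability: {self.mappability:.2%}  "
            f"accuracy: {'na' if acc is None else format(acc, '.2%')}"
        )


def _correct(rec: AlignmentRecord, truth: TruthRecord, tolerance: int) -> bool:
    hit = rec.hit
    if hit.chrom != truth.chrom or hit.tag != truth.tag:
        return False
    if IS_REVERSE[hit.tag]:
        return abs(hit.inferred_end - truth.end) <= tolerance
    return abs(hit.inferred_start - truth.start) <= tolerance


def evaluate(
    records: Iterable[AlignmentRecord],
    truth: Iterable[TruthRecord] | Mapping[str, TruthRecord],
    tolerance: int = 0,
) -> EvalReport:
    """Score alignment records against truth records (matched by read id;
    for mate pairs, by read id and mate number)."""
    tmap: dict[str, list[TruthRecord]] = {}
    items = truth.values() if isinstance(truth, Mapping) else truth
    for t in items:
        tmap.setdefault(t.read_id, []).append(t)
    n_total = n_unique = n_multiple = n_unmapped = n_correct = 0
    for rec in records:
        key = rec.read.id
        if key not in tmap:
            raise ValueError(f"read {key!r} missing from truth records")
        candidates = tmap[key]
        if rec.read.mate in (1, 2) and len(candidates) >= rec.read.mate:
            t = candidates[rec.read.mate - 1]
        else:
            t = candidates[0]
        n_total += 1
        if rec.status == "unique":
            n_unique += 1
            if _correct(rec, t, tolerance):
                n_correct += 1
        elif rec.status == "multiple":
            n_multiple += 1
        else:
            n_unmapped += 1
    return EvalReport(
        n_total=n_total,
        n_unique=n_unique,
        n_multiple=n_multiple,
        n_unmapped=n_unmapped,
        n_correct=n_correct,
    )
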