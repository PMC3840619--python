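"""Independent oracles used by the test suite.

These deliberately avoid the implementation's search machinery: the
end-to-end oracle scans every placement of every instance with a plain
shift-and-compare, and the gapped/local oracle is a direct textbook affine
dynamic program without vectorization tricks or seeding.
"""

from __future__ import annotations

import numpy as np

from trimeth.align import INSTANCE_OF_TAG, READ_RULE, READ_TAGS, TAG_OF_INSTANCE
from trimeth.genome import convert_sequence

_CODE = {b: i for i, b in enumerate("ACGT")}


def _enc(seq: str) -> np.ndarray:
    return np.array([_CODE.get(b, 4) for b in seq], dtype=np.int64)


def hamming_scan(text: str, read: str) -> np.ndarray:
    """Mismatch count of the read at every offset (N never matches)."""
    t = _enc(text)
    r = _enc(read)
    G, L = len(t), len(r)
    if G < L:
        return np.empty(0, np.int64)
    mm = np.zeros(G - L + 1, np.int64)
    for i in range(L):
        col = t[i : i + G - L + 1]
        mm += (col != r[i]) | (col == 4) | (r[i] == 4)
    return mm


def best_placements_3letter(read_seq: str, bundle, directional: bool, max_mm: int):
    """Globally best three-letter placements across searched instances.

    Returns (best_mm, [(chrom, watson_pos, tag), ...]); the list is empty
    when no placement is within the mismatch radius.
    """
    tags = ["W_BS", "C_BS"] if directional else list(READ_TAGS)
    best = None
    placements = []
    for tag in tags:
        conv = convert_sequence(read_seq, READ_RULE[tag])
        inst = bundle[INSTANCE_OF_TAG[tag]]
        for chrom, text in inst.converted_sequences.items():
            mm = hamming_scan(text, conv)
            for off in range(len(mm)):
                m = int(mm[off])
                if m > max_mm:
                    continue
                if inst.is_crick:
                    pos = len(text) - (off + len(conv))
                else:
                    pos = off
                if best is None or m < best:
                    best = m
                    placements = [(chrom, pos, tag)]
                elif m == best:
                    placements.append((chrom, pos, tag))
    return best, placements


def dp_best_score(text: str, read: str, params, local: bool):
    """Plain-Python affine-gap DP: best score and its end columns.

    For ``local`` the score is the Smith-Waterman maximum over all cells per
    end column; otherwise the read must be fully consumed (free reference
    prefix and suffix).
    """
    g = _enc(text)
    r = _enc(read)
    G, L = len(g), len(r)
    match = params.match_bonus if local else 0
    mis = -params.mismatch_penalty
    go, ge = params.gap_open, params.gap_extend
    NEG = -(10**9)
    H = [0] * (G + 1)
    F = [NEG] * (G + 1)
    col_best = [0] * (G + 1) if local else None
    for i in range(1, L + 1):
        rb = r[i - 1]
        Hn = [0] * (G + 1)
        En = [NEG] * (G + 1)
        Fn = [NEG] * (G + 1)
        Hn[0] = 0 if local else NEG
        for j in range(1, G + 1):
            gb = g[j - 1]
            s = match if (gb == rb and gb != 4 and rb != 4) else mis
            En[j] = max(Hn[j - 1] - go - ge, En[j - 1] - ge)
            Fn[j] = max(H[j] - go - ge, F[j] - ge)
            v = max(H[j - 1] + s, En[j], Fn[j])
            if local:
                v = max(v, 0)
            Hn[j] = v
            if local and v > col_best[j]:
                col_best[j] = v
        H, F = Hn, Fn
    scores = col_best if local else H
    best = max(scores)
    ends = [j for j, v in enumerate(scores) if v == best]
    return best, ends
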