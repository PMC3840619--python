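import numpy as np
import pytest

from trimeth.align import (
    AlignParams,
    AlignmentHit,
    align_pair,
    align_read,
    convert_read,
    methylation_string,
    recount_mismatches,
    search_instance,
)
from trimeth.genome import ReferenceGenome, build_index
from trimeth.reads import Read
from trimeth.simulate import SimParams, assign_methylation, generate_genome, simulate_reads


def _hit(chrom, pos, tag, ops, read_id="r"):
    return AlignmentHit(
        read_id=read_id, chrom=chrom, pos=pos, tag=tag, ops=tuple(ops),
        score=0, three_letter_mismatches=0,
    )


short = AlignParams(min_read_length=3, max_mismatches=2)


@pytest.mark.parametrize(
    "seq,rule,expected",
    [("TTCGA", "C2T", "TTTGA"), ("TTCGA", "G2A", "TTCAA"), ("AAAA", "C2T", "AAAA")],
)
def test_convert_read_keeps_original(seq, rule, expected):
    conv = convert_read(Read(id="r", seq=seq), rule)
    assert conv.seq == expected
    assert conv.orig_seq == seq


def test_search_instance_exact_substring():
    bundle = build_index(ReferenceGenome({"c1": "ATGTA"}))
    hits = search_instance(Read(id="r", seq="TGT"), bundle["W_C2T"], params=short)
    assert hits[0].pos == 1
    assert hits[0].three_letter_mismatches == 0


def test_search_instance_reports_two_best_on_duplicate():
    bundle = build_index(ReferenceGenome({"c1": "ATGTTAAAAATGTTA"}))
    hits = search_instance(Read(id="r", seq="TGTT"), bundle["W_C2T"], params=short)
    assert len(hits) == 2
    assert [h.pos for h in hits] == [1, 10]
    assert hits[0].score == hits[1].score


def test_search_instance_matches_minimum_hamming_distance():
    rng = np.random.default_rng(5)
    seq = "".join("ACGT"[i] for i in rng.integers(0, 4, 400))
    bundle = build_index(ReferenceGenome({"c1": seq}))
    inst = bundle["W_C2T"]
    text = inst.converted_sequences["c1"]
    for trial in range(20):
        start = int(rng.integers(0, 370))
        read = list(text[start : start + 30])
        for j in rng.choice(30, size=int(rng.integers(0, 4)), replace=False):
            read[j] = "ACGT"[int(rng.integers(0, 4))]
        read = "".join(read)
        # brute force in converted space
        best = min(
            sum(a != b or a == "N" for a, b in zip(text[o : o + 30], read))
            for o in range(len(text) - 29)
        )
        hits = search_instance(
            Read(id="r", seq=read), inst, params=AlignParams(max_mismatches=5)
        )
        if best > 5:
            assert not hits or hits[0].three_letter_mismatches > 5
        else:
            assert hits[0].three_letter_mismatches == best


def test_align_read_methylated_read_matches_reference():
    # genome carries a CpG; the methylated read retains its C
    bundle = build_index(ReferenceGenome({"c1": "ATCGAAT"}))
    rec = align_read(Read(id="r", seq="TCGAA"), bundle, params=short)
    assert rec.status == "unique"
    assert (rec.hit.chrom, rec.hit.pos, rec.hit.tag) == ("c1", 1, "W_BS")
    assert rec.bs_mismatches == 0


def test_align_read_converted_read_has_no_bs_mismatch():
    bundle = build_index(ReferenceGenome({"c1": "ATCGAAT"}))
    rec = align_read(Read(id="r", seq="TTGAA"), bundle, params=short)
    assert rec.status == "unique"
    assert rec.hit.pos == 1
    assert rec.bs_mismatches == 0  # read T over genome C is a conversion


def test_align_read_tie_is_multiple():
    bundle = build_index(ReferenceGenome({"c1": "GGTCGAACCAAGGTCGAACC"}))
    rec = align_read(Read(id="r", seq="TCGAA"), bundle, params=short)
    assert rec.status == "multiple"
    assert rec.reason == "multiple"


def test_align_read_too_short_is_unmapped_with_reason():
    bundle = build_index(ReferenceGenome({"c1": "ATCGAAT" * 10}))
    rec = align_read(Read(id="r", seq="ACGT"), bundle)  # default min length 20
    assert rec.status == "unmapped"
    assert rec.reason == "too_short"


def test_read_c_over_genome_t_rejected_by_mismatch_cap():
    # six read-C-over-genome-T columns are invisible in three-letter space
    # but must be counted on the original letters and exceed the default cap
    rng = np.random.default_rng(11)
    seq = "".join("ACGT"[i] for i in rng.integers(0, 4, 2000))
    genome = ReferenceGenome({"c1": seq})
    bundle = build_index(genome)
    start = 500
    read = list(seq[start : start + 60])
    t_cols = [i for i, b in enumerate(read) if b == "T"][:6]
    assert len(t_cols) == 6
    for i in t_cols:
        read[i] = "C"
    rec = align_read(Read(id="r", seq="".join(read)), bundle)
    assert rec.status == "unmapped"
    assert rec.reason == "mismatch"
    # five such columns stay within the cap
    read2 = list(seq[start : start + 60])
    for i in t_cols[:5]:
        read2[i] = "C"
    rec2 = align_read(Read(id="r", seq="".join(read2)), bundle)
    assert rec2.status == "unique"
    assert rec2.bs_mismatches == 5


@pytest.mark.parametrize(
    "genome_seq,read_seq,tag,expected",
    [
        ("TCGA", "TTGA", "W_BS", 0),   # T over C = conversion
        ("TTGA", "CTGA", "W_BS", 1),   # C over T = mismatch
        ("TCGA", "TCGA", "W_BS", 0),
        ("TNGA", "TCGA", "W_BS", 1),   # N is never a match
    ],
)
def test_recount_mismatches_rule(genome_seq, read_seq, tag, expected):
    genome = ReferenceGenome({"c1": genome_seq})
    hit = _hit("c1", 0, tag, [("M", len(read_seq))])
    assert recount_mismatches(hit, read_seq, genome) == expected


def test_recount_mismatches_ga_rule_for_rc_tag():
    genome = ReferenceGenome({"c1": "TGGA"})
    hit = _hit("c1", 0, "W_BS_RC", [("M", 4)])
    assert recount_mismatches(hit, "TAGA", genome) == 0  # A over G allowed
    assert recount_mismatches(hit, "TTGA", genome) == 1


@pytest.mark.parametrize(
    "read_seq,expected",
    [("ACGT", ".Z.."), ("ATGT", ".z.."), ("AGGT", "....")],
)
def test_methylation_string_cpg(read_seq, expected):
    genome = ReferenceGenome({"c1": "ACGT"})
    hit = _hit("c1", 0, "W_BS", [("M", 4)])
    assert methylation_string(hit, read_seq, genome) == expected


def test_methylation_string_chg_chh_letters():
    genome = ReferenceGenome({"c1": "ACAGTCTTA"})
    hit = _hit("c1", 0, "W_BS", [("M", 9)])
    # pos1 C in CAG -> CHG (X/x); pos5 C in CTT -> CHH (H/h)
    assert methylation_string(hit, "ACAGTCTTA", genome) == ".X...H..."
    assert methylation_string(hit, "ATAGTTTTA", genome) == ".x...h..."


def test_methylation_string_crick_read_reports_crick_cytosines():
    genome = ReferenceGenome({"c1": "AACGTT"})
    # Crick read covering the full genome, fully methylated: native letters
    # are the Crick strand = revcomp("AACGTT") = "AACGTT"
    hit = _hit("c1", 0, "C_BS", [("M", 6)])
    s = methylation_string(hit, "AACGTT", genome)
    # Crick cytosine sits at Watson pos 3 (G); tag orientation column 2
    assert s == "..Z..."


def test_gapped_mode_places_deletion():
    rng = np.random.default_rng(3)
    seq = "".join("ACGT"[i] for i in rng.integers(0, 4, 3000))
    genome = ReferenceGenome({"c1": seq})
    bundle = build_index(genome)
    read = seq[1000:1030] + seq[1032:1102]  # 100 bases, 2 bp deletion
    rec = align_read(Read(id="r", seq=read), bundle, mode="end2end_gapped")
    assert rec.status == "unique"
    assert rec.hit.pos == 1000
    assert ("D", 2) in rec.hit.ops
    assert rec.hit.score == -(5 + 2 * 3)  # open + 2 * extend


def test_gapped_mode_places_insertion():
    rng = np.random.default_rng(4)
    seq = "".join("ACGT"[i] for i in rng.integers(0, 4, 3000))
    genome = ReferenceGenome({"c1": seq})
    bundle = build_index(genome)
    read = seq[500:550] + "A" * 3 + seq[550:597]
    rec = align_read(Read(id="r", seq=read), bundle, mode="end2end_gapped")
    assert rec.status == "unique"
    assert rec.hit.pos == 500
    assert any(op == "I" for op, _ in rec.hit.ops)


def test_local_mode_clips_adapter_tail():
    rng = np.random.default_rng(6)
    seq = "".join("ACGT"[i] for i in rng.integers(0, 4, 3000))
    genome = ReferenceGenome({"c1": seq})
    bundle = build_index(genome)
    read = seq[700:770] + "AGATCGGAAGAGCACACGTCTGAACTCCAG"
    rec = align_read(Read(id="r", seq=read), bundle, mode="local")
    assert rec.status == "unique"
    assert rec.hit.inferred_start == 700
    assert rec.hit.ops[-1][0] == "S"
    assert rec.hit.score >= 2 * 70 - 12  # mostly matched prefix


def test_local_mode_enforces_minimum_score():
    rng = np.random.default_rng(8)
    seq = "".join("ACGT"[i] for i in rng.integers(0, 4, 2000))
    bundle = build_index(ReferenceGenome({"c1": seq}))
    junk = "".join("ACGT"[i] for i in np.random.default_rng(99).integers(0, 4, 100))
    rec = align_read(Read(id="r", seq=junk), bundle, mode="local")
    assert rec.status != "unique" or rec.hit.score >= 100


def test_paired_end_round_trip(genome50k, bundle50k, states50k):
    params = SimParams.error_free(
        genome_length=50_000, n_reads=60, read_length=60, paired=True,
        pe_insert_range=(150, 400), seed=21,
    )
    reads, truths = simulate_reads(genome50k, states50k, params)
    by_id: dict[str, list] = {}
    for r in reads:
        by_id.setdefault(r.id, []).append(r)
    correct = 0
    for rid, (r1, r2) in by_id.items():
        rec1, rec2 = align_pair(r1, r2, bundle50k)
        assert rec1.status == "unique" and rec2.status == "unique"
        t1 = next(t for t, r in zip(truths, reads) if r.id == rid)
        assert rec1.hit.inferred_start == t1.start or rec1.hit.inferred_end == t1.end
        correct += 1
    assert correct == 60


def test_paired_end_rejects_cross_chromosome_mates():
    rng = np.random.default_rng(13)
    s1 = "".join("ACGT"[i] for i in rng.integers(0, 4, 2000))
    s2 = "".join("ACGT"[i] for i in rng.integers(0, 4, 2000))
    genome = ReferenceGenome({"c1": s1, "c2": s2})
    bundle = build_index(genome)
    from trimeth.genome import revcomp

    r1 = Read(id="p", seq=s1[100:160])
    r2 = Read(id="p", seq=revcomp(s2[300:360]))
    rec1, rec2 = align_pair(r1, r2, bundle)
    assert rec1.status == "unmapped" and rec1.reason == "discordant"


def test_paired_end_rejects_excessive_insert(genome50k, bundle50k):
    from trimeth.genome import revcomp

    seq = genome50k["chrSim"]
    r1 = Read(id="p", seq=seq[1000:1060])
    r2 = Read(id="p", seq=revcomp(seq[9000:9060]))
    params = AlignParams(insert_max=1000)
    rec1, rec2 = align_pair(r1, r2, bundle50k, params=params)
    assert rec1.status == "unmapped" and rec1.reason == "discordant"
    wide = AlignParams(insert_max=10_000)
    rec1b, _ = align_pair(r1, r2, bundle50k, params=wide)
    assert rec1b.status == "unique"


def test_alignment_is_deterministic(genome50k, bundle50k, states50k):
    params = SimParams.error_containing(genome_length=50_000, n_reads=50, seed=33)
    reads, _ = simulate_reads(genome50k, states50k, params)
    a = [align_read(r, bundle50k) for r in reads]
    b = [align_read(r, bundle50k) for r in reads]
    assert [(r.status, r.hit and (r.hit.pos, r.hit.tag)) for r in a] == [
        (r.status, r.hit and (r.hit.pos, r.hit.tag)) for r in b
    ]
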