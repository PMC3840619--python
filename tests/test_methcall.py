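import pytest

from trimeth.align import AlignmentHit, AlignmentRecord
from trimeth.genome import ReferenceGenome
from trimeth.methcall import (
    ATCGmapRecord,
    CGmapRecord,
    ConversionFilterParams,
    SiteCounts,
    classify_conversion,
    context_of,
    emit_atcgmap,
    emit_cgmap,
    emit_wig,
    pileup,
    read_atcgmap,
    read_cgmap,
    read_wig,
    write_atcgmap,
    write_cgmap,
    write_wig,
)
from trimeth.reads import Read


def _rec(genome_seq, read_seq, pos, tag, chrom="c1", mate=None, read_id="r"):
    hit = AlignmentHit(
        read_id=read_id, chrom=chrom, pos=pos, tag=tag,
        ops=(("M", len(read_seq)),), score=0, three_letter_mismatches=0,
    )
    from trimeth.align import methylation_string

    genome = ReferenceGenome({chrom: genome_seq})
    meth = methylation_string(hit, read_seq, genome)
    return AlignmentRecord(
        read=Read(id=read_id, seq=read_seq, mate=mate),
        status="unique", hit=hit, bs_mismatches=0, meth_string=meth,
    )


@pytest.mark.parametrize(
    "meth,expected",
    [
        ("XXXXXX" + "h", "dense"),      # u=6 of t=7
        ("X" + "xxxxxx", "sporadic"),   # u=1 of t=7
        ("xxhh..zZ", "clean"),          # u=0
        ("....", "clean"),              # t=0
        ("XXXX" + "hhh", "sporadic"),   # u=4 below the count threshold
        ("XXXXX" + "hhhhhh", "sporadic"),  # u=5 but u/t < 0.5
        ("XXXXX" + "hhhh", "dense"),    # u=5, u/t = 5/9 >= 0.5
    ],
)
def test_classify_conversion_thresholds(meth, expected):
    assert classify_conversion(meth, ConversionFilterParams()) == expected


@pytest.mark.parametrize(
    "seq,pos,strand,expected",
    [
        ("ACGTA", 1, "watson", ("CG", "CG")),
        ("ACAGT", 1, "watson", ("CHG", "CA")),
        ("ACTTA", 1, "watson", ("CHH", "CT")),
        ("ACGTA", 2, "crick", ("CG", "CG")),
        ("TAGCA", 2, "crick", ("CHH", "CT")),  # crick 5'->3': C,T,A
        ("AC", 1, "watson", None),             # runs off the end
        ("ANGTT", 2, "crick", None),           # N neighbor
    ],
)
def test_context_of(seq, pos, strand, expected):
    genome = ReferenceGenome({"c1": seq})
    assert context_of(genome, "c1", pos, strand) == expected


def test_context_of_rejects_non_cytosine():
    genome = ReferenceGenome({"c1": "ACGTA"})
    with pytest.raises(ValueError, match="cytosine"):
        context_of(genome, "c1", 0, "watson")


def test_pileup_single_watson_read():
    rec = _rec("TCGA", "TCGA", 0, "W_BS")
    counts = pileup([rec], ReferenceGenome({"c1": "TCGA"}))
    assert counts.get("c1", 0)[0] == (0, 1, 0, 0)  # T at pos 0
    assert counts.get("c1", 1)[0] == (0, 0, 1, 0)  # retained C
    assert counts.get("c1", 2)[0] == (0, 0, 0, 1)
    assert counts.get("c1", 3)[0] == (1, 0, 0, 0)
    assert counts.get("c1", 1)[1] == (0, 0, 0, 0)  # nothing on crick


def test_pileup_is_additive():
    genome = ReferenceGenome({"c1": "TCGA"})
    rec1 = _rec("TCGA", "TCGA", 0, "W_BS", read_id="a")
    rec2 = _rec("TCGA", "TCGA", 0, "W_BS", read_id="b")
    single = pileup([rec1], genome)
    double = pileup([rec1, rec2], genome)
    for pos in range(4):
        assert double.get("c1", pos)[0] == tuple(
            2 * x for x in single.get("c1", pos)[0]
        )


def test_pileup_filter_excludes_dense_read(genome50k):
    seq = "TCTCTCTCTCTCTCTCTCTCAA"  # many CHH sites
    genome = ReferenceGenome({"c1": seq})
    dense = _rec(seq, seq, 0, "W_BS", read_id="dense")  # all CH retained
    clean = _rec(seq, seq.replace("C", "T"), 0, "W_BS", read_id="clean")
    fp = ConversionFilterParams(enabled=True)
    with_filter = pileup([dense, clean], genome, fp)
    only_clean = pileup([_rec(seq, seq.replace("C", "T"), 0, "W_BS")], genome)
    assert with_filter.n_filtered == 1
    assert dense.status == "filtered"
    for pos in range(len(seq)):
        assert with_filter.get("c1", pos) == only_clean.get("c1", pos)


def test_pileup_counts_crick_reads_in_crick_letters():
    genome = ReferenceGenome({"c1": "AACGTT"})
    # methylated Crick read: native letters = revcomp of the Watson slice
    rec = _rec("AACGTT", "AACGTT", 0, "C_BS")
    counts = pileup([rec], genome)
    # the Crick cytosine at Watson pos 3 is a crick C count
    assert counts.get("c1", 3)[1] == (0, 0, 1, 0)
    assert counts.get("c1", 3)[0] == (0, 0, 0, 0)


def test_pileup_mate_overlap_counted_once():
    genome = ReferenceGenome({"c1": "TTACGTAGCATT"})
    r1 = _rec("TTACGTAGCATT", "TTACGTAG", 0, "W_BS", mate=1, read_id="p")
    # mate 2 on the Crick strand overlapping columns 4..11
    r2 = _rec("TTACGTAGCATT", "AATGCTAC", 4, "C_BS", mate=2, read_id="p")
    counts = pileup([r1, r2], genome)
    total = sum(sum(counts.get("c1", p)[0]) + sum(counts.get("c1", p)[1]) for p in range(12))
    # mate1: 8 columns, mate2 contributes only its non-overlapping 4
    assert total == 12


def test_pileup_rejects_out_of_range_hit():
    genome = ReferenceGenome({"c1": "ACGT"})
    bad = AlignmentRecord(
        read=Read(id="x", seq="ACGTACGT"),
        status="unique",
        hit=AlignmentHit("x", "c1", 2, "W_BS", (("M", 8),), 0, 0),
        bs_mismatches=0,
        meth_string="." * 8,
    )
    with pytest.raises(ValueError, match="corrupt"):
        pileup([bad], genome)


def test_emit_cgmap_level_arithmetic():
    genome = ReferenceGenome({"c1": "ACGT"})
    counts = SiteCounts()
    for _ in range(3):
        counts.add("c1", 1, "watson", "C")
    counts.add("c1", 1, "watson", "T")
    counts.add("c1", 1, "watson", "G")  # sequencing error: not in coverage
    recs = list(emit_cgmap(counts, genome))
    assert len(recs) == 1
    r = recs[0]
    assert (r.nucleotide, r.pos, r.context, r.dinucleotide) == ("C", 2, "CG", "CG")
    assert (r.mc, r.coverage, r.level) == (3, 4, 0.75)


def test_emit_cgmap_skips_uncovered_sites():
    genome = ReferenceGenome({"c1": "ACGT"})
    counts = SiteCounts()
    counts.add("c1", 0, "watson", "A")  # non-cytosine position only
    assert list(emit_cgmap(counts, genome)) == []


def test_emit_cgmap_crick_site_uses_crick_counts():
    genome = ReferenceGenome({"c1": "AACGTT"})
    recs = list(emit_cgmap(pileup([_rec("AACGTT", "AACGTT", 0, "C_BS")], genome), genome))
    crick = [r for r in recs if r.nucleotide == "G"]
    assert len(crick) == 1
    assert (crick[0].pos, crick[0].mc, crick[0].coverage) == (4, 1, 1)


def test_atcgmap_conserves_depth_and_matches_cgmap(genome50k, states50k, bundle50k):
    from trimeth.align import align_read
    from trimeth.simulate import SimParams, simulate_reads

    params = SimParams.error_free(genome_length=50_000, n_reads=150, seed=41)
    reads, _ = simulate_reads(genome50k, states50k, params)
    recs = [align_read(r, bundle50k) for r in reads]
    counts = pileup(recs, genome50k)
    # independent depth: count covered columns per position from the hits
    depth: dict[int, int] = {}
    for rec in recs:
        if rec.status != "unique":
            continue
        for p in range(rec.hit.pos, rec.hit.pos + rec.hit.ref_span):
            depth[p] = depth.get(p, 0) + 1
    at = list(emit_atcgmap(counts, genome50k))
    cg = {(r.chrom, r.pos): r for r in emit_cgmap(counts, genome50k)}
    assert at, "no covered positions"
    for row in at:
        assert sum(row.watson) + sum(row.crick) == depth[row.pos - 1]
        key = (row.chrom, row.pos)
        if key in cg:
            assert row.level == cg[key].level
    # every context-resolved covered cytosine appears in both
    for key, r in cg.items():
        assert r.coverage >= 1


def test_wig_formatting_and_thresholds():
    recs = [
        CGmapRecord("c1", "C", 2, "CG", "CG", 0.75, 3, 4),
        CGmapRecord("c1", "C", 9, "CHH", "CT", 1 / 3, 1, 3),
    ]
    wig = emit_wig(recs)
    assert "variableStep chrom=c1 span=1" in wig
    assert "2 0.7500" in wig
    assert "9 0.3333" in wig
    filtered = emit_wig(recs, min_coverage=4)
    assert "9" not in filtered.split("span=1")[1]
    assert emit_wig([]).strip() == "track type=wiggle_0"


def test_wig_rejects_unsorted_records():
    recs = [
        CGmapRecord("c1", "C", 9, "CG", "CG", 1.0, 1, 1),
        CGmapRecord("c1", "C", 2, "CG", "CG", 1.0, 1, 1),
    ]
    with pytest.raises(ValueError, match="sorted"):
        emit_wig(recs)


def test_cgmap_atcgmap_wig_file_round_trips(tmp_path):
    cg = [
        CGmapRecord("c1", "C", 2, "CG", "CG", 0.75, 3, 4),
        CGmapRecord("c1", "G", 7, "CHG", "CA", 1 / 3, 1, 3),
    ]
    at = [
        ATCGmapRecord("c1", "C", 2, "CG", "CG", (0, 1, 3, 0), (0, 0, 0, 0), 0.75),
        ATCGmapRecord("c1", "T", 5, "--", "--", (0, 2, 0, 0), (1, 0, 0, 0), None),
    ]
    for suffix in ("", ".gz"):
        p1 = tmp_path / f"x.CGmap{suffix}"
        p2 = tmp_path / f"x.ATCGmap{suffix}"
        write_cgmap(cg, p1)
        write_atcgmap(at, p2)
        assert read_cgmap(p1) == cg
        assert read_atcgmap(p2) == at
    wpath = tmp_path / "x.wig"
    write_wig(cg, wpath)
    parsed = read_wig(wpath)
    assert parsed == {"c1": [(2, 0.75), (7, round(1 / 3, 4))]}
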