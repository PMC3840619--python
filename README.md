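# trimeth

A self-contained toolkit for aligning bisulfite sequencing reads and calling
DNA methylation, for people producing base-resolution methylomes from WGBS
(whole-genome) or RRBS (reduced-representation) libraries — including an
exact built-in three-letter aligner, an in-silico restriction digestion /
genome-masking step for RRBS, a conversion-failure read filter, the CGmap /
ATCGmap / WIG / SAM output formats, a bisulfite read simulator with ground
truth, and a mappability/accuracy evaluation harness.

## The problem and the method

Bisulfite treatment converts unmethylated cytosine to uracil (read as T)
while 5-methylcytosine survives, so a read differs from the genome by an
unknown subset of C→T changes (or G→A on the complementary strand of the
converted molecule). `trimeth` searches in the collapsed *three-letter*
alphabet, where those changes are invisible:

* four converted copies of the reference are indexed — Watson and Crick,
  each collapsed C→T and G→A (`W_C2T`, `C_C2T`, `W_G2A`, `C_G2A`);
* the C→T-converted read is searched on the C2T instances and, for
  non-directional libraries, the G→A-converted read on the G2A instances;
* a read is reported only when a **single** placement attains the best
  score (unique best hit); the winner is re-scored on the original letters,
  where read-T/genome-C is a silent conversion but read-C/genome-T is a
  mismatch, and rejected if the bisulfite-aware mismatch count exceeds the
  cap (default 5).

For every uniquely placed read a methylation string records each covered
cytosine as retained (methylated) or converted, stratified by context
(CpG `Z/z`, CHG `X/x`, CHH `H/h`). The pileup turns these into per-cytosine
levels `mC / (mC + uC)`.

RRBS libraries only sequence size-selected restriction fragments (e.g. MspI,
`C'CGG`). `trimeth` digests the genome in silico, keeps fragments in the
selected size window and masks everything else with N — which is never
matchable — so alignment is confined to the library's true origin space.
This removes *pseudo-multiple hits*: reads whose equally good second match
lies in a region the library cannot produce.

Alignment modes: `end2end` (ungapped, pigeonhole-seeded and exhaustive
within the mismatch radius), `end2end_gapped` (affine-gap, full read), and
`local` (Smith–Waterman with soft-clipped ends, which salvages reads with
3' adapter contamination or trailing errors).

## Worked example

Simulate an RRBS experiment on a 100 kb synthetic genome, build the
reduced-representation index, align with built-in adapter trimming, call
methylation, and score against the simulation truth:

```
trimeth simulate --out-dir sim --genome-length 100000 --n-reads 2000 --rrbs --seed 7
trimeth build-index --genome sim/genome.fa --out idx --rrbs --enzyme "C'CGG" --low 40 --high 250
trimeth align --index idx --reads sim/reads.fastq --trim-adapter --out run.sam --include-unmapped
trimeth call-methylation --sam run.sam --index idx --out-prefix run
trimeth evaluate --sam run.sam --truth sim/truth.tsv
```

which prints

```
{"in": 2000, "unique": 2000, "multiple": 0, "unmapped": 0}
8605 cytosines reported (0 reads removed by conversion filter)
reads: 2000  unique: 2000  multiple: 0  unmapped: 0
mappability: 100.00%  accuracy: 100.00%
```

Every simulated error-free read maps uniquely back to its fragment of
origin (mappability = unique/total, accuracy = correct/unique), and 8,605
covered cytosines are reported. The first CGmap rows look like

```
chrSim  C  13  CHH  CA  0.0  0  4
chrSim  C  16  CG   CG  1.0  4  4
```

— tab-separated: chromosome, `C` for a Watson-strand cytosine (`G` for
Crick), 1-based position, context, context dinucleotide, methylation level,
methylated-read count, coverage. Here the CpG at position 16 is methylated
in all 4 covering reads while the CHH at 13 is fully converted. The
companion `run.ATCGmap` carries the full A/T/C/G pileup counts for both
strands at every covered position, and `run.wig` is a genome-browser track
of the levels.

The same functionality is available as a library (`trimeth.align`,
`trimeth.methcall`, `trimeth.simulate`, ...); see `docs/methods.md` for the
model, parameters and design notes.

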