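# Methods

## Three-letter alignment model

Sodium bisulfite deaminates unmethylated cytosine to uracil (sequenced as
T); 5-methylcytosine is protected. A bisulfite read therefore carries an
unknown subset of C→T substitutions relative to its origin — or G→A
substitutions when the strand complementary to the converted molecule is
sequenced, as happens after PCR in non-directional libraries. Searching in
the collapsed three-letter alphabet makes all conversion states of one locus
identical, so the search itself is conversion-blind and the decision about
which changes were conversions is deferred to a recount on original letters.

Four converted reference copies are needed because the two genomic strands
convert independently:

| tag of a hit | instance searched | read conversion | placement | informs |
|---|---|---|---|---|
| `W_BS`    | `W_C2T` (Watson, C→T)          | C→T | forward | Watson cytosines (C/T) |
| `C_BS`    | `C_C2T` (Crick, C→T)           | C→T | reverse | Crick cytosines (C/T) |
| `W_BS_RC` | `W_G2A` (Watson, G→A)          | G→A | forward | Crick cytosines (G/A) |
| `C_BS_RC` | `C_G2A` (Crick, G→A)           | G→A | reverse | Watson cytosines (G/A) |

The `_RC` tags are the reverse complements of the two converted original
strands; directional libraries produce only `W_BS`/`C_BS` and only those two
instances are searched for them. Note that a `W_BS_RC` read is placed
forward on Watson but its methylation information concerns **Crick**
cytosines (it is the faithful complement of a converted Crick molecule);
the pileup assigns counts by this bisulfite-origin strand, stored in that
strand's own letters, which is what makes a methylated cytosine always a C
count regardless of which physical strand was sequenced.

Coordinates are 0-based half-open on Watson throughout; 1-based numbers
appear only in SAM/CGmap/ATCGmap/WIG. Crick-derived instances store the
reverse-complemented text and positions are mapped back to Watson at hit
creation, keeping a single coordinate authority.

`N` is never matchable, in genome or read, under any rule. Ambiguity codes
in reference FASTA are replaced by N on input (with a logged count); this is
a deliberate conservative choice — an ambiguous base should not create a
unique hit.

## Search algorithms and exactness

**end2end (default).** Ungapped. The converted read is split into
`max_mismatches + 1` disjoint segments; any placement within the mismatch
radius must match at least one segment exactly (pigeonhole), so probing a
sorted k-mer table with one seed per segment enumerates *all* placements
with ≤ `max_mismatches` three-letter mismatches. Candidates are verified
with a vectorized Hamming count. Because the recount on original letters
can only add mismatches, placements outside the radius can never become
reportable, so the search is exact for the unique-best decision. Seed
length is the largest of {16, 12, 8, 4, 3, 2, 1} that fits the segment;
k-mers containing N are never indexed, which keeps masked RRBS regions out
of the search space entirely.

**end2end_gapped / local.** Full affine-gap dynamic programming against
every reference position (no seeding, no heuristics): rows run over the
read, columns over the reference, with the horizontal gap state resolved by
an exact running-maximum scan (valid because `gap_open ≥ 0` makes chained
gaps dominated by a single longer gap). Local mode is Smith–Waterman with
soft-clipped read ends. Tracebacks are recomputed in a small window around
each best end column. These modes are O(genome × read) per read and are
intended for desk-scale genomes (the test oracles run them against a plain
textbook DP); end2end is the mode for bulk alignment.

**Scoring.** Simple auditable integers, all configurable: mismatch −6; a
gap of length L costs 5 + 3·L (open −5, extend −3); local mode adds +2 per
match and requires the score to reach `max(20, read_length)` — half of the
best achievable score for reads ≥ 20 bp. Base qualities are not used in
scoring. Reads shorter than 20 bp are not aligned.

**Unique best hit.** Candidate hits from all searched instances are pooled.
If two or more distinct placements (chromosome, position, tag) tie at the
best score the read is *multiple* and discarded from all downstream counts;
within an instance, ties are ordered by lower coordinate then chromosome
name so the reported best/second-best pair is deterministic. The winning
hit is recounted on original letters: read-T over genome-C (C2T tags) and
read-A over genome-G (G2A tags, genome taken in the tag's orientation) are
silent; read-C over genome-T **is** a mismatch (the conversion is
directional); N on either side is a mismatch; indel columns count zero
(they are already paid through the score). Reads with more than
`max_mismatches` (default 5) bisulfite-aware mismatches are rejected.

**Paired ends.** Mate 2 is constrained to the reverse-complement tag of
mate 1's strand, same chromosome, inner (FR) orientation, with the fragment
span inside `insert_min..insert_max` (defaults 0–1000). The pair score is
the sum; unique-best-pair logic mirrors the single-end case. The search
enumerates up to 50 hits per instance per mate, which bounds the pairing
work on pathological repeats.

## Reduced-representation (RRBS) genome

The genome is cut at every occurrence of each enzyme's recognition sequence
(offset at the marked position, e.g. MspI `C'CGG` cuts after the first C);
overlapping occurrences all contribute, and multiple enzymes are a
simultaneous double digestion (union of cut coordinates). Fragments tile
each chromosome exactly. Fragments with length inside the inclusive
size-selection window keep their sequence; all other positions become N in
the masked copy from which the index is built. Cut coordinates are used
directly as fragment boundaries — no end-repair/fill-in chemistry is
modeled. The default index window is 40–220 bp (a typical laboratory size
selection); the simulator's default window is 40–250 bp. Both are plain
parameters: an appropriately broad window is advisable when the laboratory
selection is uncertain. A BED file of selected fragments is written next to
the masked FASTA for audit.

## Adapter trimming

3' adapter removal uses leftmost-match semantics: the earliest read position
where a prefix of the adapter matches the read suffix with overlap ≥ 3 and
mismatch rate ≤ 0.1 truncates the read there. The adapter is matched in
plain four-letter space because it is ligated after conversion. Adapter
tails shorter than the minimum overlap (reads from fragments 1–2 bp short
of the read length) are not trimmable; they survive alignment because the
mismatch budget absorbs them. Reads trimmed below the minimum alignment
length are dropped and counted. The default adapter is the Illumina TruSeq
read-1 sequence `AGATCGGAAGAGCACACGTCTGAACTCCAGTCA`.

## Methylation calling

Unique alignments are piled up per position with A/T/C/G counts split by
bisulfite-origin strand. For each genomic cytosine the level is
`mC / (mC + uC)` with mC = retained-C and uC = converted-T observations on
the cytosine's own strand; other observed bases (sequencing errors) are
excluded from coverage. Contexts are read 5'→3' on the cytosine's strand:
CG, CHG, CHH with H ∈ {A,C,T}; a cytosine whose neighbors run off the
chromosome or touch N has no context — it is omitted from CGmap (whose rows
are context-typed) but still appears with context `--` in ATCGmap.
Overlapping columns of a mate pair are counted once (mate 1 wins) to avoid
double-counting one molecule.

**Conversion-failure filter.** Incomplete conversion inflates apparent
methylation. Reads split into two groups by their unconverted non-CpG
sites: sporadic (occasional failures or T→C errors) and dense (whole
molecules that escaped conversion, e.g. via secondary structure). With
`u` = unconverted CH sites (X/H in the methylation string) and `t` = all CH
observations, a read is *dense* when `u ≥ 5` and `u/t ≥ 0.5` (both
configurable); enabling the filter drops dense reads from the pileup. The
thresholds are intentionally permissive so sporadic reads are retained; the
filter is off by default and is not recommended for samples with genuinely
high non-CpG methylation.

**Formats.** CGmap rows: chrom, nucleotide (C = Watson cytosine, G =
Crick), 1-based position, context, dinucleotide, level, mC, coverage.
ATCGmap rows: chrom, reference nucleotide, position, context, dinucleotide,
four Watson counts (A,T,C,G), four Crick counts (in Crick-strand letters),
level or `na`. Both are tab-separated without header and round-trip through
the provided readers (levels are written at full float precision; WIG uses
4 decimals). SAM output stores reverse-placed reads reverse-complemented
with tags XO (strand tag), XM (methylation string, read orientation), NM
(bisulfite-aware mismatches), XS (dense-unconverted flag), plus ZS/ZM
(three-letter score and mismatches) so records re-parse losslessly.

## Simulator

The synthetic reference is i.i.d. over A/C/G/T with P(G)=P(C)=gc/2 (default
0.5, one chromosome). Every cytosine on both strands is independently
methylated with its context probability; defaults CG 0.7, CHG 0.02,
CHH 0.02 — a mammalian-like methylome with predominantly CpG methylation —
with CG 0.8 / CHG 0.2 / CHH 0.05 used in the level-recovery tests to
exercise all three contexts well away from 0 and 1. Conversion follows the
chemistry: methylated C always retained; unmethylated C converted to T
except with probability `conversion_failure` (default 0.01; the error-free
regime uses 0). WGBS reads take uniform positions on both strands
(directional by default; non-directional adds the reverse complements).
RRBS reads start at the 5' cut ends of size-selected fragments in both
orientations; fragments shorter than the read length sequence into the 3'
adapter, which is appended and truncated to the read length. Sequencing
errors substitute each cycle's base to a uniformly chosen other base at the
cycle's rate; the bundled `ramp_error_profile` rises linearly 0.1% → 1%
across the read as a stand-in for an empirically measured cycle-error
curve, and any per-cycle profile can be supplied. Defaults: 100 bp
single-end (2×60 bp is the paired-end convention in the tests), 10,000
reads, constant base quality. All randomness flows from one integer seed;
identical inputs and seed give byte-identical outputs.

What the simulator deliberately does **not** emulate: indel sequencing
errors, PCR duplicates, quality-score variation, CpG-island composition,
repeats, or SNPs. Passing the round-trip accuracy tests therefore shows the
pipeline is internally correct (every read can be traced to its origin), not
that real-genome mappability will be 100% — real genomes contain repeats
that legitimately produce multiple hits, and real reads contain artifacts
the local mode only partially recovers.

## Evaluation

Mappability = uniquely mapped / all reads; accuracy = correctly mapped /
uniquely mapped. Correct means: same chromosome, same strand tag, and the
5' anchor within `tolerance` (default 0) of the truth. The anchor is the
Watson-leftmost coordinate for forward-placed tags and Watson-rightmost for
reverse-placed tags, with soft-clips folded back in, so local alignments of
contaminated reads and adapter-trimmed reads are judged by the coordinate
that trimming cannot move. Position alone would misjudge a reverse-strand
read whose 3' end lost a base to trimming.

## Scaled-down acceptance protocols

`scripts/acceptance.py` and the acceptance tests run the simulation study at
desk scale: a seeded 1 Mb genome and 10,000 reads per protocol (error-free,
directional, 100 bp; RRBS uses MspI `C'CGG` with 40–250 bp selection), with
alignment end-to-end at ≤ 5 mismatches. On a non-repetitive random genome
every error-free read is uniquely placeable, so the measured accuracy is
100.00% for the RRBS, WGBS and full-pipeline (adapter + trimming) runs; the
property suite additionally checks the pseudo-multiple-hit rescue, oracle
equivalence of the search (brute-force scan at 50 kb, textbook DP at 5 kb),
recovery of the 1% conversion-failure rate and of per-context methylation
levels within binomial error, and format round-trips. Problem sizes were
chosen so each protocol completes in seconds to a couple of minutes on one
CPU.

## Known limitations

* Gapped/local modes are exact but O(genome × read) per read — practical
  for the desk-scale genomes used here, not for mammalian chromosomes.
* The unique-best decision considers placements within the mismatch radius;
  a read whose *every* placement exceeds the radius is reported unmapped
  rather than multiple, which is the standard convention but means
  "multiple" counts depend on `max_mismatches`.
* CGmap omits context-less cytosines (chromosome edges, N neighbors); use
  ATCGmap for a complete pileup.
* Paired-end search caps candidate hits per instance at 50; on extremely
  repetitive toy genomes a concordant pair beyond that horizon would be
  missed (single-end search has no such cap).
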