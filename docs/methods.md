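# Methods

## Scope and design

`circscreen` implements a desk-scale, fully testable rendition of a
screen for translatable circular RNAs: back-splice junction detection
from split reads, RPM quantification, exact differential testing between
single libraries, and circular sORF enumeration, joined by a candidate
funnel (differential in transcriptome *and* translatome → non-coding
host → coding potential). A synthetic-data generator stands in for real
sequencing runs and doubles as the scoring oracle: it plants circRNAs
with known coordinates and per-library expected counts and emits a truth
ledger alongside the FASTQ files.

Coordinates are 0-based half-open everywhere in memory and in BED
output; GTF files are converted at the boundary. A junction is reported
as `(chrom, acceptor, donor, strand)` with `acceptor < donor` in genomic
order and the strand carried separately; on the transcribed strand the
acceptor is always flanked by AG and the donor by GT, which on the `-`
strand maps to genomic `AC…CT` around the circle.

## The simulator

**Genome and annotation.** Per chromosome (default 3 × 35 kb) random
uniform DNA; genes (default 30) are placed left to right with 1–3 exons
of 300–1500 nt, introns of 100–500 nt and intergenic gaps of 200–800 nt.
Biotypes are drawn as 60% protein-coding, 20% lincRNA, 10% antisense,
10% other non-coding; the first gene is forced to be a single-exon
lincRNA so a non-coding host always exists. Random sequence at this
scale is effectively repeat-free at 20-mer resolution, which is the
regime the bespoke seed-and-verify placement engine is built for; the
package makes no claim to aligner performance on real genomes.

**Planted circles.** Each of the default 20 circles occupies part of one
exon of a distinct host gene (300–1000 nt; precondition: at least the
read length). The simulator *writes the splice flanks into the genome*
at the breakpoints, so the flank rule is satisfiable by construction. A
config requesting circles longer than any exon of the sampled host is
rejected with the gene named.

**The translatable cassette.** One circle (1200 nt, in the lincRNA
host) receives a designed, clearly synthetic sequence: random AUG-free
background carrying exactly two planted sORFs — an internal 87-aa ORF
that does not cross the back-splice origin and a 69-aa ORF that wraps
around it — plus an IRES-like interval ending 231 nt upstream of the
internal ORF start (spanning −478..−231, the position a functional IRES
occupies relative to the ORF it drives). ORF bodies are built from a
codon alphabet that cannot create stop codons or spurious AUGs across
codon boundaries; any stray AUG at cassette/background boundaries is
repaired. This cassette is a **synthetic stand-in** for a natural
translatable exon-derived circle: it reproduces the sORF architecture
(sizes, junction relationship, upstream IRES) without being a natural
transcript, and it is what the worked example and the acceptance checks
run on.

**Libraries.** The study layout is two conditions × two fractions
(total RNA and RNC-RNA) plus a circle-free control. Reads are
single-end 100 nt, error-free by default (an optional per-base
substitution rate exists to exercise mismatch tolerance), constant
quality, Phred+33. Translatome libraries are simulated at four-fold
depth (72k vs 18k linear reads), reflecting a deeper translatome
sequencing design, and baseline junction-read means scale accordingly.
rRNA contamination defaults to 5% of the non-junction reads, drawn from
two bundled random rRNA sequences on either strand. Linear reads are
contiguous genomic windows from gene bodies (pre-mRNA-like), so every
linear read maps colinearly and never straddles a back-splice; this
deliberately sidesteps linear splice-junction reads, which the detection
model here does not attempt to handle.

**Counts.** Junction reads per circle per library are drawn
negative-binomially with `variance = mean + φ·mean²`, `φ = BCV² = 1e-4`,
matching the differential model downstream (φ = 0 gives Poisson). Reads
straddle the junction uniformly with at least one anchor length (20 nt)
on each side. Planted roles: the translatable circle changes eight-fold
in both fractions (down in the tumor condition); decoys change in one
fraction only, or in both but from a protein-coding host, or in both
from a non-coding host without IRES evidence; up/down decoys are paired
so library junction totals stay roughly balanced; the remainder are
null. These role means are the study conditions; they are fixed
defaults, not tuning knobs.

Read ids encode the truth class (`lib|junc|circ_007|37|4`), redundantly
with the ledger, so any stage can be scored exactly.

## Detection

Mismatch tolerance `m` defaults to 0 and applies uniformly to rRNA
filtering, linear mapping and breakpoint extension; the index seed
length is `anchor // (m+1)` so pigeonhole seeding stays complete.
"Unique" supporting reads are interpreted as distinct read *sequences*
(robust to PCR duplicates): two reads with identical sequence count
once toward the ≥2-read calling threshold. Anchor uniqueness means
exactly one best-stratum placement genome-wide across both strands.

Breakpoint extension scans splits in ascending order and accepts the
first split satisfying both the sequence match and the flank rule —
i.e. the leftmost acceptor, a deterministic convention for junctions
with repeated sequence. Failures are categorized exhaustively
(non-unique anchor, colinear geometry — which also absorbs anchor pairs
on different chromosomes or strands — no canonical flank, no consistent
extension), and the categories partition the unmapped reads; this
partition is asserted in tests.

For quantification the catalog is the union of per-library candidates;
`C` in each library is the number of junction reads aligned to the
junction there (including libraries where the circle fell below the
calling threshold), and `N` is the column sum over the catalog —
i.e. totals are taken after the ≥2-support filter, making the RPM
identity `Σ RPM = 10^6` exact per library.

## Differential testing

The exact conditional NB test is described in the README. Numerical
notes: pseudo-counts use round-half-to-even; the joint masses are
computed in log space and normalized/summed with compensated (`fsum`)
summation, since two-sided tail sums over many near-equal terms
otherwise accumulate error; outcomes within a relative `1e-12` of the
observed probability are counted as ties so the test is exactly
symmetric. Two zero counts return p = 1 (no evidence). BH adjustment
delegates to statsmodels and is verified in tests against a direct
step-up implementation.

log2 fold-changes are computed on RPM with a pseudo-RPM of 1 so zero
counts stay finite; the DEG rule is |log2FC| ≥ 1 and q ≤ 0.01, both
configurable. Empirically (and asserted in the acceptance suite), 5,000
null pairs at dispersion 1e-4 give a type-I error at p ≤ 0.05 of about
0.04 — mildly conservative, as expected for a discrete conditional test.

## Circular sORFs

Start codons are ATG only; translation uses the standard nuclear code
(via Biopython's table). Each start is walked with wrap-around for at
most three full passes (3L nt — one frame revisit when L is divisible by
3, all three phases otherwise); a frame that never terminates is
emitted once per frame cycle with `rolling=True` and three passes' worth
of residues. By default only the longest ORF per stop codon is reported
(earliest start wins); `all_starts` exposes nested starts. An sORF
spans the junction when `start + 3·(aa_len+1) > L`. The enumeration is
checked exactly against a brute-force scan of the concatenated sequence
on hundreds of random circles, and for rotation invariance.

The default minimum length is 20 aa — deliberately far below 100 aa,
since functional circRNA-encoded peptides shorter than 100 aa are
exactly the cases a conventional ORF-database cutoff would discard.

## The screen

Cross-matching the two contrasts does not require the direction of
change to agree (a `require_concordant` flag enables it). Hostless
(intergenic) circles are dropped and counted. Coding potential is an
operational definition — ≥1 sORF ≥ min_aa, plus IRES evidence *when an
IRES table is supplied* (IRES intervals are user-supplied genomic
intervals, mapped onto circle coordinates; an interval must end within
500 nt upstream of an sORF start, measured circularly). When no IRES
table exists the IRES requirement is waived rather than failing every
candidate. Ranking is deterministic: coding potential, then the smaller
of the two q-values, then support, then id.

## What passing tests do and do not show

The simulator emulates the *structure* of a real screen (split junction
reads, canonical flanks, rRNA contamination, NB counts,
condition/fraction-dependent abundance, decoy funnel paths) but not
sequencing error profiles, linear splice junctions, paired-end
fragments, repeat-rich genomes, rolling-circle cDNA artifacts, or
multi-mapping ambiguity. Detector recall/precision of 100%/0 on these
genomes therefore validates the algorithmic contract — not performance
on full-size mammalian genomes, which this package does not attempt. Problem sizes
(3 × 35 kb genome, 20 circles, ~226k reads, 5,000 calibration pairs,
51×51 closed-form grid) were chosen so the full suite runs in seconds
while keeping every statistical check well-powered.

## Known limitations

- No gapped alignment, adapter trimming, quality modeling, or
  multi-mapped rescue; single-end reads only.
- Exon-spliced circle sequences require a host gene; multi-exon circles
  are supported in sequence assembly but the simulator plants
  single-exon circles only.
- The fixed-BCV exact test is honest only to the extent the fixed
  dispersion is; with replicates a proper dispersion estimate should
  replace it.
- Coding potential is a sequence-level operational call (sORF + IRES
  interval); it is not evidence of translation.
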