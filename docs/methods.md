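# Methods

This note records the models, estimators, parameter choices, and known
limitations behind each stage of the toolkit.

## The synthetic locus

`simdata.generate_ir_genome` builds a single chromosome carrying, left to
right: background sequence; **gene A** on the minus strand; a
**nonpalindromic spacer** (default 50 bp); **gene B** on the plus strand;
background; a **distal paralog C**; an optional **trans-target D**; and
trailing background. Background composition is i.i.d. uniform over ACGT —
no compositional structure is claimed or needed by any stage.

Genes A and B are homologs in head-to-head orientation: each gene's "arm"
(5'UTR 100 bp + first exon 1,500 bp + first intron + part of the second
exon, 3,200 bp in total by default) is the reverse complement of the other's
at `arm_identity` (default 1.0, i.e. a perfect palindrome). With defaults
the IR extent is 2 × 3200 + 50 = 6,450 bp. Gene bodies beyond the arms are
independent random sequence, so the planted IR boundaries are the maximal
palindrome and therefore recoverable; for the same reason the spacer is
drawn so that its outermost bases are not mutually complementary, and the
first bases of the two gene tails differ.

First introns carry a planted tandem repeat (`intron_repeat_period` 80 bp,
within the 75–83 bp band typical of such loci; default 4 copies per gene)
flanked by 20-bp unique sequence. The distal paralog's first exon is gene
A's first exon with exactly `round((1 − identity) × length)` substitutions
(default identity 0.94), whose positions are the **diagnostic SNPs** stored
in the ground truth. The trans-target carries a site perfectly complementary
to a 21-mer taken from gene A's first exon; the planted slicing coordinate
is the target base paired to sRNA position 10.

All coordinates are 0-based half-open internally. Start-codon-relative
positions skip zero: −1 abuts +1, and +1 is the A of ATG.

### Randomness

One top-level seed; each sub-simulation (genome, sRNA, WGBS, RACE, panel)
derives an independent child stream keyed by a fixed index, so adding one
simulation never perturbs another, and a fixed seed gives byte-identical
outputs.

### Small-RNA library

Reads are error-free genomic substrings (the analysis aligns at 0
mismatches, so sequencing errors would only shrink the library). Sizes are
drawn from `srna_size_weights` (default 21-nt-dominated: 0.10 / 0.60 / 0.15
/ 0.05 / 0.10 over 20–24 nt). IR-derived reads start uniformly on both
strands of the two arms; spacer positions emit at the arm rate divided by
`loop_depletion` (default 10). The IR read count is Poisson with mean
`dosage × library_size × ir_fraction_per_allele` (default 0.5), so the
library reaches its nominal size (default 10⁵) at dosage 2 and halves at
dosage 1. Background is an explicit `background_fraction` of the library
and **defaults to 0**: on a ~16-kb synthetic chromosome any appreciable
uniform background blankets the locus, which would contradict the intended
study conditions (a locus-focused library in which a dosage-0 genotype
yields zero locus reads). Tests that need background noise switch it on
explicitly.

### Bisulfite library

Directional protocol only (original-top / original-bottom). Each cytosine
on the sequenced strand is read as C with probability
`p + (1 − p)(1 − conversion_rate)` and as T (G/A on the bottom strand)
otherwise, where `p` is the planted per-(region, context) methylation
probability. Defaults emulate an RdDM-marked IR (arm/spacer CG 0.60, CHG
0.30, CHH 0.30) over a quiet background (CG 0.10, non-CG 0.02);
`conversion_rate` defaults to 0.995, so a fully unmethylated site reads
~0.5% apparent methylation. Coverage defaults to 50×, read length 80 bp.

### 5'RACE library

Tags are a fixed 5' adapter plus a genomic suffix starting at a planted TSS
(start-codon-relative, jittered by a rounded normal with
`tss_jitter_sd` = 3 bp) or exactly at the planted slicing coordinate
(`race_cleavage_fraction`, default 0.2 of 1,000 tags). Defaults plant a
single TSS at −45, inside the windows such experiments typically report.

### Accession panel

Each accession applies an independent random subset (each edit with
probability 0.5) of: an intergenic deletion (2,700 bp), an arm-internal
inversion (1,000 bp inside gene B's first exon), an intron tandem-repeat
copy-number change (4 → 7), and a TE-fragment insertion (400 bp in the
intergenic region). Panels are generated from a long-spacer base
configuration (2,800 bp) so the deletion mirrors the ancestral-to-derived
shortening of the intergenic region. All accessions share the base
sequence, so they differ only by the planted edits; truth records
first-intron lengths and a class label per accession.

## Structural scanning

**Pairwise identity** uses Biopython's `PairwiseAligner` in global mode
with match +1 / mismatch −2 / gap open −4 / gap extend −1 (the first gap
column costs the open score). The printed identity of near-identical gene
pairs depends on the aligner and its parameters, so these are exposed in
every entry point; identity is identical columns over **all** columns,
gap columns included (stated explicitly because conventions differ).

**IR detection** compares a region against its own reverse complement:
12-mer seed matches are grouped by diagonal (`i − j` against the reverse
complement, which is constant along an inverted-repeat arm pair), merged
along runs with gaps ≤ 3 seeds, and the best non-self-overlapping pair
meeting `min_arm` / `min_identity` wins. Self-overlapping pairs are the
masked trivial self-complementarity. This is a sequence-level palindromy
test by design — the evidence for such loci is palindromy, not folding
thermodynamics, so no ΔG model is involved. Orientation (head-to-head vs
tail-to-tail) comes from annotated gene 5' ends facing inward vs outward
when a GFF3 is supplied.

**Structural comparison** anchors two loci on shared k-mers unique in both
(k = 31 by default; uniqueness avoids repeat-induced spurious chains in
this repeat-rich locus type), chains them by longest increasing
subsequence, and classifies inter-anchor gap differences ≥ 30 bp as
insertions/deletions. Inversions are reported two ways: (a) anchors whose
reverse complement is unique in the other sequence, restricted to regions
the forward chain leaves unexplained — the restriction matters because an
IR-containing locus would otherwise "invert" onto itself; and (b) a
fallback for blocks inverted inside one arm of a palindrome (which
duplicates the other arm's sequence and defeats k-mer uniqueness): a
forward-chain gap of similar size on both sequences whose contents share a
long exact block under reverse complement. Inversion intervals are
anchor-bounded uncertainty intervals, not point breakpoints — near-perfect
homology makes exact breakpoints undefinable in this locus class.

**Tandem repeats** are found by self-comparison at each candidate lag p:
the best contiguous segment with ≥ 80% lag-p agreement (maximum subarray of
agreement − 0.8) is scored, the period maximizing matched length wins, and
copy number = (matched length + p)/p. Requires ≥ 2 copies at ≥ 80%
consensus identity.

## Small-RNA processing

Because the alignment policy is 0 mismatches, a seed-and-verify exact
substring index over the genome is exactly equivalent to a short-read
aligner run at 0 mismatches, and keeps the artifact self-contained. All
placements on both strands are kept up to `max_hits` (default 1,000; reads
over the cap are discarded and counted). Multimapping reads are weighted
1/n for quantification; the disambiguation step instead retains all
placements, since read retrieval must not lose multimappers.

Clusters are weighted-coverage islands merged across gaps ≤ 75 bp and
filtered at ≥ 10 weighted reads; both parameters are conventions, not
measured values, and are exposed in the interface. Note that an IR locus
with a 50-bp spacer always yields **one** IR-spanning cluster under a 75-bp
merge gap. CP10M normalizes weighted counts by aligned reads; TP10M
normalizes distinct tags by distinct aligned tags (whether "tags" should be
abundance-weighted is genuinely ambiguous; both numerators are available,
distinct tags being the default).

The arm/loop enrichment ratio is mean weighted coverage over the arms
divided by mean over the spacer, with the spacer mean taken after trimming
one maximal read length (24 bp) from its upstream edge — reads starting in
the last ~20 bp of the upstream arm unavoidably bleed coverage into a 50-bp
spacer and would bias the ratio several-fold. A spacer with no coverage is
floored at one read-equivalent and flagged.

Dosage response is summarized by a least-squares slope through the origin
(abundance at dosage 0 is structurally zero) plus a monotonicity flag.

Phasing scores use the definition standard among small-RNA cluster
callers: sliding 9-cycle (189-nt)
windows stepped by one cycle, registers = 5'-end position mod 21 with
antisense 5' ends shifted so that the two strands of one 2-nt-overhang
duplex share a register, and
`score = (k − 2) · ln(1 + 10·P/(P+U))` for k ≥ 3, else 0. The score
threshold conventionally applied to call a locus "phased" is configurable
(default 10); the uniformly processive but unphased libraries the generator
emits score well below it, as expected for hairpin substrates diced by
multiple enzymes.

## 5'RACE processing

Reads must carry the 5' adapter as a prefix (≤ 1 mismatch), which is then
trimmed; inserts < 20 nt are dropped. Trimmed tags are matched exactly
(forward strand only, mirroring the strand-specific primer design) against
per-gene windows of first exon + 500 bp upstream; antisense transcription
is assayed by emitting each window's reverse complement as its own target.
A tag matching several windows — unavoidable between identical paralog
first exons — is assigned to all with an ambiguity flag, and tag counts are
conserved (assigned + ambiguous + unmatched = input).

TSS windows are an operationalization of what such studies draw as boxes:
the maximal run of occupied positions (gaps ≤ 2) with counts ≥ 25% of the
modal count, ranked by contained-tag fraction. Both parameters are exposed;
no claim is made that published figures used this exact rule.

Cleavage matching slides each 20–24-nt candidate sRNA's reverse complement
along the target transcript (≤ 3 mismatches, no gaps) and predicts the
slice at the target base paired to sRNA position 10 — the canonical cut
between positions 10 and 11. A match requires a tag 5' end exactly at the
predicted coordinate (offset tolerance 0 by default, configurable ±1, since
published evidence for any allowed offset is graphical only).

## Bisulfite analysis

Contexts are assigned from the reference alone: CG, then CHG, then CHH by
the two downstream bases on the cytosine's own strand; cytosines within
2 bp of a sequence end are excluded. Alignment collapses C→T (top) and G→A
(bottom) on both read and genome and keeps uniquely placed reads only — on
a perfect palindrome this discards arm-interior reads (each matches both
arms), so arm levels are estimated from reads overlapping arm boundaries;
the estimate stays unbiased, only coverage drops. Methylation levels are
weighted (read-pooled) — Σmethylated/Σtotal — which is invariant under
window splitting and re-pooling; per-site averaging is available but not
default. Windows with no covered cytosine are reported as missing, never
as 0.

Comparisons across structurally different alleles always go through an
explicit `CoordinateMap` built by removing the structurally variable
interval, never through raw coordinates. Hyper/hypo calls require both
windows covered and |difference| ≥ 0.1 — a reporting margin, not a
significance test; replicate-based DMR statistics are out of scope.

## Pipeline and problem sizes

`pipeline.run_all` runs, per seed: genome simulation; IR detection; three
dosage libraries (10⁵ reads each) with alignment, clustering, profiling and
dosage regression; a 20,000-read single-exon library for disambiguation;
1,000 RACE tags with TSS and cleavage calling; two 50× bisulfite libraries
(IR-methylated vs low-RdDM profile) with windowed comparison at 200-bp
windows; a coordinate-synchronization demonstration on a long-spacer
allele; and a 6-accession panel with recovery of intron lengths and
structural classes. These sizes keep a full run around ten seconds on one
CPU while leaving every sampling-based check far from its tolerance
boundary. The recovery table marks each stage PASS/FAIL at the tolerances
stated in its row.

## What the synthetic data does and does not show

The generator reproduces the statistical structure the analysis assumes:
palindrome geometry, dosage-proportional sRNA emission, loop depletion,
size composition, diagnostic-SNP-bearing paralogy, context-specific
methylation with incomplete conversion, jittered TSSs, an exact slicing
site, and panel-scale structural variation. It deliberately omits
sequencing errors, adapter read-through, PCR duplicates, paired-end reads,
non-uniform coverage biases, chromatin signal, and genome-scale background
transcription. Passing tests therefore demonstrate the correctness of the
estimators and coordinate arithmetic under the stated model — not
robustness to the noise sources of real libraries. Printed values from real
assemblies (gene-pair identities, spacer lengths, read-partition
percentages) can be checked through `irsirna validate` on user-downloaded
data, which is never fetched automatically.
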