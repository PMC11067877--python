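# Methods

## Coordinate and data conventions

All genomic coordinates are 0-based half-open internally (BED
convention). GTF and CIRI2-format tables, both 1-based inclusive on
disk, are converted at the I/O boundary and nowhere else. Intron
ordinals are 1-based and follow transcript orientation: on a minus-
strand transcript the genomically last gap is intron 1. Strand "." is
treated as "+" for sequence extraction; all retention metrics are
strand-symmetric, so only ordinal numbering depends on strand.

Multi-mapped reads are excluded from retention metrics through a
mapping-quality floor (default ≥ 1, i.e. MAPQ-0 records dropped):
intronic sequence is repeat-rich and multi-mappers would inflate
coverage. Duplicate reads are not removed. Both choices are
configurable (`DetectConfig.min_mapq`, upstream deduplication being the
caller's responsibility).

## Host assignment

The boundary score counts exact coordinate matches between the BSJ span
and annotated exon boundaries (0/1/2). Matching is exact with no
tolerance: BSJ calls are splice-site anchored, and fuzziness would
manufacture false exon matches. When several transcripts tie at the
maximal score, **all** are kept as hosts and their internal introns are
unioned (deduplicated by coordinates); a single-winner rule would
silently drop candidate introns. An intersection mode is available
(`assign_hosts(..., union_introns=False)`). Host transcripts must match
the call's strand when the call is stranded; unstranded calls match
either strand.

## Circular pseudo-references and pair placement

A circle spanning genomic `[start, end)` is linearized as that span
plus its first `readlen − 1` bases appended again. The pad length
`readlen − 1` is the minimum that lets any single read cross the BSJ
exactly once; every pad position projects back to `start + (pos − L)`
where `L = end − start`, so back-projection is single-valued everywhere
and injective on the circle body. Spans shorter than 20 nt are refused
as un-alignable.

The pseudo-reference is the *genomic* sequence of the span — introns
included — because intron retention is exactly what is being tested:
reads carrying intronic sequence must be able to align inside introns.
The flip side is that reads from spliced regions that cross an
exon–exon junction cannot align contiguously; the built-in placement
therefore soft-clips. Placement is exact-k-mer seeding (k = 20, seeds
at k-spaced offsets) followed by ungapped X-drop extension (match +1,
mismatch −3, drop 8): the aligned part must reach 30 bases with at most
5% mismatches, and a read whose best score is achieved at two distinct
positions is discarded as ambiguous. The placement is ungapped by
design — indel-bearing data can instead supply an external SAM aligned
to the pseudo-references. Mates of a pair must place in opposite
orientations; left/right order is not enforced because it is
rotationally ambiguous on a circle.

Classification works on **aligned** bases only (soft-clips ignored): a
pair is `intronic` if some mate's projected bases fall entirely inside
one candidate intron, `exon_intron_junction` if some mate's aligned
block crosses an intron boundary with at least the overhang (default
5 nt) on both sides, `exonic_only` otherwise. The intron-evidence rule
is pair-level: a mate with intronic sequence qualifies because its
fragment contains the BSJ, whether or not that same mate crosses the
junction. (`crosses_bsj` is still recorded per pair for stricter
downstream filtering.) A candidate needs `min_support` (default 1) such
pairs — permissive on purpose, because step 3 does the real validation.

## Retention metrics and validation

For one intron and the library's genome alignments:

* **#EE** — reads with an N gap equal to the intron *exactly* (both
  boundaries), with ≥ 5 aligned bases flanking both gap ends. Near-miss
  gaps indicate different splice sites and are ignored. A read counted
  as EE for an intron is excluded from that intron's EI/IE.
* **#EI / #IE** — reads with a contiguous aligned block crossing the
  intron start (resp. end) with ≥ 5 bases on each side. A read spanning
  the whole intron contributes to both boundaries, once each.
* **#I** — reads with ≥ 1 aligned base in the intron's middle window
  (the centered 200 nt, offset `⌊(len − 200)/2⌋`, or the whole intron
  when shorter) whose every block overlapping the intron lies inside it.
* **#IC** — fraction of intron positions under ≥ 1 aligned block
  (N gaps do not cover). Deletions (D) count as covering; splices (N)
  split blocks.

Metrics use **all** primary alignments above the MAPQ floor, not only
BSJ reads: BSJ fragments are short and cannot tile a whole intron, so
linear-read coverage legitimately contributes to #IC and #EE.

Validation requires `#EE ≥ 1 ∧ #EI ≥ 1 ∧ #IE ≥ 1 ∧ #I ≥ 1 ∧ #IC ≥ 0.9`
(all thresholds configurable, boundaries inclusive). Percent intron
retention is the junction-based ratio

    PIR = m / (m + #EE),   m = (#EI + #IE) / 2,

defined as 0 when all three counts are zero. The same ratio computed on
a poly(A)-plus (linear) library serves as the IRratio for linear intron
retention; the two contexts differ by source library, not by formula.
Class labels: **CIR** = validated in the circRNA context with
PIR ≥ 0.1; **NCI** = internal to an EcircRNA with circ-context
PIR ≤ 0.02; **LIR** = linear-context IRratio ≥ 0.1. An intron meeting
several definitions carries all its labels; overlaps are reported, not
resolved.

A record's BSJ count is the number of distinct BSJ pairs that provided
qualifying intron evidence (the step-2 count), not the caller's raw
junction-read count. BRPM divides this by total mapped reads of the
library × 10⁻⁶ — per-million-*mapped* is the standard depth
normalization and the denominator is recorded in the run report.
Detection deliberately reports single introns validated independently;
multi-intron EIciRNAs appear as records listing several validated
introns but are not jointly modeled.

## tau

`τ = Σᵢ (1 − xᵢ/x_max) / (n − 1)` over a per-tissue vector (n ≥ 2);
0 for uniform, 1 for single-tissue expression. Replicates are averaged
(arithmetic mean) per tissue first; values are log2(x + 1)-transformed
by default before the formula — common practice for expression-based
tau — and the transform is switchable and recorded in output headers.
All-zero vectors are flagged undefined rather than given a value.

## Intron features and the class network

Nine features are computable from genome + annotation alone: log10
intron length, intron GC, relative position (ordinal / intron count),
donor and acceptor splice-site strengths, log10 length and GC of the
transcript-orientation upstream and downstream exons. Splice-site
strength is the log2-odds score (vs uniform background) under position
weight matrices estimated from the catalog's own annotated introns with
pseudocount 1 — donor window 3 exonic + 6 intronic nt, acceptor window
20 intronic + 3 exonic nt. A catalog-trained PWM keeps the scorer
self-contained; any external scorer (e.g. maximum-entropy models) can
be substituted since features enter the classifier as plain columns,
and user-supplied extra columns (conservation, structure, motifs,
nucleosome positioning) are accepted untouched.

The classifier is a feed-forward network with three hidden layers
(64/32/16, ReLU, softmax output, Adam, max 400 epochs, fixed seed ⇒
bit-identical weights), on features standardized with training-split
statistics only. Splits are stratified 70/15/15. Class imbalance is
handled by deterministic inverse-frequency oversampling of the training
split to balance — equivalent in expectation to inverse-frequency loss
weights, which the underlying optimizer does not take per-sample.
Evaluation is pairwise one-vs-one on the held-out test split: AUROC and
AUPRC from the softmax score of the second-named (positive) class, and
permutation importance as the mean AUROC drop over 20 shuffles of one
feature column, signed by the point-biserial correlation between
feature and class indicator. Pairs with fewer than 2 test examples of
either class are reported as undefined. Architecture, sizes, epochs and
split fractions are all arguments with these recorded defaults.

## Synthetic data: what it emulates, what it does not

The simulator draws paired-end fragments (Gaussian length, default
300 ± 30 nt, truncated to [read length, template length]; default reads
2 × 150 nt) from three template kinds: spliced mRNA (`linear`),
circularized spliced exons (`ecirc`) and circularized exons plus one
retained intron (`eici`). Fragment starts on circles are uniform and
may wrap the BSJ; fragment count per template is
`⌈depth·L/(2·readlen)⌉`. Substitution errors are uniform (default
0.5%); quality strings are constant Phred 30. Toy genomes are uniform-
random sequence with planted canonical GT…AG dinucleotides at intron
boundaries. Defaults follow the library design the detector targets —
fragments above 250 nt and reads of 150 nt, the regime where BSJ
fragments reach past the junction into an adjacent intron.

Alongside FASTQ the simulator emits genome SAM records that are
splice-aware by construction (spliced-out introns become N operations).
A read whose fragment wraps the BSJ has no linear representation; its
longest genomically colinear run is aligned and the remainder
soft-clipped, as a splice-aware linear aligner would do. This SAM is
the primary test path, so the whole pipeline runs hermetically without
an external aligner.

The standard test scenario is three 5-exon genes (exons 120–180 nt,
introns 280–400 nt): gene1 hosts the EIciRNA — the whole transcript
circularized with intron 1 retained, placing the intron adjacent to the
BSJ where ~300 nt fragments can reach it — and is also expressed
linearly (the source of #EE evidence); gene2 hosts an intron-free
EcircRNA; gene3 is linear background. Depths default to 50× circles /
30× linears.

Not emulated: empirical error and quality profiles, indels, coverage
biases, rolling-circle or long reads, multi-mapping ambiguity, and
real splice-site sequence composition beyond the planted GT/AG. Passing
tests therefore demonstrate the pipeline's logic (coordinate handling,
classification rules, threshold behavior, determinism), not its
robustness to alignment artifacts in real libraries — for real data the
external-SAM path with a production aligner is the intended route. The
synthetic feature sets for the classifier are class-conditional
Gaussians whose mean shifts follow the observed directions of effect
between intron classes (retained classes shorter, higher-GC, weaker
splice sites than NCI; CIR longer, lower-GC and more 5′ than LIR); they
validate the learning and evaluation machinery, not biological feature
distributions.

## Numerical and design notes

* Problem sizes in tests and the acceptance script (20 replicate
  simulations, ≤ 200-read oracle fixtures, 600/class feature sets) keep
  the whole suite in the tens of seconds while leaving every check
  well-powered; they are the package's chosen defaults, not limits of
  the method.
* Ambiguous placements are dropped, never guessed; they are counted in
  the per-circle diagnostics table.
* Ties in host scoring keep all transcripts (see above); ties in
  placement quality discard the pair.
* `gzip` output is written with a fixed zero mtime so identical seeds
  give byte-identical files.
* The external aligner steps around the package (BWA-MEM/CIRI2 for BSJ
  calling, a splice-aware aligner for the genome BAM) are interface
  boundaries: the package consumes their outputs and never shells out,
  which keeps runs hermetic and reproducible.
* Known limitations: no GFF3 input; no indel handling in the built-in
  placer; single-intron validation only (no joint multi-intron model);
  PIR is a junction-read ratio and inherits its small-count noise — at
  #EE + mean(#EI,#IE) below ~10 the ratio is better read as a flag than
  a quantity.
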