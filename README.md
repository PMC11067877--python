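# eicirna

Detection, validation and quantification of **exon–intron circular RNAs
(EIciRNAs)** from paired-end RNA-seq.

EIciRNAs are back-spliced circular RNAs that retain one or more introns
between their circularized exons. Generic circRNA callers report the
back-splice junction (BSJ) but not whether the internal introns are
retained, so EIciRNAs are usually lumped together with purely exonic
circRNAs (EcircRNAs). This package separates them: starting from BSJ
calls (a CIRI2-format table), it decides — read by read — which circles
carry retained-intron evidence and validates that evidence against the
whole library.

## Method

Detection runs in three steps:

1. **Host assignment.** Each exon-type circRNA call is scored against
   every overlapping transcript: score 2 if both BSJ coordinates
   coincide with annotated exon boundaries, 1 if one does, 0 otherwise.
   All transcripts at the maximal score become hosts, and their introns
   inside the circle span are the candidate retained introns.
2. **BSJ pair evidence.** The circle's genomic span is linearized with a
   *rotation pad* (its first `readlen − 1` bases appended again), so any
   read from the circle aligns contiguously no matter where the BSJ falls
   inside it. The BSJ-supporting read pairs named by the caller are
   placed on this pseudo-reference (exact k-mer seeding + ungapped
   X-drop extension with soft-clipping, or an external SAM), projected
   back to genomic coordinates, and classified: a pair supports an
   intron if a mate maps entirely inside it, or crosses an exon–intron
   boundary with ≥ 5 aligned bases on both sides.
3. **Retention validation.** For each candidate intron, genome
   alignments of the whole library yield five metrics: spliced
   exon–exon reads whose gap matches the intron exactly (#EE),
   unspliced reads crossing the exon→intron (#EI) and intron→exon (#IE)
   boundaries (5-nt overhang throughout), reads confined to the
   intron's middle 200 nt (#I), and the fraction of intron positions
   covered (#IC). An intron is retained when
   `#EE ≥ 1, #EI ≥ 1, #IE ≥ 1, #I ≥ 1, #IC ≥ 0.9`.

Validated circles are reported with percent intron retention
`PIR = mean(#EI, #IE) / (mean(#EI, #IE) + #EE)` and quantified as
**BRPM** (back-spliced reads per million mapped reads), where the count
is the number of BSJ pairs that provided qualifying intron evidence.

Around the detector the package ships:

* a paired-end **read simulator** (linear, EcircRNA and EIciRNA
  templates, wrap-around fragments on circles, FASTQ/SAM/truth-table
  output) used for all testing;
* intron class labels — **CIR** (retained in a circRNA, PIR ≥ 0.1),
  **NCI** (internal to an EcircRNA but spliced out, PIR ≤ 0.02) and
  **LIR** (retained in the linear transcript, IRratio ≥ 0.1) — plus a
  three-hidden-layer neural network that distinguishes the classes from
  sequence-computable intron features (length, GC, splice-site PWM
  strength, position, flanking-exon features), evaluated by pairwise
  AUROC/AUPRC and permutation importance;
* the **tau** tissue-specificity index
  `τ = Σᵢ (1 − xᵢ/x_max) / (n − 1)` over per-tissue expression.

## Worked example

Simulate the standard toy bundle (three 5-exon genes; one EIciRNA
retaining intron 1 of gene1, one EcircRNA on gene2, linear expression of
gene1 and gene3; 2 × 150 nt reads, 300 ± 30 nt fragments, 50× depth),
then run detection on it:

```bash
eicirna simulate --outdir sim --seed 7
# simulated 449 fragments into sim
eicirna detect --genome sim/genome.fa --gtf sim/annotation.gtf \
    --circ sim/truth_circ.tsv --alignments sim/alignments.sam \
    --fastq1 sim/reads_1.fastq.gz --fastq2 sim/reads_2.fastq.gz \
    --outdir det
# detected 1 EIciRNA(s); reports in det
```

`det/eicirna.tsv` then contains exactly the planted EIciRNA:

```
chrom  start  end   circ_id  strand  host_transcripts  intron_start  intron_end  EE  EI  IE  I   IC      PIR     bsj_count  brpm
chrT   500    2610  eici1    +       gene1.t1          650           950         28  48  49  53  1.0000  0.6340  20         22271.7149
```

Reading the row: the circle spans chrT:500–2610 on gene1's transcript;
its intron at 650–950 is fully covered (IC = 1.0), has 48/49 reads
crossing its two boundaries and 28 spliced reads skipping it — so both
the retained (circular) and the spliced (linear gene1) isoforms are
visible, giving PIR = 0.63. Twenty BSJ pairs carried intronic evidence
(bsj_count), which at this tiny library depth works out to a BRPM of
~22,272. The EcircRNA receives no record: its BSJ pairs are all exonic
(`det/pair_diagnostics.tsv` shows 40 exonic-only, 0 intronic).

The other subcommands: `eicirna classify` trains and evaluates the
intron-class network (on a supplied feature table or a synthetic one)
and `eicirna tau --matrix expr.tsv --out tau.tsv` computes tissue
specificity from an expression matrix.

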