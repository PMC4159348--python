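# Methods

This note documents the models, conventions and numerical choices behind
sdrnakit, and what the synthetic-data tests do and do not demonstrate
about real data.

## Coordinate model

All genomic coordinates are 0-based half-open (BED convention); GFF3 input
(1-based inclusive) is converted on read and back on write.  snoRNA
sub-annotations (boxes, guides) and all sdRNA end logic use
*mature-relative* coordinates: nucleotides from the 5′ end of the mature
transcript in transcript orientation.  For a mature interval
[m₀, m₁) on the − strand, a genomic read interval [s, e) maps to
[m₁−e, m₁−s); this makes every downstream rule strand-independent, which
the strand-symmetry property test verifies directly.

## Read ingest and the unique-position filter

A logical read is one read_id with one retained placement and a
multiplicity `n_hits`.  Multiplicity precedence is: explicit NH-style tag >
repeated read_id placements > 1; BED6 carries no tag, so repeated
placements are the only multi-mapping signal there.  The unique-position
filter retains exactly the reads with `n_hits == 1`; it is idempotent and
conserving (kept + dropped = input), both asserted as properties.  SAM
minus-strand records are reverse-complemented so that `seq` is always the
read's own sense (sdRNAs are same-sense fragments of their snoRNA).  Reads
outside the 10–40 nt size-selection window are kept with a warning, since
the gel cut is approximate.

## Assignment and summary conventions

A read is assignable to a feature iff same contig, same strand, and at
least `min_overlap_frac` (default 0.8) of the read length overlaps the
feature; largest overlap wins and exact ties are counted separately as
ambiguous.  No overlap rule is canonical for 19–26 nt fragments; 0.8
tolerates 1–4 nt terminal overhangs without letting reads bleed across
neighbouring loci, and the parameter is exposed.  Reads on the rDNA contig
(modelled as an extra contig, so one ingest path serves both references)
are classified rRNA with the best-overlapping segment recorded.

The alignment summary mirrors the conventional presentation of such
tables: %Aligned and %Aligned-sRNA are relative to *raw* reads while %rRNA
is relative to *aligned* reads.  The inconsistency is deliberate — it is
what the summary reproduces — and `uniform_denominator=True` switches
everything to raw reads.  The biotype breakdown is relative to aligned
sRNA reads and mirrors the mixed printed precision of its source layout
(miRNA at 1 decimal, others at 2).  Rounding everywhere is half-away-from-
zero at the reported precision, which is what reproduces the printed
values from the integer counts (e.g. 28,865/31,061 → 92.93).

Size-histogram "modes" are all lengths whose count reaches 50% of the peak
count: this reports both peaks of a genuinely bimodal spectrum (19/25 nt)
while ignoring minor secondary biotypes, and degrades gracefully to a
single mode for unimodal libraries.

## sdRNA characterization

**End of origin.**  The read midpoint is compared with the mature-
transcript midpoint.  The midpoint rule is parameter-free and symmetric
under strand reflection; reads spanning the whole mature transcript are
AMBIGUOUS, and reads entirely outside it are flanking fragments, counted
but not called.  An alternative `edge:k` rule (read start within k nt of a
terminus) is available for sensitivity analysis.

**Box scanning.**  Every full window of the read is tested by Hamming
distance against the box C core consensus `TGATGA` with ≤1 mismatch and
the box D consensus `CTGA` with 0 mismatches; `N` counts as a mismatch;
windows spanning read ends are not considered (a partial motif is not
evidence of retention).  C/C′ and D/D′ are not distinguished during
scanning — both families match one consensus — matching the pooled
reporting convention; an extra per-hit label marks whether a hit coincides
with an annotated box interval.  The scanner is validated against an
independent brute-force oracle on thousands of random sequences.

**Guide retention** is full containment of at least one annotated guide
interval; partial overlap does not count, because a truncated guide cannot
base-pair its full substrate span.

**Aggregation.**  The locus table aggregates calls per (locus,
compartment); `five_prime_fraction` uses the total read count as
denominator (ambiguous calls dilute both ends).  The locus filter default
is ≥10 reads — threshold statements of "ten or more" vs "more than ten"
both circulate for this kind of filter; ≥10 is the documented default and
`min_reads` changes it.  Pearson correlation defaults to the
`union_detected` scope (any locus with ≥1 read in either compartment,
missing counts zero-filled) since raw scatter plots show all detected
loci; `filter_first` restricts to loci at ≥`min_reads` first.  A constant
count vector raises instead of returning r = 0: an undefined statistic
should be loud.

## Synthetic data

The generator emulates the *structure* of a subcellular small RNA-seq
experiment, not its platform chemistry:

* a toy genome with 24 snoRNA loci (mature 61–100 nt, box C at
  mature-relative [5,11), C′ and D′ internal, D at [L−8,L−4), one 12 nt
  guide adjacent to D, alternating strands), 24 miRNA loci (23–25 nt),
  snRNA/misc loci, and a 2 kb rDNA contig with 5′ETS/18S segments;
* reads drawn compartment → biotype → locus → end (Bernoulli p5, fragment
  anchored at the mature 5′ or 3′ terminus) → length mixture (resampled if
  longer than the mature transcript, logged) → i.i.d. substitution errors
  at rate ε → optional second decoy placement (multi-mapped fraction);
* alignments are emitted by the simulator as the truth placements rather
  than produced by an aligner, keeping the package download-free and
  deterministic end to end (byte-identical FASTQ/BED/truth under a fixed
  seed, asserted).

Background sequence is i.i.d. uniform over ACGT, so spurious motif hits
are quantifiable (per-window box C hit probability 19/4⁶ ≈ 0.0046).  The
truth table therefore records box flags twice: `boxes_planted` (annotated
box interval inside the read, by construction) and `boxes_detected` (an
independent vectorized Hamming scan of the emitted sequence).  At ε = 0
the classifier must agree with `boxes_detected` on 100% of sdRNA reads —
asserted — while `boxes_planted` provides the lower bound for motif
recovery and the basis of the error-rate bound: a planted C survives one
error (tolerance 1), so C misses require ≥2 errors in its 6-mer window,
and any error in the 4-mer kills a D; observed miss rates are asserted
below twice those probabilities.

The `paper-like` preset encodes the study conditions: nucleolar biotype
mixture (snoRNA 0.93, miRNA 0.068, other 0.002); a dominant locus carrying
71% of nucleolar snoRNA weight, emitted purely as 5′ fragments of 19/25
nt; other sdRNA lengths {19, 20, 25, 26} with weights (.35, .25, .3, .1) —
the source spectra give modes, not a full distribution, so the weights are
a declared choice; miRNA lengths peaked at 22–23 nt; non-nucleolar
compartments miRNA-dominated with ~24% unannotated and ~0.3–0.7% rRNA
weight so alignment summaries are non-trivial; ε = 0.005 and 2%
multi-mapped.  Library depths are 40k/40k/40k/20k aligned reads — scaled
an order of magnitude below a real run, with 20,000 nucleolar reads as the
documented recovery condition — and per-compartment aligned fractions
(0.717/0.695/0.682/0.577) back out the raw-read metadata.  Nuclear and
cellular libraries share one locus-weight profile (hence their high
per-locus count correlation) that differs from the nucleolar profile.

### What passing tests show, and what they do not

Recovery tests show the pipeline is *self-consistent*: parameters the
generator draws from are re-estimated within their sampling error, and at
ε = 0 every per-read label is reproduced exactly.  They do not establish
robustness to properties the generator omits: homopolymer indel errors
(Ion Torrent's dominant mode), adapter/ligation bias, PCR duplication,
misannotation, overlapping or nested real loci, or cross-contamination
between fractions.  Statistical recovery checks use 99% binomial
intervals; where ~17 loci are tested simultaneously, the number of
out-of-interval loci is compared against its Binomial(k, 0.01) null and a
pooled z-statistic bounds systematic bias, since demanding every one of k
99% intervals simultaneously would reject a correct implementation with
probability 1 − 0.99ᵏ.

## Pipeline and reproducibility

The `run` pipeline chains the stages per compartment, writes TSV/JSON
outputs, and ends with a manifest recording version, config hash, input
and output SHA-256 checksums, seed and per-stage counts (which must
satisfy the conservation invariants: unique = assigned + unannotated +
ambiguous, etc.).  Determinism contract: identical config and seed give
identical output checksums; manifest timestamps are informational only.
All randomness flows from the single integer seed in the config.  The CLI
subcommands `ingest`, `profile` and `sdrna` operate on one library each
(multi-library orchestration is `run`'s job), and `report` summarizes an
existing run directory.

## Known limitations

* No normalization (CPM/RPKM) or differential-abundance statistics — the
  analysis compares raw per-locus counts, as its summary tables do.
* Box H/ACA motifs (H: AnAnnA, ACA) can be annotated but are not scanned;
  the scanner targets box C/D chemistry.
* The guide-retention figure depends entirely on guide annotation quality;
  loci without guide annotations count as non-retaining.
* SAM records whose sequence length disagrees with the aligned span
  (soft-clips/indels) have their sequence dropped with a warning rather
  than being reconciled; alignment production is out of scope.
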