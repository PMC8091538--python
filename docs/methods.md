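# Methods

## Coordinates and identity conventions

All internal coordinates are 0-based half-open on the forward genome
strand; GTF/GFF3 input (1-based inclusive) is converted on read. An intron
is identified by the full tuple (chrom, strand, start, end): identical
coordinates on opposite strands are distinct entries because splice-site
dinucleotides are strand-dependent. Introns shared across strands of
overlapping antisense genes are therefore *not* deduplicated. Gene spans
are the min-start/max-end over each gene's transcripts, unioned across
annotation sources; junctions on non-primary contigs are kept if present —
contig filtering belongs upstream.

## Junction discovery

Junction candidates are CIGAR `N` operations. Read-level filters: records
that are unmapped, duplicate-flagged (0x400) or below MAPQ 5 are dropped
before parsing (duplicate marking itself is an upstream responsibility —
no internal deduplication is attempted). Overhangs are the
reference-consuming aligned length on each side of a gap, bounded by
adjacent `N` operations; soft clips never count. The identity requirement
("≥ 90% exact match") is evaluated inside the 15-nt reference window
adjacent to the gap on each side — i.e. ≥ 14/15 matching positions, with
deleted or substituted positions counting as mismatches — not over the
whole read side; the clause qualifies the anchoring windows. Mismatch
positions come from the MD tag when present, otherwise from direct
comparison against the genome; both paths are exercised by the tests.

Junction-level filters: "detectable in all replicates of a particular
library type" means ≥ 1 read in *each* replicate of at least one library
type, and the mean-count ≥ 2 filter is evaluated within that same library
type. Annotated junctions (exact coordinate match against the merged
reference) pass through the detectability filters only; unannotated
candidates must additionally overlap an annotated gene span, resolve to a
unique strand (unique overlapping gene strand first, splice-site
dinucleotides as tie-breaker; junctions consensus on both strands inside
antisense gene pairs are dropped as ambiguous) and carry GT-AG or AT-AC
dinucleotides (major/minor spliceosome). Whether both mates of a pair
spanning one junction count once or twice is an open question for
paired-end input; counting is per alignment record, and the simulator
emits single-end reads so the question does not arise in testing.

## Event classification

Rules applied in order against the host gene's annotated splice sites:
both sites annotated but pairing novel → skipped exon (all planted and
observed cases span ≥ 1 complete annotated internal exon; multi-exon skips
count as one event); annotated donor + novel acceptor → alt 3′SS; novel
donor + annotated acceptor → alt 5′SS; both novel → new intron. Cassette
promotion: within one annotated host intron, a junction reusing the host
donor with a novel acceptor at `a` pairs with a junction using a novel
donor at `b` and the host acceptor when `a < b`; the exon is `[a, b)`.
Each junction joins at most one exon. Ambiguity is resolved shortest exon
first, ties by higher summed read count; under this interval feasibility
order the shortest-first greedy is also maximum-cardinality (exchange
argument), which the tests confirm against an exhaustive-search oracle.
Cassette events are counted as one event with two junctions, and unpaired
halves remain alt-SS events.

Frame status is `length mod 3`; stop scanning reads the exon in
transcription orientation in the phase of the annotated CDS of the longest
protein-coding transcript containing the host intron (codons start at
offset `(3 − phase) mod 3`). Without any CDS, all three frames are scanned
and stops are reported only if every frame contains one — conservative for
the poison call. Poison = frameshifting OR (in-frame AND ≥ 1 in-frame
stop).

## Usage statistics

The exact PSI/PIR/PSO formulas are centralized in `quantify.py` so
alternates are one-line changes. PSI uses the mean of the (one or two)
inclusion-junction RPMs against the exclusion RPM, computed per replicate
and averaged over replicates with defined values; PIR uses the mean of the
two exon–intron boundary RPMs against the spliced-junction RPM; PSO is the
complement of PIR. RPM denominators are post-filter mapped read counts per
replicate. Values are clamped to [0, 100] (pure floating-point guard) and
undefined ratios are NaN, never 0. Transcript-unique junctions are those
occurring in exactly one annotated transcript; per-biotype enrichment is
the median per-junction RPM ratio between two library types, excluding
(and reporting separately) junctions with a zero denominator.

## Proximity analysis

A novel 5′ site is paired with annotated 5′ sites of junctions sharing its
3′ site (and symmetrically for 3′ sites), nearest by |distance|, ties
toward the downstream site. Distances are signed in transcription
orientation: for donors +d is d nt further into the intron; for acceptors
+d is d nt past the annotated acceptor into the downstream exon (the
NAGNAG +3/+4/+5 configuration extends the intron). Distance 0 is excluded
(it is the annotated site), and the availability scan counts a GT (donor
analysis) or AG (acceptor analysis) at distance d when using it as the
novel site would place it there; the annotated site's own dinucleotide
appears only at d = 0. Per-position usage is emitted both as site counts
and as summed RPM, since either normalization is defensible.

## Splice-site strength and conservation

Windows are 9 nt for donors (3 exonic + 6 intronic, GT at positions 4–5)
and 23 nt for acceptors (20 intronic + 3 exonic, AG at positions 19–20),
reverse-complemented into transcription orientation on the minus strand.
The default strength score is a 0th-order position-weight-matrix log2-odds
(pseudocount 0.5, uniform background) trained on the annotated-site
windows of the merged reference — a rank-preserving stand-in for
maximum-entropy scoring; the `ScoreTableModel` backend accepts externally
supplied per-position score tables for bit-compatible parity with such
scorers.

Conservation is the arithmetic mean of basewise track values over the
window's genomic footprint, orientation-independent. Track gaps are
averaged over covered bases only, with the covered fraction reported;
windows under 50% coverage are NaN (and NaN never passes a conservation
filter).

The noise null rejection-samples windows uniformly inside annotated gene
spans — both strands with equal probability, pooled across the genome
(repeated pooled draws with seed control rather than per-chromosome
strata) — keeping only windows with the consensus GT/AG at the fixed
offsets, and takes the empirical 95th percentile of each side's
conservation draws as the cutoff. Cutoffs are re-derived per dataset and
track; published cutoff values from any particular study are reference
metadata, not constants of the method. Sites at exactly the cutoff count
as conserved (≥ rule). Conserved cassette exons additionally require both
splice-site windows and the exon body at or above configurable thresholds
(defaults 1.0/1.0/1.0; null-derived per-side cutoffs are equally
supported).

## Synthetic data generator

The generator emulates the study design the pipeline targets: 20
multi-exon genes (4–7 exons of 120–240 nt, introns 300–800 nt, ~90 kb
genome) with consensus-flavored GT-AG splice sites; four annotation
sources agreeing on canonical introns with a few source-private variant
transcripts for intersection accounting; two library types — "EJC" with
50% alternative-isoform inclusion and "RNASEQ" with 5% — three replicates
each, 50,000 single-end 100-nt reads per replicate, 0.1% substitution
errors, 2% low-MAPQ and 1% duplicate-flagged decoys. Planted events cover
all five classes: an exon skip, an alt 5′SS at +5, alt 3′SS at +3/+4/+5
(NAGNAG), an exonic new intron, and cassette exons of 94 nt
(frameshifting), 69 nt (in-frame, planted stops) and 72 nt (in-frame,
scrubbed of stops), plus an annotated NMD isoform with an annotated poison
exon. Five probe junctions each trip exactly one filter: GC-AG
dinucleotides, mean count 1.67, a missing replicate, 8-nt overhangs — and
one passes everything as a called-but-noise control.

The conservation track is piecewise-constant background noise
(N(0, 0.15²) in 10-bp chunks) with annotated splice-site windows at 1.5
and planted conserved elements at 2.0. The +4/+5 NAGNAG acceptors are
recorded as conserved in the ground truth because their 23-nt windows
necessarily overlap the annotated acceptor's conserved footprint — the
same inheritance that makes acceptor-side conservation cutoffs
conservative on real data; the background-level noise exemplars are the
exonic new intron and the probe junction.

What the generator does not emulate: realistic error/quality models
(uniform qualities), paired-end mates (single-end by default, so per-read
counting is exact), RNP biochemistry or EJC footprint positioning,
chimeric alignments, and multi-contig genomes. Passing tests therefore
demonstrate correctness of the junction arithmetic, filter cascade,
classification, quantification and conservation logic under known truth —
not robustness to alignment artifacts absent from the simulation.

## Scales used by tests and the acceptance script

The end-to-end checks run at the generator defaults above. The
oracle-equivalence check uses 20 reduced alignment sets (80 reads per
replicate) so the brute-force reimplementation stays exhaustive. PSI/PIR
parameter recovery uses Poisson count sampling at depth 2000 over 200
seeded runs per inclusion level (0.1/0.5/0.9), the frame-blindness null
plants 2000 acceptor events per seed over five seeds, and null-model
convergence uses 10,000 draws per side, comparing independent-seed cutoffs
within the asymptotic quantile standard error (kernel density at the
quantile).

## Known limitations

* Strand resolution for unannotated junctions outside any stranded gene
  context relies on dinucleotide consensus alone and discards ambiguous
  cases; true antisense events inside overlapping gene pairs are excluded
  rather than guessed.
* The PWM strength model shares only rank behaviour with maximum-entropy
  scorers; absolute score values are not comparable unless a score table
  is supplied.
* PSI from uniform read sampling carries a small (< 3 points at the
  simulated scales) bias from isoform length differences; the recovery
  analyses use junction-count sampling, which is unbiased.
* bedGraph tracks are loaded fully into memory; use bigWig for
  genome-scale tracks.
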