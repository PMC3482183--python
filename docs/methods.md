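# Methods

## Problem setting

`strainsnp` implements transcriptome-based SNP discovery for pooled
population samples. Short reads from each strain are assumed already
aligned to a reference transcriptome (a set of cDNA contigs, some with
ESTScan-style ORF annotations) and summarised as samtools-mpileup
6-column text, one file per strain. The pipeline identifies, for each
strain, sites that are polymorphic within the pooled sample
(*intra-strain* SNPs), sites fixed for different alleles between two
strains (*inter-strain* SNPs), and the derived set-algebraic layers
(non-redundant unions, strain-specific SNPs, SNPs shared by all
strains), then classifies each SNP against its contig's reading frame
and summarises minor allele frequencies, transition/transversion
composition and per-contig distributions.

## Calling model

Each pileup column is decoded into substitution calls paired with
Phred+33 base qualities. Indels are parsed and discarded (the pipeline
reports substitutions only); deletion placeholders (`*`) and reference
skips consume a quality character, matching samtools' encoding.

The rule applied per site and strain:

1. discard base calls with Phred quality < `min_base_quality`
   (default 20) and all N calls;
2. if the filtered depth is < `min_depth` (default 10) the site is
   **uncallable**;
3. otherwise reduce to the two highest-count alleles (ties broken
   alphabetically). If the second allele has at least
   `min_minor_support` reads (default 2) the site is **polymorphic**,
   with MAF = minor/(major+minor) over the two called alleles only;
   otherwise it is **monomorphic** for the top allele.

The depth-10 and quality-20 thresholds are the callability regime the
pipeline is designed around. The quality filter is applied per base
call; likelihood-based genotype quality is explicitly out of scope.
`min_minor_support = 2` reflects that a single discordant read is
indistinguishable from a sequencing error at realistic error rates; it
is exposed as a knob. "Monomorphic" therefore means "no second allele
with sufficient support", which is robust to singleton errors but
implies that at a per-base error rate around 10⁻³ and depth near 100,
occasional error pairs do produce low-MAF polymorphic calls — a
property of any count-threshold caller without an error model. Sites
where a third allele also reaches the support threshold are flagged
(`extra_allele`) but still reduced to the top two.

## Set algebra

SNP identity is coordinate **plus** unordered allele pair (`SnpKey`).
Two strains polymorphic at one position for different pairs contribute
two distinct non-redundant SNPs; this is the conservative choice for
downstream assay design, where the allele pair is part of the marker.

- intra(s): sites where strain *s* is polymorphic, keyed by its pair.
- inter(a,b): sites where both strains are callable and monomorphic
  with different consensus alleles; the key's pair is the two consensus
  alleles. Monomorphism excludes polymorphism, so inter sets are
  site-disjoint from the intra sets of their two strains.
- non-redundant intra / inter: unions over strains / unordered pairs.
- strain-specific(s): sites polymorphic in *s* only. By default the
  other strains must be **callable and monomorphic** there
  (`require_callable_others=True`): absence of coverage is not evidence
  of specificity. The lenient variant (uncallable elsewhere still
  counts) is available as a flag; specific sets are pairwise disjoint
  under both rules.
- shared-all: intersection of all intra sets, reported together with
  the full 2ⁿ−1-region Venn partition of the non-redundant intra set;
  region counts sum to the union size by construction.

## Effect classification

Coordinates are 1-based inclusive. A position left of `cds_start` is
5'UTR and right of `cds_end` is 3'UTR on plus-strand ORFs; the sides
swap for minus-strand ORFs, whose reading frame runs along the reverse
complement anchored at `cds_end`. Contigs without an ORF annotation
yield `undefined`.

For coding positions the containing codon is extracted in frame, the
alternate base substituted (complemented for minus strands), and both
codons translated with the standard genetic code (NCBI table 1, via
Biopython). Categories: `synonymous` (identical amino acid),
`missense` (different amino acids, no stop involved), `pre_terminated`
(sense codon → stop; nonsense), `skip_stop_codon` (stop → sense;
stop-loss). A substitution turning the stop codon into a *different*
stop codon is classified synonymous: the protein product is unchanged.
Multi-allele sites produce one effect per (ref, alt) pair; roll-ups for
tables take the most severe category, ordered
skip_stop_codon > pre_terminated > missense > synonymous. The
reference codon is always taken from the reference transcriptome, never
a strain consensus, matching calling against a single reference.

Correctness is checked against an independent oracle that mutates the
whole contig, retranslates the entire ORF and diffs the protein; the
codon-local classifier agrees on every coding position × 3 alternate
alleles over random ORF-bearing contigs, and classification is
invariant under reverse-complementing the contig with mirrored ORF
coordinates.

## Synthetic data generator

The generator provides the study conditions for every downstream test:

- **Contigs**: uniform-random length within `contig_length_range`
  (default 300–600 bp, a realistic assembled-cDNA contig scale);
  a fraction `orf_fraction` (default 0.8) carries an embedded ORF
  (ATG + sense codons + stop, length divisible by 3, nonempty UTR
  flanks, random strand).
- **Truth**: each base independently becomes, with probability
  `poly_rate`, a within-strain polymorphism in one uniformly chosen
  strain (minor allele frequency uniform in [0.1, 0.5], a pooled
  population-level frequency, not individual genotypes — matching
  pooled pileup semantics) or, with probability `fixed_diff_rate`, a
  fixed non-reference allele in one strain. No site carries both, and
  truth is biallelic; the caller's biallelic reduction is tested
  separately with hand-built pileups.
- **Pileups**: per-site depth Poisson(`mean_depth`, default 100);
  read bases drawn from the strain's true allele frequencies, miscalled
  uniformly to another base with probability `base_error_rate`
  (default 10⁻³); qualities Gaussian(`quality_mean` = 35, sd 3)
  truncated to [2, 41] and rounded — deep-coverage RNA-seq territory,
  comfortably above the Phred-20 filter. Read-start/read-end marks are
  sprinkled in so decoders face realistic symbol streams; zero-depth
  sites are omitted as samtools does.

All randomness flows through seeded `numpy` generators with one
substream per stage, so a config + seed yields byte-identical FASTA,
ORF, truth and pileup files.

What the generator does **not** emulate: read-level artefacts
(alignment error, strand bias, indels, duplicated reads), expression-
dependent coverage (depth is homogeneous Poisson, whereas RNA-seq depth
tracks expression), tri-allelic truth, and linkage between sites.
Passing recovery tests therefore demonstrate the correctness of the
decoding/calling/set logic under the stated sampling model, not
robustness to alignment pathology in real libraries.

## Recovery criterion

With `base_error_rate = 0` and mean depth 100, the caller is expected
to be *exact*: every supportable truth polymorphism recovered with the
correct allele pair and zero polymorphic calls at truth-monomorphic
sites. "Supportable" is judged from the decoded reads alone,
independently of the calling rule: a truth polymorphic site counts if
its quality-filtered pileup contains at least `min_minor_support` reads
of each allele and at least `min_depth` total. At minor frequencies
≥ 0.1 and depth 100 this excludes only the rare binomial dropout
(order 10⁻⁴ per site); the acceptance runs use 200 contigs × 4 strains
and recover 100% of supportable sites with zero false calls, and the
called inter-strain and strain-specific sets equal the sets computed
directly from the truth table.

## Summaries and numerical choices

- Percentages are rounded half-up to one decimal (66.05 → 66.1), the
  display precision of survey tables; Python's banker's rounding is
  deliberately avoided.
- MAF histograms use 0.05-wide left-closed bins over (0, 0.5], the last
  bin right-closed so 0.5 is counted. The bin width is a documented
  knob, not a canonical value.
- Per-contig SNP distributions use exact counts as classes, with the
  cumulative series expressed as percentage of SNPs (not contigs);
  zero-SNP contigs enter only when a reference contig list is supplied.
- Gene-interval binning uses 1 Mb windows per chromosome by default.
- Ts/Tv with zero transversions reports an undefined marker rather than
  dividing; empty inputs yield undefined percentages.
- Classification tables enforce the partition identities
  (5'UTR + 3'UTR + coding + undefined = total;
  missense + pre_terminated + skip_stop_codon = non-synonymous) by
  construction.

## Problem sizes

The test suite and the reproduction script run the full pipeline at
200 contigs × 4 strains × mean depth 100 (~90 kb of reference,
~360,000 pileup columns) for recovery analysis, 50 ORF contigs
(~8,000 substitution cases) for the codon oracle, and 1,000 random
matrices for the set-algebra laws. These sizes give per-site event
counts in the hundreds, ample for exact recovery checks, while keeping
a full run around a minute.

## Known limitations

- No genotype-likelihood model; the caller is count-threshold based and
  will produce low-MAF false positives at depth ≫ 1/error-rate.
- One pileup per strain; multi-sample pileup columns are not parsed.
- Indels are discarded, not called.
- The standard genetic code only; mitochondrial contigs are not
  handled.
- ORFs lacking an in-frame stop are accepted as annotated; positions
  beyond the last complete codon are classified by frame regardless.
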