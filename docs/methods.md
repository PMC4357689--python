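# Methods

## Scope and data model

`riboforge` consumes aligned ribosome-protected-fragment (RPF) reads — one
elongating-condition sample (cycloheximide, CHX) and optionally one
initiating-condition sample (harringtonine or lactimidomycin, HARR/LTM) — plus
a genome FASTA, an Ensembl-dialect GTF, and optional VCFs (sample variants and
a dbSNP-style reference). Adapter clipping, contaminant filtering and
alignment are upstream concerns; duplicate removal is likewise assumed done.
Internally all genomic coordinates are 1-based inclusive (the GTF convention);
0-based conversions happen only at the pysam boundary and in BedGraph output.
Transcript coordinates are 0-based offsets along the mature transcript.

Transcript models are built by grouping GTF `exon` features per
`transcript_id`; CDS bounds come from `CDS` features extended by the
`stop_codon` feature (Ensembl CDS rows exclude the stop codon). Transcripts
with CDS rows but no stop codon are flagged `incomplete_cds` and their last
CDS base is used as the CDS end — common in Ensembl and must not crash.
Unknown feature types are ignored. For non-coding transcripts the "CDS" used
in footprint counting is the full exonic region.

## P-site assignment

Only RPFs of 26–34 nt (aligned length after soft clipping; clipped bases are
not part of the fragment) are relevant; others are discarded and counted. The
P-site offset from the fragment 5′ end is +12 (≤30 nt), +13 (31–33 nt) or
+14 (≥34 nt). The offset is walked along aligned reference bases, so for
spliced alignments the P-site can never land in an intron; for minus-strand
alignments the fragment 5′ end is the rightmost aligned base and the offset
walks leftwards. Mapping multiplicity is read from the `NH` tag (absent means
unique). QC stages use unique mappers only; database-construction stages
additionally accept reads reported at ≤ 15 locations, each alignment
contributing a full count at its location (no fractional 1/n weighting — the
alternative is noted as a limitation below).

## Metagenic classification

Classification is strand-aware (RIBO-seq is stranded). Translation-associated
categories exist only on protein-coding transcripts with precedence
CDS exon > 5′UTR > 3′UTR > intron; across overlapping protein-coding
isoforms the best category wins. P-sites not attributable to a protein-coding
transcript fall to any overlapping non-coding transcript (span overlap,
exons preferred) as `other_biotypes` with a per-biotype breakdown; the rest is
`intergenic`. Gene-level counts use P-sites (not whole-alignment overlap) of
unique mappers, restricted to exonic, strand-matched positions; a P-site in
exons of several genes counts for each.

## Translated-transcript calling

Footprint accumulation at start and stop codons would bias per-transcript
rates, so the first 15 and last 15 CDS positions are excluded; the normalised
count is total footprints over the remaining positions divided by their number
(CDS length − 30). A CDS of ≤ 30 nt leaves nothing to count and the
transcript is reported uncallable. Per-exon coverage is the mean count over
that exon's counted positions; exons entirely inside the exclusion windows
carry no vote. A transcript is translated when at least 85 % of its voting
exons reach the transcript-specific threshold — mean exonic footprint
coverage divided by 5. Both comparisons are carried out in exact integer
arithmetic (`5·n·Σₑ ≥ total·nₑ` and `20·n_pass ≥ 17·n_exons`), so the 85 %
boundary and the threshold comparison are sharp and scale-invariant: scaling
all counts by c > 0 cannot change a verdict. A transcript with zero counted
footprints is never called translated, although its threshold (0) would be
vacuously met by every exon — the rule is about observed synthesis, and an
all-zero transcript shows none.

## TIS calling

Initiating-ribosome P-sites concentrate at initiation codons but with
sub-codon jitter; counts are therefore accumulated over a ±1 nt window
(transcript orientation) around the first nucleotide of every candidate
codon — AUG and the nine near-cognates differing from AUG at one position
(CUG GUG UUG AAG ACG AGG AUA AUC AUU). A candidate becomes a call when

1. its accumulated count is the maximum over the 7-nt window spanning one
   codon up- and downstream (ties between candidate positions within one
   codon go to the 5′-most candidate — scanning ribosomes initiate at the
   first available start);
2. the accumulated count reaches the category's minimum count; and
3. R_init − R_elong ≥ θ with R_k = (X_k / N_k) × 10, X_k the accumulated
   count at the candidate and N_k the condition's total count over the
   transcript's exonic positions. X_elong uses the same ±1 nt window for
   symmetry.

Categories are transcript-relative: aTIS (the annotated start), 5′UTR,
downstream CDS, 3′UTR, or `no_translation` for non-coding transcripts; the
same genomic position may be called in several isoforms and is deduplicated
only at assembly. Defaults (min count, θ): aTIS (5, 0.01), 5′UTR (10, 0.05),
CDS (15, 0.15), 3′UTR (10, 0.05), no_translation (10, 0.05) — the CDS
category is strictest because elongating occupancy makes it the most
false-positive-prone. The aTIS of every transcript with elongating occupancy
is always emitted, labelled TRUE (rules pass), FALSE (covered but
non-compliant) or NO_DATA (no accumulated initiating coverage); aTIS of
non-translated transcripts are emitted only when they pass all rules.
Candidates of other categories failing any rule are discarded.

Degenerate inputs: a transcript with zero initiating reads has R_init
undefined — its non-aTIS candidates are discarded and its aTIS becomes
NO_DATA. A transcript with zero elongating reads has R_elong undefined by the
formula; it is taken as 0 (no elongating evidence against initiation) so that
initiating-only transcripts, e.g. non-coding ones, remain callable. HARR and
LTM are treated as alternative initiating conditions; one initiating profile
per run, never summed.

## Variant integration

Only single-nucleotide substitutions are supported (indels in input VCFs are
skipped with a logged count). The externally produced sample VCF is merged
with dbSNP-rescued read mismatches: every aligned read base differing from the
genome whose position **and** alternate allele occur in the dbSNP VCF is
retained (position-only matching would be laxer; the stricter reading was
chosen). Deduplication is by (chrom, pos, alt) with the caller taking
precedence. To bound database growth, rescued mismatches are counted per
overlapping transcript (exonic containment, either strand) and transcripts
exceeding five lose those records; a record shared with an under-cap
transcript survives for that transcript only, and caller variants are exempt.
The cap is idempotent.

## Proteoform assembly

Each retained TIS is translated with the standard genetic code (table 1; no
selenocysteine or read-through) from its codon to the first in-frame stop
within the transcript's exonic sequence; the initiator always yields Met
(near-cognate recoding). If no stop occurs before the transcript end the
product is truncated at the last complete codon and flagged `partial=true`;
codons containing N translate to X and flag the record. Products shorter than
6 aa are dropped (default; below any MS-identifiable length). Variants
overlapping the transcript are substituted at the nucleotide level
(strand-complemented as needed); per transcript the reference proteoform and
one proteoform with all retained variants applied are emitted, rather than a
2^n haplotype expansion, keeping the database bounded. Only non-synonymous
changes (per-variant effect against the reference codon) are listed in the
descriptor.

Redundancy elimination collapses identical sequences to the record with the
most plausible annotation (aTIS > 5′UTR > CDS > 3′UTR > no translation);
among equals a record with variant information wins; remaining ties are
resolved by a seeded random draw over lexicographically sorted contenders, so
the output is deterministic for a given seed and independent of input order.
Sequences fully contained in a longer surviving sequence are then removed
(longest-first scan). Canonical mapping assigns IDs to aTIS/5′UTR records via
a transcript→canonical table and to the other categories via exact/containment
matching against the canonical FASTA; an alignment-search tabular result
(twelve-column format, best bitscore per query) can be imported instead. In
combined mode, canonical entries unmatched by any record are appended to the
FASTA. The header grammar is
`rf|<transcript>:<tis>` followed by `key=value` descriptor fields
(`tid, tis, codon, cat, status, snv, canonical, partial`), parseable with
`riboforge.assembly.read_proteoform_fasta`.

## Synthetic data generator

The generator exists so every rule is testable against known ground truth at
desk scale (two chromosomes, ≤ ~10 genes, a few thousand reads; a full
pipeline run takes seconds). Defaults: genes alternate chromosome and strand;
protein-coding genes have 36–60 nt UTRs, CDS of 81–186 nt (ATG, random sense
codons, stop), 1–4 exons with 25–60 nt introns, and a CTG planted in the
5′UTR; every fourth gene is a 200–320 nt lincRNA with a planted ATG; every
third gene from the third onwards is left untranslated and receives no reads.
Some coding genes carry a second isoform with a 5′-truncated first exon and
the same CDS, exercising redundancy elimination. Elongating reads (default
300 per translated transcript) place P-sites uniformly over the CDS with 3×
weight inside the 15-nt start/stop windows; initiating reads (default 150 per
transcript with planted sites) put ~92 % of P-sites within ±1 nt of planted
codons and the rest as uniform noise. These depths put every planted peak at
or above twice its category's minimum count with an R margin far above θ,
while the noise floor stays well below any threshold. Read lengths are drawn
from 26–34 nt with a mode at 28 nt. Planted variants sit in CDS interiors;
when six or more are requested, six go to a single transcript as dbSNP-only
records to exercise the cap; reads carry alternate alleles with probability
0.5. All outputs are byte-stable per seed.

What the generator does **not** emulate: sequencing errors and quality
degradation, rRNA/contaminant reads, non-uniform (sequence-biased) footprint
densities, overlapping genes, multimapping ambiguity, indels, or realistic
transcriptome scale. Passing tests therefore demonstrate rule exactness and
pipeline correctness, not calling performance on noisy real libraries.

## Design choices on open points

- Exon "coverage" in the 85 % rule is the per-position mean over counted
  positions, not breadth; the transcript threshold uses the same counted set,
  keeping the two quantities commensurable.
- The 15-nt exclusion windows apply only around the annotated start/stop, not
  around alternative called TIS.
- Multimapped reads are not fractionally weighted (see above).
- The rule-(i) maximum is taken over accumulated (±1 nt) counts, not raw
  single-position counts, consistent with the accumulation step.
- dbSNP matching is by position and allele.
- The per-transcript variant cap applies to dbSNP-rescued mismatches; caller
  variants are exempt — the cap's purpose is to stop dbSNP-dense transcripts
  from flooding the database.

## Known limitations

- Substitutions only; no indel-aware assembly.
- One initiating condition per run; HARR and LTM are never combined.
- Canonical sequence mapping is exact containment, not alignment; distant
  homologs will not map unless an external alignment-search result is
  imported.
- The reference + all-variants proteoform pair under-represents mixed
  haplotypes.
- Translated-transcript calling assumes fairly uniform CDS coverage; strongly
  paused transcripts can fail the exon rule.
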