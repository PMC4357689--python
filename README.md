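# riboforge

**From ribosome-profiling alignments to a proteoform protein-sequence search
space.**

Standard proteomics searches a curated protein database (e.g. Swiss-Prot) and
therefore cannot identify proteoforms that are missing from it: 5′-extended
forms, products of upstream ORFs, near-cognate initiation events, alternative
isoforms, or sequence variants. Ribosome profiling (RIBO-seq) observes
translation directly — elongating ribosomes frozen with cycloheximide (CHX)
cover coding regions, while initiating ribosomes stalled with harringtonine
(HARR) or lactimidomycin (LTM) pile up at translation-initiation sites (TIS).
`riboforge` turns aligned RIBO-seq reads into a compact, non-redundant FASTA
of the translation products a sample actually makes, suitable as an MS/MS
search space, requiring only one-reading-frame translation rather than a
three- or six-frame explosion.

It is aimed at proteogenomics practitioners who already have aligned
RIBO-seq data (SAM/BAM), an Ensembl-dialect GTF and a genome FASTA, and
optionally a variant VCF, a dbSNP-style reference VCF and a canonical protein
database.

## Method

1. **P-site assignment.** Alignments of relevant ribosome-protected fragments
   (26–34 nt after clipping) are reduced to their ribosomal P-site using the
   length-dependent 5′ offset (+12 for ≤30 nt, +13 for 31–33 nt, +14 for
   ≥34 nt), walked along aligned bases only so spliced alignments never place
   a P-site in an intron. QC uses uniquely mapped reads; database construction
   additionally admits multimappers reported at up to 15 locations. Per-strand
   BedGraph tracks are emitted for genome-browser inspection.
2. **Metagenic QC.** Each P-site is classified into 5′UTR / CDS exon / intron
   / 3′UTR (protein-coding transcripts), other biotypes, or intergenic, plus
   gene-level abundance, cumulative-distribution and density summaries.
3. **Translated-transcript calling.** Footprints are counted over the CDS
   excluding the 15 nt after the start and before the stop codon (start/stop
   accumulation artefacts) and normalised by the counted length (CDS − 30).
   A transcript is translated when ≥ 85 % of its exons reach a mean coverage
   of at least one fifth of the transcript's mean exonic footprint coverage.
4. **TIS calling.** Initiating-ribosome counts are accumulated over a ±1 nt
   window at every AUG or near-cognate codon (one mismatch from AUG). A
   candidate is kept when it is the accumulated maximum within a 7-nt window,
   reaches a per-category minimum count, and satisfies

   > R<sub>LTM/HARR</sub> − R<sub>CHX</sub> ≥ θ, with
   > R<sub>k</sub> = (X<sub>k</sub>/N<sub>k</sub>) × 10,

   where X<sub>k</sub> is the windowed count at the candidate and
   N<sub>k</sub> the transcript total for condition *k*. Default (min count,
   θ) per category: aTIS (5, 0.01), 5′UTR (10, 0.05), downstream CDS
   (15, 0.15), 3′UTR and non-coding (10, 0.05). Annotated starts of
   transcripts with elongating occupancy are always reported as TRUE, FALSE
   or NO_DATA.
5. **Variant integration.** An externally called VCF is merged with read
   mismatches rescued through dbSNP (position + allele match); transcripts
   accumulating more than five rescued mismatches have them removed.
6. **Proteoform assembly.** Each retained TIS is translated in one frame to
   the first in-frame stop (near-cognate starts recoded to Met), variants are
   applied at the nucleotide level, and only non-synonymous changes are kept
   in the descriptor. Identical sequences collapse by annotation rank
   (aTIS > 5′UTR > CDS > 3′UTR > no translation; variant information breaks
   ties; remaining ties are a seeded random draw) and subsequences of
   surviving entries are removed. Records map to a canonical database by
   transcript-ID table (aTIS/5′UTR) or sequence containment (other
   categories), and unmatched canonical entries can be appended to form a
   combined search space.

## Worked example

The package ships a synthetic-data generator with full ground truth, so a
complete run needs no external data:

```bash
riboforge fixtures --out-dir demo/fix --n-genes 6 --seed 4
riboforge run \
    --gtf demo/fix/annotation.gtf --fasta demo/fix/genome.fa \
    --chx-bam demo/fix/chx.sam --ltm-bam demo/fix/ltm.sam \
    --sample-vcf demo/fix/sample.vcf --dbsnp-vcf demo/fix/dbsnp.vcf \
    --seed 4 --out-dir demo/out
```

which prints `pipeline complete; FASTA at demo/out/proteoforms.fasta` and
leaves per-stage artifacts under `demo/out/`. The transcript-call table
(`transcript_calls.tsv`) for this run starts:

```
transcript_id  uncallable  normalized_count  threshold  n_exons  n_pass  is_translated
t1             False       1.5806…           0.3161…    3        3       True
t2             False       1.7407…           0.3481…    1        1       True
t3             False       0.0               0.0        2        2       False
```

`normalized_count` is footprints per counted-CDS nucleotide, `threshold` is
one fifth of the mean exonic coverage, and `is_translated` applies the 85 %
exon rule — t3 received no footprints and is correctly not translated. The
final FASTA headers encode transcript, TIS, category, aTIS status and
non-synonymous variants:

```
>rf|t1:195 tid=t1|tis=195|codon=ATG|cat=aTIS|status=TRUE|snv=chr1:280A>G(R20G);chr1:304T>G(W28G)
>rf|t2:123 tid=t2|tis=123|codon=CTG|cat=5UTR|snv=chr2:208C>T(A29V)
>rf|t4:687 tid=t4|tis=687|codon=ATG|cat=no_translation
```

Here t1's annotated start passes all TIS rules (status TRUE) and carries two
non-synonymous variants; t2 initiates at a near-cognate CTG in its 5′UTR
(recoded to Met); t4 is a non-coding transcript with initiating-ribosome
evidence. The run manifest for this example reports 7 transcripts, 4 called
translated, 12 TIS calls, 3 retained variants and 7 proteoform entries.

Every stage is also callable as a library function (`riboforge.build_profile`,
`riboforge.call_translated`, `riboforge.call_tis`, `riboforge.assemble`, …) or
as an individual subcommand (`ingest`, `qc`, `transcripts`, `tis`,
`variants`, `assemble`) on the flat-file artifacts.

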