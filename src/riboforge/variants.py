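"""Variant integration: dbSNP rescue of read mismatches and the per-transcript cap.

Externally called variants (a VCF consumed in place of a pileup-caller run) are
merged with read mismatches rescued via a dbSNP-style reference VCF: every
substitution observed in the aligned reads whose position and alternate allele
match a dbSNP record is retained.  To keep the search database bounded, the
number of dbSNP-rescued mismatches is counted per transcript and, when a
transcript accumulates more than five, those records are dropped for that
transcript (a record survives through any other transcript that stays under
the cap).  Caller-produced variants are exempt from the cap.  Only
single-nucleotide substitutions are handled; indels are skipped and counted.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, replace
from pathlib import Path
from typing import Iterable

import pandas as pd
import pysam

from .annotation import AnnotationBundle, GenomeSequence

logger = logging.getLogger(__name__)

SOURCE_CALLER = "caller"
SOURCE_DBSNP = "dbsnp_rescue"

MAX_DBSNP_PER_TRANSCRIPT = 5


@dataclass(frozen=True)
class VariantRecord:
    chromosome: str
    position: int  # 1-based
    ref: str
    alt: str
    source: str
    transcript_ids: frozenset[str] = frozenset()

    @property
    def key(self) -> tuple[str, int, str]:
        return (self.chromosome, self.position, self.alt)


def read_vcf_snvs(path: str | Path) -> list[tuple[str, int, str, str]]:
    """Read single-nucleotide substitutions from a VCF as
    (chrom, pos, ref, alt); multi-allelic records are expanded and indels
    skipped (with a logged count)."""
    out = []
    skipped = 0
    with pysam.VariantFile(str(path)) as vcf:
        for rec in vcf:
            for alt in rec.alts or ():
                if len(rec.ref) == 1 and len(alt) == 1 and alt != rec.ref:
                    out.append((rec.chrom, rec.pos, rec.ref.upper(), alt.upper()))
                else:
                    skipped += 1
    if skipped:
        logger.info("skipped %d non-SNV alleles in %s", skipped, path)
    return out


def _overlapping_transcripts(
    annotation: AnnotationBundle, chrom: str, pos: int
) -> frozenset[str]:
    """Transcripts whose exons contain the position (either strand: variants
    are genomic)."""
    return frozenset(
        t.transcript_id
        for t in annotation.transcripts_at(chrom, pos)
        if t.genomic_to_tpos(pos) is not None
    )


def rescue_dbsnp_mismatches(
    alignments: str | Path | Iterable[pysam.AlignedSegment],
    genome: GenomeSequence,
    dbsnp_vcf: str | Path,
    annotation: AnnotationBundle | None = None,
) -> list[VariantRecord]:
    """Scan aligned read bases for substitutions present in dbSNP.

    Every aligned (read base != genome base) site whose position and alternate
    allele occur in the dbSNP VCF becomes a rescue record; mismatches absent
    from dbSNP are dropped by this path.
    """
    dbsnp: dict[tuple[str, int], set[tuple[str, str]]] = {}
    for chrom, pos, ref, alt in read_vcf_snvs(dbsnp_vcf):
        dbsnp.setdefault((chrom, pos), set()).add((ref, alt))

    close_me = None
    if isinstance(alignments, (str, Path)):
        close_me = pysam.AlignmentFile(str(alignments), check_sq=False)
        records: Iterable[pysam.AlignedSegment] = close_me
    else:
        records = alignments

    found: dict[tuple[str, int, str], str] = {}  # (chrom,pos,alt) -> ref
    try:
        for read in records:
            if read.is_unmapped:
                continue
            chrom = read.reference_name
            seq = read.query_sequence
            if seq is None:
                continue
            for qpos, rpos in read.get_aligned_pairs(matches_only=True):
                pos1 = rpos + 1
                base = seq[qpos].upper()
                ref = genome.base(chrom, pos1)
                if base == ref or base == "N":
                    continue
                if (ref, base) in dbsnp.get((chrom, pos1), ()):
                    found[(chrom, pos1, base)] = ref
    finally:
        if close_me is not None:
            close_me.close()

    out = []
    for (chrom, pos, alt), ref in sorted(found.items()):
        tids = (
            _overlapping_transcripts(annotation, chrom, pos)
            if annotation is not None
            else frozenset()
        )
        out.append(
            VariantRecord(chrom, pos, ref, alt, SOURCE_DBSNP, transcript_ids=tids)
        )
    return out


def merge_with_caller(
    caller_snvs: list[tuple[str, int, str, str]],
    rescued: list[VariantRecord],
    annotation: AnnotationBundle | None = None,
    genome: GenomeSequence | None = None,
) -> list[VariantRecord]:
    """Combine caller variants with dbSNP rescues, deduplicating by
    (chrom, pos, alt); the caller takes precedence."""
    merged: dict[tuple[str, int, str], VariantRecord] = {}
    for r in rescued:
        merged[r.key] = r
    for chrom, pos, ref, alt in caller_snvs:
        if genome is not None and genome.base(chrom, pos) != ref:
            raise ValueError(
                f"caller variant {chrom}:{pos} {ref}>{alt}: REF does not match genome"
            )
        tids = (
            _overlapping_transcripts(annotation, chrom, pos)
            if annotation is not None
            else frozenset()
        )
        merged[(chrom, pos, alt)] = VariantRecord(
            chrom, pos, ref, alt, SOURCE_CALLER, transcript_ids=tids
        )
    return [merged[k] for k in sorted(merged)]


def cap_per_transcript(
    variants: list[VariantRecord],
    max_per_transcript: int = MAX_DBSNP_PER_TRANSCRIPT,
) -> list[VariantRecord]:
    """Apply the per-transcript cap on dbSNP-rescued mismatches.

    Transcripts carrying more than ``max_per_transcript`` rescued mismatches
    have those records removed; a record shared with an under-cap transcript
    survives for that transcript only (its transcript set is pruned).  Caller
    variants pass through untouched.  The operation is idempotent.
    """
    counts: dict[str, int] = {}
    for v in variants:
        if v.source != SOURCE_DBSNP:
            continue
        for tid in v.transcript_ids:
            counts[tid] = counts.get(tid, 0) + 1
    capped = {tid for tid, n in counts.items() if n > max_per_transcript}

    out: list[VariantRecord] = []
    for v in variants:
        if v.source != SOURCE_DBSNP or not v.transcript_ids:
            out.append(v)
            continue
        keep = v.transcript_ids - capped
        if keep:
            out.append(replace(v, transcript_ids=frozenset(keep)))
    return out


def variants_to_frame(variants: list[VariantRecord]) -> pd.DataFrame:
    rows = [
        {
            "chromosome": v.chromosome,
            "position": v.position,
            "ref": v.ref,
            "alt": v.alt,
            "source": v.source,
            "transcript_ids": ",".join(sorted(v.transcript_ids)),
        }
        for v in sorted(variants, key=lambda v: v.key)
    ]
    return pd.DataFrame(
        rows,
        columns=["chromosome", "position", "ref", "alt", "source", "transcript_ids"],
    )


def write_variants_tsv(variants: list[VariantRecord], path: str | Path) -> None:
    variants_to_frame(variants).to_csv(path, sep="\t", index=False)


def integrate_variants(
    annotation: AnnotationBundle,
    alignments: str | Path | Iterable[pysam.AlignedSegment] | None,
    sample_vcf: str | Path | None,
    dbsnp_vcf: str | Path | None,
) -> list[VariantRecord]:
    """Full variant stage: rescue + merge + cap.  Any input may be absent."""
    rescued: list[VariantRecord] = []
    if alignments is not None and dbsnp_vcf is not None:
        rescued = rescue_dbsnp_mismatches(
            alignments, annotation.genome, dbsnp_vcf, annotation=annotation
        )
    caller = read_vcf_snvs(sample_vcf) if sample_vcf is not None else []
    merged = merge_with_caller(
        caller, rescued, annotation=annotation, genome=annotation.genome
    )
    return cap_per_transcript(merged)
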