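"""Translated-transcript calling from elongating-ribosome coverage.

Footprints pile up at start and stop codons, so the 15 nt following the start
codon and the 15 nt preceding the stop codon are excluded from counting; the
per-transcript footprint count is normalised by the remaining counted CDS
length (CDS length - 30 nt).  A transcript is called translated when at least
85% of its exons reach a per-exon mean coverage of at least one fifth of the
transcript's mean exonic footprint coverage.  All comparisons use exact
integer/rational arithmetic so the 85% boundary is sharp.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import pandas as pd

from .annotation import AnnotationBundle, TranscriptModel, coding_sequence
from .ingest import PsiteProfile

EXCLUSION_NT = 15  # after start codon / before stop codon
PASS_FRACTION_NUM, PASS_FRACTION_DEN = 17, 20  # 85%


def counted_cds_positions(t: TranscriptModel) -> tuple[int, ...]:
    """Genomic positions over which footprints are counted.

    For coding transcripts this is the CDS minus the first and last 15 nt
    (start/stop accumulation windows); non-coding transcripts use their full
    exonic region with no exclusion.  A CDS of 30 nt or less leaves nothing to
    count and the transcript is uncallable.
    """
    cds = coding_sequence(t)
    if not t.is_coding:
        return cds
    if len(cds) <= 2 * EXCLUSION_NT:
        return ()
    return cds[EXCLUSION_NT:-EXCLUSION_NT]


def normalized_count(t: TranscriptModel, profile: PsiteProfile) -> float | None:
    """Footprints per counted-CDS nucleotide, or ``None`` if uncallable."""
    counted = counted_cds_positions(t)
    if not counted:
        return None
    total = sum(
        profile.count_at(t.chromosome, t.strand, g) for g in counted
    )
    return total / len(counted)


@dataclass
class TranslationCall:
    transcript_id: str
    uncallable: bool
    normalized_count: float | None
    threshold: float | None  # mean exonic footprint coverage / 5
    exon_coverages: list[float] = field(default_factory=list)
    n_exons_counted: int = 0
    n_exons_passing: int = 0
    is_translated: bool = False

    @property
    def fraction_exons_passing(self) -> float | None:
        if self.n_exons_counted == 0:
            return None
        return self.n_exons_passing / self.n_exons_counted


def call_translated(t: TranscriptModel, profile: PsiteProfile) -> TranslationCall:
    """Apply the 85% exon-coverage rule to one transcript."""
    counted = counted_cds_positions(t)
    if not counted:
        return TranslationCall(
            transcript_id=t.transcript_id,
            uncallable=True,
            normalized_count=None,
            threshold=None,
        )

    # per-exon partition of the counted positions (transcript exon order)
    per_exon_sum: list[int] = []
    per_exon_n: list[int] = []
    counted_set = set(counted)
    for s, e in t.exons:
        n_here = 0
        sum_here = 0
        for g in range(s, e + 1):
            if g in counted_set:
                n_here += 1
                sum_here += profile.count_at(t.chromosome, t.strand, g)
        if n_here:  # exons entirely inside exclusion windows carry no vote
            per_exon_n.append(n_here)
            per_exon_sum.append(sum_here)

    total = sum(per_exon_sum)
    n_counted = sum(per_exon_n)
    # exon passes iff  sum_e/n_e >= total/(5*n_counted)
    #             iff  5 * n_counted * sum_e >= total * n_e   (exact, integer)
    n_pass = sum(
        1
        for sum_e, n_e in zip(per_exon_sum, per_exon_n)
        if 5 * n_counted * sum_e >= total * n_e
    )
    n_exons = len(per_exon_n)
    translated = (
        total > 0 and PASS_FRACTION_DEN * n_pass >= PASS_FRACTION_NUM * n_exons
    )
    return TranslationCall(
        transcript_id=t.transcript_id,
        uncallable=False,
        normalized_count=total / n_counted,
        threshold=total / n_counted / 5,
        exon_coverages=[s / n for s, n in zip(per_exon_sum, per_exon_n)],
        n_exons_counted=n_exons,
        n_exons_passing=n_pass,
        is_translated=translated,
    )


def call_all(
    annotation: AnnotationBundle, profile: PsiteProfile
) -> dict[str, TranslationCall]:
    return {
        tid: call_translated(t, profile)
        for tid, t in sorted(annotation.transcripts.items())
    }


def calls_to_frame(calls: dict[str, TranslationCall]) -> pd.DataFrame:
    rows = []
    for tid in sorted(calls):
        c = calls[tid]
        rows.append(
            {
                "transcript_id": tid,
                "uncallable": c.uncallable,
                "normalized_count": c.normalized_count,
                "threshold": c.threshold,
                "n_exons": c.n_exons_counted,
                "n_pass": c.n_exons_passing,
                "is_translated": c.is_translated,
            }
        )
    return pd.DataFrame(rows)


def write_calls_tsv(calls: dict[str, TranslationCall], path: str | Path) -> None:
    calls_to_frame(calls).to_csv(path, sep="\t", index=False)
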