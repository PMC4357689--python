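"""Transcript models, genome access and interval lookup for Ensembl-style annotation.

Coordinates are 1-based inclusive genomic positions throughout (the GTF
convention); conversion to 0-based half-open happens only at BedGraph emission
and at the pysam boundary.  Transcript ("spliced") coordinates are 0-based
offsets along the mature transcript in 5'->3' orientation.
"""

from __future__ import annotations

import functools
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping

import gffutils
from intervaltree import IntervalTree
from pyfaidx import Fasta

_COMPLEMENT = str.maketrans("ACGTNacgtn", "TGCANtgcan")

PROTEIN_CODING = "protein_coding"


def reverse_complement(seq: str) -> str:
    return seq.translate(_COMPLEMENT)[::-1]


class AnnotationError(ValueError):
    """Raised for malformed or inconsistent annotation inputs."""


@dataclass
class TranscriptModel:
    """One annotated transcript isoform.

    Parameters
    ----------
    exons
        Genomic ``[start, end]`` intervals, 1-based inclusive.  They may be
        given in any order; they are stored sorted 5'->3' in transcript
        orientation (ascending start for ``+`` strand, descending for ``-``).
    cds_start
        Genomic position of the first nucleotide of the annotated start codon,
        or ``None`` for transcripts without an annotated CDS.
    cds_end
        Genomic position of the last nucleotide of the stop codon (or of the
        last CDS base when the stop codon is not annotated, in which case
        ``incomplete_cds`` is set).
    """

    transcript_id: str
    gene_id: str
    chromosome: str
    strand: str
    biotype: str
    exons: list[tuple[int, int]]
    cds_start: int | None = None
    cds_end: int | None = None
    incomplete_cds: bool = False

    def __post_init__(self) -> None:
        if self.strand not in {"+", "-"}:
            raise AnnotationError(
                f"{self.transcript_id}: strand must be '+' or '-', got {self.strand!r}"
            )
        if not self.exons:
            raise AnnotationError(f"{self.transcript_id}: transcript has no exons")
        exons = sorted((int(s), int(e)) for s, e in self.exons)
        for s, e in exons:
            if s > e:
                raise AnnotationError(
                    f"{self.transcript_id}: exon start {s} > end {e}"
                )
        for (_, e1), (s2, _) in zip(exons, exons[1:]):
            if s2 <= e1:
                raise AnnotationError(f"{self.transcript_id}: overlapping exons")
        if self.strand == "-":
            exons.reverse()
        self.exons = [tuple(x) for x in exons]
        if (self.cds_start is None) != (self.cds_end is None):
            raise AnnotationError(
                f"{self.transcript_id}: cds_start/cds_end must both be set or absent"
            )

    # -- basic geometry ---------------------------------------------------

    @property
    def length(self) -> int:
        return sum(e - s + 1 for s, e in self.exons)

    @property
    def span(self) -> tuple[int, int]:
        """Genomic (min, max) over all exons."""
        lo = min(s for s, _ in self.exons)
        hi = max(e for _, e in self.exons)
        return lo, hi

    @property
    def is_coding(self) -> bool:
        return self.cds_start is not None

    @functools.cached_property
    def _genomic_order(self) -> tuple[int, ...]:
        """Genomic position of each transcript coordinate, 5'->3'."""
        out: list[int] = []
        for s, e in self.exons:
            if self.strand == "+":
                out.extend(range(s, e + 1))
            else:
                out.extend(range(e, s - 1, -1))
        return tuple(out)

    @functools.cached_property
    def _genomic_index(self) -> dict[int, int]:
        return {g: i for i, g in enumerate(self._genomic_order)}

    def exonic_positions(self) -> tuple[int, ...]:
        """All exonic genomic positions in transcript 5'->3' order."""
        return self._genomic_order

    def tpos_to_genomic(self, tpos: int) -> int:
        if not 0 <= tpos < self.length:
            raise IndexError(
                f"{self.transcript_id}: transcript position {tpos} out of range"
            )
        return self._genomic_order[tpos]

    def genomic_to_tpos(self, gpos: int) -> int | None:
        """Transcript coordinate of a genomic position, or ``None`` if intronic
        / outside the exons."""
        return self._genomic_index.get(gpos)

    def contains(self, gpos: int) -> bool:
        lo, hi = self.span
        return lo <= gpos <= hi

    def blocks_for_tinterval(self, tstart: int, length: int) -> list[tuple[int, int]]:
        """Genomic blocks (ascending, 1-based inclusive) covered by transcript
        interval ``[tstart, tstart+length)`` — the CIGAR-style block layout of
        a read whose fragment covers that interval."""
        if length <= 0:
            return []
        positions = sorted(
            self._genomic_order[tstart : tstart + length]
        )
        if len(positions) != length:
            raise IndexError(
                f"{self.transcript_id}: interval [{tstart},{tstart + length}) "
                "exceeds transcript length"
            )
        blocks: list[tuple[int, int]] = []
        run_start = prev = positions[0]
        for p in positions[1:]:
            if p == prev + 1:
                prev = p
                continue
            blocks.append((run_start, prev))
            run_start = prev = p
        blocks.append((run_start, prev))
        return blocks

    # -- CDS geometry ------------------------------------------------------

    @functools.cached_property
    def cds_tpos_bounds(self) -> tuple[int, int] | None:
        """(first, last) transcript coordinates of the CDS (incl. stop codon)."""
        if not self.is_coding:
            return None
        ts = self.genomic_to_tpos(self.cds_start)
        te = self.genomic_to_tpos(self.cds_end)
        if ts is None or te is None:
            raise AnnotationError(
                f"{self.transcript_id}: CDS bounds fall outside the exon union"
            )
        if ts > te:
            raise AnnotationError(
                f"{self.transcript_id}: CDS bounds inverted in transcript coordinates"
            )
        return ts, te

    def cds_positions(self) -> tuple[int, ...]:
        """Genomic positions of the CDS (start through stop codon), 5'->3'."""
        bounds = self.cds_tpos_bounds
        if bounds is None:
            raise AnnotationError(f"{self.transcript_id}: transcript has no CDS")
        ts, te = bounds
        return self._genomic_order[ts : te + 1]


class GenomeSequence:
    """In-memory genome: chromosome name -> uppercased nucleotide string."""

    def __init__(self, sequences: Mapping[str, str]):
        self._seqs = {name: str(seq).upper() for name, seq in sequences.items()}

    @classmethod
    def from_fasta(cls, path: str | Path) -> "GenomeSequence":
        fa = Fasta(str(path), as_raw=True, read_ahead=1_000_000)
        try:
            return cls({name: str(fa[name][:]) for name in fa.keys()})
        finally:
            fa.close()

    def __contains__(self, chrom: str) -> bool:
        return chrom in self._seqs

    def chromosomes(self) -> list[str]:
        return list(self._seqs)

    def length(self, chrom: str) -> int:
        return len(self._seqs[chrom])

    def fetch(self, chrom: str, start: int, end: int) -> str:
        """Sequence of ``chrom:[start, end]`` (1-based inclusive)."""
        if chrom not in self._seqs:
            raise KeyError(f"unknown chromosome {chrom!r}")
        seq = self._seqs[chrom]
        if not (1 <= start <= end <= len(seq)):
            raise IndexError(
                f"{chrom}:{start}-{end} outside chromosome bounds (1-{len(seq)})"
            )
        return seq[start - 1 : end]

    def base(self, chrom: str, pos: int) -> str:
        return self.fetch(chrom, pos, pos)


def transcript_sequence(t: TranscriptModel, genome: GenomeSequence) -> str:
    """Mature transcript sequence, 5'->3' (reverse-complemented on ``-``)."""
    parts = []
    for s, e in t.exons:
        block = genome.fetch(t.chromosome, s, e)
        parts.append(reverse_complement(block) if t.strand == "-" else block)
    return "".join(parts)


def coding_sequence(t: TranscriptModel) -> tuple[int, ...]:
    """Genomic positions of the region used as "CDS" for footprint counting.

    Protein-coding transcripts with CDS bounds: start codon through stop codon,
    exonic positions only.  Everything else: the full exonic region.
    """
    if t.is_coding:
        return t.cds_positions()
    return t.exonic_positions()


@dataclass
class AnnotationBundle:
    """Parsed annotation: transcript models + genome + interval index."""

    transcripts: dict[str, TranscriptModel]
    genome: GenomeSequence
    _trees: dict[str, IntervalTree] = field(default_factory=dict, repr=False)

    def __post_init__(self) -> None:
        if not self._trees:
            trees: dict[str, IntervalTree] = {}
            for t in self.transcripts.values():
                lo, hi = t.span
                trees.setdefault(t.chromosome, IntervalTree()).addi(
                    lo, hi + 1, t.transcript_id
                )
            self._trees = trees

    def transcripts_at(
        self, chrom: str, pos: int, strand: str | None = None
    ) -> list[TranscriptModel]:
        """Transcripts whose genomic span (exons+introns) covers ``pos``."""
        tree = self._trees.get(chrom)
        if tree is None:
            return []
        hits = [self.transcripts[iv.data] for iv in tree.at(pos)]
        if strand is not None:
            hits = [t for t in hits if t.strand == strand]
        return sorted(hits, key=lambda t: t.transcript_id)

    def genes(self) -> dict[str, list[str]]:
        out: dict[str, list[str]] = {}
        for t in self.transcripts.values():
            out.setdefault(t.gene_id, []).append(t.transcript_id)
        return {g: sorted(ts) for g, ts in out.items()}


def _attr(feature, *keys: str) -> str | None:
    for key in keys:
        if key in feature.attributes:
            return feature.attributes[key][0]
    return None


def load_annotation(
    gtf_path: str | Path,
    genome_path: str | Path | None = None,
    genome: GenomeSequence | None = None,
) -> AnnotationBundle:
    """Parse an Ensembl-dialect GTF plus genome FASTA into an annotation bundle.

    Transcript models are assembled by grouping ``exon`` features by their
    ``transcript_id``; CDS bounds come from ``CDS`` features extended by the
    ``stop_codon`` feature when present (Ensembl CDS excludes the stop codon).
    Transcripts with CDS but no annotated stop codon are flagged
    ``incomplete_cds`` rather than rejected.  Unknown feature types are ignored.
    """
    if genome is None:
        if genome_path is None:
            raise ValueError("either genome_path or genome must be given")
        genome = GenomeSequence.from_fasta(genome_path)

    try:
        db = gffutils.create_db(
            str(gtf_path),
            ":memory:",
            force=True,
            keep_order=True,
            disable_infer_genes=True,
            disable_infer_transcripts=True,
        )
    except Exception as exc:  # gffutils raises assorted parse errors
        raise AnnotationError(f"failed to parse GTF {gtf_path}: {exc}") from exc

    exons: dict[str, list] = {}
    cds: dict[str, list] = {}
    stops: dict[str, list] = {}
    meta: dict[str, dict] = {}

    for feat in db.all_features():
        ftype = feat.featuretype
        if ftype not in {"exon", "CDS", "stop_codon"}:
            continue
        tid = _attr(feat, "transcript_id")
        if tid is None:
            raise AnnotationError(
                f"{gtf_path}: {ftype} feature at {feat.seqid}:{feat.start} "
                "lacks transcript_id"
            )
        if feat.seqid not in genome:
            raise AnnotationError(
                f"{gtf_path}: chromosome {feat.seqid!r} (transcript {tid}) "
                "absent from the genome FASTA"
            )
        if tid not in meta:
            gene_id = _attr(feat, "gene_id") or tid
            biotype = (
                _attr(feat, "transcript_biotype", "gene_biotype", "biotype")
                or feat.source
            )
            meta[tid] = {
                "gene_id": gene_id,
                "chromosome": feat.seqid,
                "strand": feat.strand,
                "biotype": biotype,
            }
        {"exon": exons, "CDS": cds, "stop_codon": stops}[ftype].setdefault(
            tid, []
        ).append((feat.start, feat.end))

    transcripts: dict[str, TranscriptModel] = {}
    for tid, info in meta.items():
        ex = exons.get(tid)
        if not ex:
            continue  # CDS-only rows without exons: nothing to model
        strand = info["strand"]
        cds_start = cds_end = None
        incomplete = False
        if tid in cds:
            lo = min(s for s, _ in cds[tid])
            hi = max(e for _, e in cds[tid])
            if tid in stops:
                slo = min(s for s, _ in stops[tid])
                shi = max(e for _, e in stops[tid])
                lo, hi = min(lo, slo), max(hi, shi)
            else:
                incomplete = True
            cds_start, cds_end = (lo, hi) if strand == "+" else (hi, lo)
        transcripts[tid] = TranscriptModel(
            transcript_id=tid,
            gene_id=info["gene_id"],
            chromosome=info["chromosome"],
            strand=strand,
            biotype=info["biotype"],
            exons=ex,
            cds_start=cds_start,
            cds_end=cds_end,
            incomplete_cds=incomplete,
        )
    return AnnotationBundle(transcripts=transcripts, genome=genome)
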