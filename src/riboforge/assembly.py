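"""Proteoform assembly: translation of retained TIS into a non-redundant FASTA
search space.

Each retained TIS is translated in a single reading frame from its codon to
the first in-frame stop within the transcript's exonic sequence; near-cognate
initiator codons are recoded to methionine.  Retained sequence variants are
substituted at the nucleotide level before translation and only
non-synonymous changes appear in the record descriptor.  Redundancy is then
eliminated: identical sequences collapse to the record with the most plausible
annotation (aTIS > 5'UTR > CDS > 3'UTR > no_translation; among equals, variant
information wins; remaining ties break by a seeded random draw) and any
sequence fully contained in another surviving sequence is removed.  Survivors
can be mapped to a canonical protein database by transcript-ID table (aTIS and
5'UTR records) or by exact/containment sequence matching (the remaining
categories), and the final FASTA can optionally append unmatched canonical
entries to form a combined search space.
"""

from __future__ import annotations

import logging
import random
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable, Mapping

from Bio import SeqIO
from Bio.Data import CodonTable
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

from .annotation import (
    GenomeSequence,
    TranscriptModel,
    reverse_complement,
    transcript_sequence,
)
from .tis import (
    CAT_3UTR,
    CAT_5UTR,
    CAT_ATIS,
    CAT_CDS,
    CAT_NO_TRANSLATION,
    TISCall,
)
from .variants import VariantRecord

logger = logging.getLogger(__name__)

_TABLE = CodonTable.unambiguous_dna_by_id[1]  # standard genetic code
_CODON_TO_AA = dict(_TABLE.forward_table)
_STOP_CODONS = frozenset(_TABLE.stop_codons)

MIN_PROTEIN_LENGTH = 6  # aa; shorter products are not identifiable by MS

ANNOTATION_RANK = {
    CAT_ATIS: 0,
    CAT_5UTR: 1,
    CAT_CDS: 2,
    CAT_3UTR: 3,
    CAT_NO_TRANSLATION: 4,
}


@dataclass(frozen=True)
class AppliedVariant:
    chromosome: str
    position: int
    ref: str
    alt: str
    codon_index: int | None   # 0-based codon within the ORF, None if outside
    ref_aa: str | None
    alt_aa: str | None

    @property
    def is_nonsynonymous(self) -> bool:
        return (
            self.codon_index is not None
            and self.ref_aa is not None
            and self.ref_aa != self.alt_aa
        )


@dataclass
class ProteoformRecord:
    transcript_id: str
    tis_genomic_pos: int
    tis_tpos: int
    codon: str
    category: str
    atis_status: str | None
    sequence: str
    applied_variants: tuple[AppliedVariant, ...] = ()
    canonical_id: str | None = None
    truncated: bool = False   # no in-frame stop before transcript end
    ambiguous: bool = False   # contains X from N-containing codons

    @property
    def has_variants(self) -> bool:
        return len(self.applied_variants) > 0

    @property
    def nonsynonymous_variants(self) -> tuple[AppliedVariant, ...]:
        return tuple(v for v in self.applied_variants if v.is_nonsynonymous)

    def descriptor(self) -> str:
        fields = [
            f"tid={self.transcript_id}",
            f"tis={self.tis_genomic_pos}",
            f"codon={self.codon}",
            f"cat={self.category}",
        ]
        if self.atis_status:
            fields.append(f"status={self.atis_status}")
        nsv = self.nonsynonymous_variants
        if nsv:
            fields.append(
                "snv="
                + ";".join(
                    f"{v.chromosome}:{v.position}{v.ref}>{v.alt}"
                    f"({v.ref_aa}{v.codon_index + 1}{v.alt_aa})"
                    for v in nsv
                )
            )
        if self.canonical_id:
            fields.append(f"canonical={self.canonical_id}")
        if self.truncated:
            fields.append("partial=true")
        return "|".join(fields)


def _translate_codon(codon: str) -> str | None:
    """Amino acid for a codon; None for stop; X for unresolvable (N-containing)."""
    if codon in _STOP_CODONS:
        return None
    return _CODON_TO_AA.get(codon, "X")


def _translate_orf(seq: str, start: int) -> tuple[str, bool, bool]:
    """Translate from ``start`` to the first in-frame stop.

    Returns (protein, truncated, ambiguous).  The initiator codon always
    yields M (near-cognate recoding).
    """
    aas: list[str] = []
    truncated = True
    ambiguous = False
    for i in range(start, len(seq) - 2, 3):
        codon = seq[i : i + 3]
        aa = _translate_codon(codon)
        if aa is None:
            truncated = False
            break
        if aa == "X":
            ambiguous = True
        aas.append(aa)
    if aas:
        aas[0] = "M"
    return "".join(aas), truncated, ambiguous


def _apply_variants_to_sequence(
    t: TranscriptModel, seq: str, variants: Iterable[VariantRecord]
) -> tuple[str, list[tuple[VariantRecord, int]]]:
    """Substitute variant alleles into the transcript sequence.

    Returns the edited sequence and the list of (variant, transcript position)
    actually applied (variants outside the exons are ignored)."""
    chars = list(seq)
    applied: list[tuple[VariantRecord, int]] = []
    for v in sorted(variants, key=lambda v: v.key):
        if v.chromosome != t.chromosome:
            continue
        tpos = t.genomic_to_tpos(v.position)
        if tpos is None:
            continue
        ref_t = v.ref if t.strand == "+" else reverse_complement(v.ref)
        alt_t = v.alt if t.strand == "+" else reverse_complement(v.alt)
        if chars[tpos] != ref_t:
            raise ValueError(
                f"variant {v.chromosome}:{v.position} {v.ref}>{v.alt}: REF does "
                f"not match transcript {t.transcript_id} at tpos {tpos}"
            )
        chars[tpos] = alt_t
        applied.append((v, tpos))
    return "".join(chars), applied


def translate_from_tis(
    t: TranscriptModel,
    tis: TISCall,
    genome: GenomeSequence,
    variants: Iterable[VariantRecord] = (),
    min_protein_length: int = MIN_PROTEIN_LENGTH,
    sequence: str | None = None,
) -> list[ProteoformRecord]:
    """Translate one retained TIS into proteoform record(s).

    Emits the reference proteoform and, when variants overlapping the
    transcript exist, one additional proteoform with all retained variants
    applied.  Products shorter than ``min_protein_length`` amino acids (or
    identical to the reference product) are dropped.
    """
    c = tis.candidate
    ref_seq = sequence if sequence is not None else transcript_sequence(t, genome)
    start = c.tpos

    records: list[ProteoformRecord] = []
    ref_prot, ref_trunc, ref_amb = _translate_orf(ref_seq, start)
    if len(ref_prot) >= min_protein_length:
        records.append(
            ProteoformRecord(
                transcript_id=t.transcript_id,
                tis_genomic_pos=c.genomic_pos,
                tis_tpos=start,
                codon=c.codon,
                category=c.category,
                atis_status=tis.status,
                sequence=ref_prot,
                truncated=ref_trunc,
                ambiguous=ref_amb,
            )
        )
    else:
        logger.debug(
            "%s TIS@%d: reference product of %d aa below minimum, dropped",
            t.transcript_id, c.genomic_pos, len(ref_prot),
        )

    relevant = [
        v
        for v in variants
        if v.chromosome == t.chromosome
        and t.genomic_to_tpos(v.position) is not None
        and (not v.transcript_ids or t.transcript_id in v.transcript_ids)
    ]
    if relevant:
        var_seq, applied = _apply_variants_to_sequence(t, ref_seq, relevant)
        var_prot, var_trunc, var_amb = _translate_orf(var_seq, start)
        if var_prot != ref_prot and len(var_prot) >= min_protein_length:
            annotated: list[AppliedVariant] = []
            for v, tpos in applied:
                if start <= tpos:
                    k = (tpos - start) // 3
                    cs = start + 3 * k
                    ref_codon = ref_seq[cs : cs + 3]
                    # effect of this variant alone within the ORF context
                    alone = list(ref_codon)
                    alone[tpos - cs] = (
                        v.alt if t.strand == "+" else reverse_complement(v.alt)
                    )
                    ref_aa = "M" if k == 0 else (_translate_codon(ref_codon) or "*")
                    alt_aa = "M" if k == 0 else (_translate_codon("".join(alone)) or "*")
                    in_orf = k < len(var_prot) or (k == len(var_prot) and not var_trunc)
                    annotated.append(
                        AppliedVariant(
                            v.chromosome, v.position, v.ref, v.alt,
                            codon_index=k if in_orf else None,
                            ref_aa=ref_aa if in_orf else None,
                            alt_aa=alt_aa if in_orf else None,
                        )
                    )
                else:
                    annotated.append(
                        AppliedVariant(
                            v.chromosome, v.position, v.ref, v.alt,
                            codon_index=None, ref_aa=None, alt_aa=None,
                        )
                    )
            records.append(
                ProteoformRecord(
                    transcript_id=t.transcript_id,
                    tis_genomic_pos=c.genomic_pos,
                    tis_tpos=start,
                    codon=c.codon,
                    category=c.category,
                    atis_status=tis.status,
                    sequence=var_prot,
                    applied_variants=tuple(annotated),
                    truncated=var_trunc,
                    ambiguous=var_amb,
                )
            )
    return records


def deduplicate(
    records: list[ProteoformRecord], seed: int = 1
) -> list[ProteoformRecord]:
    """Annotation-ranked redundancy elimination plus subsequence removal.

    Identical sequences collapse to the highest-ranked record (variant
    information breaks rank ties; remaining ties are broken by a seeded random
    draw over the lexicographically sorted contenders, so the result is
    independent of input order).  Then any sequence contained in a longer
    surviving sequence is removed (longest first).
    """
    rng = random.Random(seed)
    by_seq: dict[str, list[ProteoformRecord]] = {}
    for r in records:
        by_seq.setdefault(r.sequence, []).append(r)

    survivors: list[ProteoformRecord] = []
    for seq in sorted(by_seq):
        group = by_seq[seq]
        best_rank = min(ANNOTATION_RANK[r.category] for r in group)
        group = [r for r in group if ANNOTATION_RANK[r.category] == best_rank]
        if any(r.has_variants for r in group):
            group = [r for r in group if r.has_variants]
        group.sort(key=lambda r: (r.transcript_id, r.tis_genomic_pos))
        survivors.append(group[0] if len(group) == 1 else rng.choice(group))

    # subsequence elimination, longest first
    survivors.sort(key=lambda r: (-len(r.sequence), r.sequence))
    kept: list[ProteoformRecord] = []
    for r in survivors:
        if any(r.sequence in k.sequence for k in kept):
            continue
        kept.append(r)
    kept.sort(key=lambda r: (r.transcript_id, r.tis_genomic_pos, r.sequence))
    return kept


def read_id_map(path: str | Path) -> dict[str, str]:
    """Two-column TSV: transcript_id <tab> canonical_id."""
    out: dict[str, str] = {}
    with open(path) as fh:
        for line in fh:
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            tid, canonical = line.split("\t")[:2]
            out[tid] = canonical
    return out


def read_blast_tabular(path: str | Path) -> dict[str, str]:
    """BLAST outfmt-6 import hook: best hit (by bitscore) per query id."""
    best: dict[str, tuple[float, str]] = {}
    with open(path) as fh:
        for line in fh:
            parts = line.rstrip("\n").split("\t")
            if len(parts) < 12:
                continue
            q, s, bits = parts[0], parts[1], float(parts[11])
            if q not in best or bits > best[q][0]:
                best[q] = (bits, s)
    return {q: s for q, (_, s) in best.items()}


def map_canonical(
    records: list[ProteoformRecord],
    id_map: Mapping[str, str] | None = None,
    canonical_seqs: Mapping[str, str] | None = None,
    blast_hits: Mapping[str, str] | None = None,
) -> list[ProteoformRecord]:
    """Assign canonical protein IDs.

    aTIS and 5'UTR records map by transcript ID through ``id_map``; the other
    categories (CDS, 3'UTR, no_translation) map by exact/containment matching
    against ``canonical_seqs`` (sequence-based stand-in for an alignment
    search); ``blast_hits`` (query = transcript_id) overrides sequence
    matching when supplied.  Unmatched records keep an empty canonical_id.
    """
    out: list[ProteoformRecord] = []
    sorted_canonical = (
        sorted(canonical_seqs.items()) if canonical_seqs is not None else []
    )
    for r in records:
        canonical: str | None = None
        if r.category in (CAT_ATIS, CAT_5UTR):
            if id_map is not None:
                canonical = id_map.get(r.transcript_id)
        else:
            if blast_hits is not None and r.transcript_id in blast_hits:
                canonical = blast_hits[r.transcript_id]
            elif sorted_canonical:
                for cid, cseq in sorted_canonical:
                    if r.sequence in cseq:
                        canonical = cid
                        break
        out.append(replace(r, canonical_id=canonical))
    return out


def read_canonical_fasta(path: str | Path) -> dict[str, str]:
    return {rec.id: str(rec.seq).upper() for rec in SeqIO.parse(str(path), "fasta")}


def write_fasta(
    records: list[ProteoformRecord],
    out: str | Path,
    canonical_seqs: Mapping[str, str] | None = None,
    include_canonical_db: bool = False,
) -> None:
    """Emit the final FASTA search space.

    Headers read ``rf|<transcript_id>:<tis>|<descriptor>``.  With
    ``include_canonical_db``, canonical entries not matched by any record are
    appended, yielding the combined search space.
    """
    seq_records = [
        SeqRecord(
            Seq(r.sequence),
            id=f"rf|{r.transcript_id}:{r.tis_genomic_pos}",
            description=r.descriptor(),
        )
        for r in records
    ]
    if include_canonical_db:
        if canonical_seqs is None:
            raise ValueError("combined mode requires a canonical database")
        matched = {r.canonical_id for r in records if r.canonical_id}
        for cid in sorted(canonical_seqs):
            if cid not in matched:
                seq_records.append(
                    SeqRecord(Seq(canonical_seqs[cid]), id=cid, description="canonical")
                )
    SeqIO.write(seq_records, str(out), "fasta")


def read_proteoform_fasta(path: str | Path) -> list[tuple[str, dict[str, str], str]]:
    """Parse a FASTA written by :func:`write_fasta` back into
    (id, descriptor fields, sequence) tuples."""
    out = []
    for rec in SeqIO.parse(str(path), "fasta"):
        desc = rec.description[len(rec.id) :].strip()
        fields: dict[str, str] = {}
        if desc and desc != "canonical":
            for item in desc.split("|"):
                if "=" in item:
                    k, v = item.split("=", 1)
                    fields[k] = v
        out.append((rec.id, fields, str(rec.seq)))
    return out


def assemble(
    annotation_transcripts: Mapping[str, TranscriptModel],
    genome: GenomeSequence,
    tis_calls: Iterable[TISCall],
    variants: Iterable[VariantRecord] = (),
    seed: int = 1,
    min_protein_length: int = MIN_PROTEIN_LENGTH,
    id_map: Mapping[str, str] | None = None,
    canonical_seqs: Mapping[str, str] | None = None,
    blast_hits: Mapping[str, str] | None = None,
) -> list[ProteoformRecord]:
    """Translate all retained TIS, deduplicate and map to the canonical DB."""
    variants = list(variants)
    records: list[ProteoformRecord] = []
    seq_cache: dict[str, str] = {}
    for call in tis_calls:
        if not call.retained:
            continue
        tid = call.candidate.transcript_id
        t = annotation_transcripts[tid]
        if tid not in seq_cache:
            seq_cache[tid] = transcript_sequence(t, genome)
        records.extend(
            translate_from_tis(
                t, call, genome,
                variants=variants,
                min_protein_length=min_protein_length,
                sequence=seq_cache[tid],
            )
        )
    records = deduplicate(records, seed=seed)
    if id_map is not None or canonical_seqs is not None or blast_hits is not None:
        records = map_canonical(
            records, id_map=id_map, canonical_seqs=canonical_seqs, blast_hits=blast_hits
        )
    return records
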