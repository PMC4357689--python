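"""Synthetic fixture generation: toy genomes, annotation, reads and variants
with known ground truth.

The generator emulates the features of ribosome-profiling data that the
pipeline's rules act on: elongating-condition coverage roughly uniform over
the counted CDS with 3x pileups in the 15-nt start/stop windows; initiating
condition coverage as sharp peaks (spread over +/-1 nt) at planted AUG or
near-cognate start codons with a small noise floor; planted single-nucleotide
variants carried by half the overlapping reads.  Planted peaks are sized to at
least twice every category's minimum-count threshold so that rule-exactness is
testable.  All outputs are deterministic per seed and byte-stable.
"""

from __future__ import annotations

import random
from dataclasses import dataclass, field
from pathlib import Path

import pysam

from .annotation import (
    GenomeSequence,
    TranscriptModel,
    reverse_complement,
    transcript_sequence,
)
from .ingest import psite_offset

_BASES = "ACGT"
_SENSE_CODONS = [
    a + b + c
    for a in _BASES
    for b in _BASES
    for c in _BASES
    if a + b + c not in {"TAA", "TAG", "TGA"}
]
_STOPS = ["TAA", "TAG", "TGA"]

# read-length distribution over the relevant RPF range (mode at 28 nt)
READ_LENGTHS = [26, 27, 28, 29, 30, 31, 32, 33, 34]
READ_LENGTH_WEIGHTS = [5, 10, 35, 20, 10, 10, 5, 3, 2]

CHX_DEPTH = 300   # elongating reads per translated transcript
LTM_DEPTH = 150   # initiating reads per transcript carrying planted TIS
LTM_NOISE_FRACTION = 0.08
START_STOP_PILEUP = 3  # weight multiplier inside the 15-nt windows


@dataclass(frozen=True)
class PlantedTIS:
    transcript_id: str
    tpos: int
    genomic_pos: int
    codon: str
    category: str


@dataclass(frozen=True)
class PlantedVariant:
    chromosome: str
    position: int
    ref: str
    alt: str
    transcript_id: str
    in_dbsnp: bool
    in_caller: bool


@dataclass
class FixtureTruth:
    genome: GenomeSequence
    transcripts: dict[str, TranscriptModel]
    translated: dict[str, bool]
    planted_tis: list[PlantedTIS] = field(default_factory=list)
    variants: list[PlantedVariant] = field(default_factory=list)
    genome_path: Path | None = None
    gtf_path: Path | None = None

    def translated_ids(self) -> set[str]:
        return {tid for tid, flag in self.translated.items() if flag}

    def write_tsv(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            fh.write("record\tfields\n")
            for tid in sorted(self.transcripts):
                fh.write(f"transcript\t{tid},translated={self.translated[tid]}\n")
            for p in self.planted_tis:
                fh.write(
                    f"tis\t{p.transcript_id},tpos={p.tpos},gpos={p.genomic_pos},"
                    f"codon={p.codon},category={p.category}\n"
                )
            for v in self.variants:
                fh.write(
                    f"variant\t{v.chromosome}:{v.position},{v.ref}>{v.alt},"
                    f"tid={v.transcript_id},dbsnp={v.in_dbsnp},caller={v.in_caller}\n"
                )


def _random_seq(rng: random.Random, n: int) -> str:
    return "".join(rng.choice(_BASES) for _ in range(n))


def _choose_cuts(
    rng: random.Random, length: int, n_cuts: int, forbidden: set[int]
) -> list[int]:
    """Splice points (spliced coordinates) avoiding forbidden zones, min gap 10."""
    if n_cuts == 0:
        return []
    candidates = [
        i for i in range(15, length - 15) if i not in forbidden
    ]
    if len(candidates) < n_cuts:
        return []
    for _ in range(50):
        cuts = sorted(rng.sample(candidates, n_cuts))
        ok = all(b - a >= 10 for a, b in zip(cuts, cuts[1:]))
        if ok:
            return cuts
    return []  # fall back to a single exon


def make_genome(
    n_genes: int, seed: int, out_dir: str | Path
) -> FixtureTruth:
    """Generate a toy genome (FASTA) and Ensembl-dialect annotation (GTF).

    Genes alternate between two chromosomes and both strands.  Most genes are
    protein-coding (CDS >= 81 nt, ATG...stop, 36-60 nt UTRs, 1-4 exons) with a
    near-cognate CTG planted in the 5'UTR; every fourth gene is a single- or
    two-exon lincRNA with a planted ATG (a no_translation TIS).  Every third
    gene index (>=2) is left untranslated (it receives no reads downstream).
    Some protein-coding genes carry a second isoform with a 5'-truncated first
    exon (same CDS), exercising redundancy elimination.  Deterministic per
    seed; outputs are byte-stable.
    """
    if n_genes < 1:
        raise ValueError("n_genes must be >= 1")
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    rng = random.Random(seed * 10 + 1)

    chrom_seqs: dict[str, list[str]] = {"chr1": [], "chr2": []}
    chrom_cursor = {"chr1": 0, "chr2": 0}
    transcripts: dict[str, TranscriptModel] = {}
    translated: dict[str, bool] = {}
    planted: list[PlantedTIS] = []
    gtf_rows: list[tuple] = []

    for gi in range(n_genes):
        gene_id = f"g{gi + 1}"
        chrom = "chr1" if gi % 2 == 0 else "chr2"
        strand = "+" if (gi // 2) % 2 == 0 else "-"
        is_linc = gi % 4 == 3
        is_translated = not (gi >= 2 and gi % 3 == 2)

        if is_linc:
            biotype = "lincRNA"
            length = rng.randint(200, 320)
            seq = list(_random_seq(rng, length))
            tis_pos = rng.randint(20, 40)
            seq[tis_pos : tis_pos + 3] = "ATG"
            # guarantee a downstream in-frame stop well inside the transcript
            stop_at = tis_pos + 3 * rng.randint(12, 25)
            seq[stop_at : stop_at + 3] = rng.choice(_STOPS)
            spliced = "".join(seq)
            cds_lo = cds_hi = None
            forbidden = set(range(tis_pos - 8, tis_pos + 11))
            n_exons = rng.randint(1, 2)
            planted_specs = [(tis_pos, "ATG", "no_translation")]
            is_translated = False
        else:
            biotype = "protein_coding"
            utr5_len = rng.randint(36, 60)
            utr3_len = rng.randint(30, 60)
            n_codons = rng.randint(25, 60)
            utr5 = list(_random_seq(rng, utr5_len))
            nc_pos = rng.randint(16, utr5_len - 20)
            utr5[nc_pos : nc_pos + 3] = "CTG"
            cds = "ATG" + "".join(
                rng.choice(_SENSE_CODONS) for _ in range(n_codons)
            ) + rng.choice(_STOPS)
            spliced = "".join(utr5) + cds + _random_seq(rng, utr3_len)
            cds_lo, cds_hi = utr5_len, utr5_len + len(cds) - 1  # spliced coords
            forbidden = set(range(cds_lo - 8, cds_lo + 11)) | set(
                range(cds_hi - 10, cds_hi + 9)
            ) | set(range(nc_pos - 8, nc_pos + 11))
            n_exons = rng.randint(1, 4)
            # untranslated genes carry no planted TIS and receive no reads
            planted_specs = [(cds_lo, "ATG", "aTIS")] if is_translated else []
            if is_translated:
                planted_specs.append((nc_pos, "CTG", "5UTR"))
                # downstream in-frame-agnostic ATG inside the CDS (dTIS)
                dtis = spliced.find("ATG", cds_lo + 30, cds_hi - 20)
                if dtis != -1:
                    planted_specs.append((dtis, "ATG", "CDS"))
                    forbidden |= set(range(dtis - 8, dtis + 11))

        cuts = _choose_cuts(rng, len(spliced), n_exons - 1, forbidden)
        pieces = []
        prev = 0
        for cut in cuts + [len(spliced)]:
            pieces.append((prev, cut))  # spliced half-open intervals
            prev = cut

        introns = [_random_seq(rng, rng.randint(25, 60)) for _ in range(len(pieces) - 1)]
        premrna_parts = []
        exon_spliced: list[tuple[int, int]] = []   # within pre-mRNA, half-open
        cursor = 0
        for i, (s, e) in enumerate(pieces):
            premrna_parts.append(spliced[s:e])
            exon_spliced.append((cursor, cursor + (e - s)))
            cursor += e - s
            if i < len(introns):
                premrna_parts.append(introns[i])
                cursor += len(introns[i])
        premrna = "".join(premrna_parts)

        gene_offset = chrom_cursor[chrom] + rng.randint(60, 120)
        locus = premrna if strand == "+" else reverse_complement(premrna)
        chrom_seqs[chrom].append(_random_seq(rng, gene_offset - chrom_cursor[chrom]))
        gene_start = gene_offset + 1  # 1-based genomic start of the locus
        chrom_seqs[chrom].append(locus)
        chrom_cursor[chrom] = gene_offset + len(premrna)

        lp = len(premrna)

        def to_genomic(ps: int, pe: int) -> tuple[int, int]:
            """Pre-mRNA half-open [ps, pe) -> genomic 1-based inclusive interval."""
            if strand == "+":
                return gene_start + ps, gene_start + pe - 1
            return gene_start + (lp - pe), gene_start + (lp - 1 - ps)

        exons = [to_genomic(ps, pe) for ps, pe in exon_spliced]

        # pre-mRNA coordinate of each spliced coordinate
        spliced_to_pre: list[int] = []
        for (ps, pe) in exon_spliced:
            spliced_to_pre.extend(range(ps, pe))

        def spliced_to_genomic(sc: int) -> int:
            pc = spliced_to_pre[sc]
            return gene_start + pc if strand == "+" else gene_start + (lp - 1 - pc)

        tid = f"t{gi + 1}"
        cds_start = cds_end = None
        if cds_lo is not None:
            cds_start = spliced_to_genomic(cds_lo)
            cds_end = spliced_to_genomic(cds_hi)
        model = TranscriptModel(
            transcript_id=tid,
            gene_id=gene_id,
            chromosome=chrom,
            strand=strand,
            biotype=biotype,
            exons=exons,
            cds_start=cds_start,
            cds_end=cds_end,
        )
        transcripts[tid] = model
        translated[tid] = is_translated
        for (sc, codon, category) in planted_specs:
            planted.append(
                PlantedTIS(tid, sc, spliced_to_genomic(sc), codon, category)
            )
        gtf_rows.append((model, biotype, cds_lo, cds_hi, spliced_to_genomic))

        # occasional second isoform: 5'-truncated first exon, same CDS
        if biotype == "protein_coding" and rng.random() < 0.4 and len(spliced) > 0:
            trim = rng.randint(5, 12)
            first = model.exons[0]
            if first[1] - first[0] + 1 > trim + 20:
                if strand == "+":
                    iso_exons = [(first[0] + trim, first[1])] + list(model.exons[1:])
                else:
                    iso_exons = [(first[0], first[1] - trim)] + list(model.exons[1:])
                iso_id = f"t{gi + 1}b"
                iso = TranscriptModel(
                    transcript_id=iso_id,
                    gene_id=gene_id,
                    chromosome=chrom,
                    strand=strand,
                    biotype=biotype,
                    exons=iso_exons,
                    cds_start=cds_start,
                    cds_end=cds_end,
                )
                transcripts[iso_id] = iso
                # shares the covered CDS with the primary isoform
                translated[iso_id] = is_translated
                if cds_lo is not None and is_translated:
                    iso_atis = iso.genomic_to_tpos(cds_start)
                    planted.append(
                        PlantedTIS(iso_id, iso_atis, cds_start, "ATG", "aTIS")
                    )
                gtf_rows.append((iso, biotype, None, None, None))

    # pad chromosome tails
    for chrom in chrom_seqs:
        chrom_seqs[chrom].append(_random_seq(rng, 80))

    genome = GenomeSequence(
        {chrom: "".join(parts) for chrom, parts in chrom_seqs.items()}
    )

    genome_path = out_dir / "genome.fa"
    with open(genome_path, "w") as fh:
        for chrom in sorted(genome.chromosomes()):
            fh.write(f">{chrom}\n")
            seq = genome.fetch(chrom, 1, genome.length(chrom))
            for i in range(0, len(seq), 60):
                fh.write(seq[i : i + 60] + "\n")

    gtf_path = out_dir / "annotation.gtf"
    _write_gtf(gtf_path, [row[0] for row in gtf_rows])

    truth = FixtureTruth(
        genome=genome,
        transcripts=transcripts,
        translated=translated,
        planted_tis=planted,
        genome_path=genome_path,
        gtf_path=gtf_path,
    )
    truth.write_tsv(out_dir / "truth.tsv")
    return truth


def _runs(positions: list[int]) -> list[tuple[int, int]]:
    """Group sorted genomic positions into maximal consecutive runs."""
    positions = sorted(positions)
    runs: list[tuple[int, int]] = []
    start = prev = positions[0]
    for p in positions[1:]:
        if p == prev + 1:
            prev = p
            continue
        runs.append((start, prev))
        start = prev = p
    runs.append((start, prev))
    return runs


def _write_gtf(path: Path, models: list[TranscriptModel]) -> None:
    lines: list[str] = []
    for t in sorted(models, key=lambda m: (m.chromosome, m.span[0], m.transcript_id)):
        attrs = (
            f'gene_id "{t.gene_id}"; transcript_id "{t.transcript_id}"; '
            f'gene_biotype "{t.biotype}"; transcript_biotype "{t.biotype}";'
        )
        lo, hi = t.span

        def row(ftype: str, start: int, end: int, frame: str = ".") -> str:
            return (
                f"{t.chromosome}\triboforge\t{ftype}\t{start}\t{end}\t.\t"
                f"{t.strand}\t{frame}\t{attrs}"
            )

        lines.append(row("transcript", lo, hi))
        for i, (s, e) in enumerate(t.exons, start=1):
            lines.append(row("exon", s, e) + f' exon_number "{i}";')
        if t.is_coding:
            cds_positions = list(t.cds_positions())
            coding = cds_positions[:-3]   # Ensembl CDS excludes the stop codon
            stop = cds_positions[-3:]
            cum = 0
            # frames per CDS block in transcript order
            blocks_to = _runs(coding)
            if t.strand == "-":
                blocks_to = blocks_to[::-1]
            for (s, e) in blocks_to:
                frame = (3 - cum % 3) % 3
                lines.append(row("CDS", s, e, str(frame)))
                cum += e - s + 1
            ss, se = min(stop), max(stop)
            lines.append(row("start_codon", min(cds_positions[:3]), max(cds_positions[:3]), "0"))
            lines.append(row("stop_codon", ss, se, "0"))
    with open(path, "w") as fh:
        fh.write("\n".join(lines) + "\n")


# ---------------------------------------------------------------------------
# read simulation
# ---------------------------------------------------------------------------


def _variant_sequence(
    t: TranscriptModel, seq: str, variants: list[PlantedVariant]
) -> str:
    chars = list(seq)
    for v in variants:
        if v.chromosome != t.chromosome:
            continue
        tpos = t.genomic_to_tpos(v.position)
        if tpos is None:
            continue
        chars[tpos] = v.alt if t.strand == "+" else reverse_complement(v.alt)
    return "".join(chars)


def _sam_header(genome: GenomeSequence) -> pysam.AlignmentHeader:
    return pysam.AlignmentHeader.from_dict(
        {
            "HD": {"VN": "1.6", "SO": "unsorted"},
            "SQ": [
                {"SN": chrom, "LN": genome.length(chrom)}
                for chrom in sorted(genome.chromosomes())
            ],
        }
    )


def _make_read(
    header: pysam.AlignmentHeader,
    name: str,
    t: TranscriptModel,
    t5: int,
    length: int,
    fragment: str,
) -> pysam.AlignedSegment:
    blocks = t.blocks_for_tinterval(t5, length)
    a = pysam.AlignedSegment(header)
    a.query_name = name
    a.reference_name = t.chromosome
    a.reference_start = blocks[0][0] - 1
    a.mapping_quality = 255
    cigar = []
    prev_end = None
    for (s, e) in blocks:
        if prev_end is not None:
            cigar.append((3, s - prev_end - 1))  # N
        cigar.append((0, e - s + 1))  # M
        prev_end = e
    a.cigartuples = cigar
    if t.strand == "-":
        a.flag = 16
        a.query_sequence = reverse_complement(fragment)
    else:
        a.flag = 0
        a.query_sequence = fragment
    a.query_qualities = pysam.qualitystring_to_array("I" * length)
    a.set_tag("NH", 1)
    return a


def simulate_reads(
    truth: FixtureTruth,
    condition: str,
    out_sam: str | Path,
    seed: int,
    depth: int | None = None,
    apply_variants: bool = True,
) -> Path:
    """Simulate RPF alignments for one condition and write a SAM file.

    ``elongating``: per translated transcript, ``depth`` reads whose P-sites
    fall uniformly over the counted CDS with 3x weight in the 15-nt start/stop
    windows.  ``initiating``: per transcript with planted TIS, ~92% of reads
    place P-sites within +/-1 nt of a planted codon's first position, the rest
    is uniform noise.  Reads overlapping a planted variant carry the alternate
    allele with probability 0.5.  Untranslated protein-coding transcripts
    receive no reads.  Deterministic per seed.
    """
    if condition not in {"elongating", "initiating"}:
        raise ValueError(f"unknown condition {condition!r}")
    rng = random.Random(seed * 10 + (2 if condition == "elongating" else 3))
    if depth is None:
        depth = CHX_DEPTH if condition == "elongating" else LTM_DEPTH

    header = _sam_header(truth.genome)
    out_sam = Path(out_sam)
    reads: list[pysam.AlignedSegment] = []

    tis_by_tid: dict[str, list[PlantedTIS]] = {}
    for p in truth.planted_tis:
        tis_by_tid.setdefault(p.transcript_id, []).append(p)

    for tid in sorted(truth.transcripts):
        t = truth.transcripts[tid]
        seq = transcript_sequence(t, truth.genome)
        var_here = [
            v for v in truth.variants if t.genomic_to_tpos(v.position) is not None
        ] if apply_variants else []
        var_seq = _variant_sequence(t, seq, var_here) if var_here else seq

        targets: list[int] = []
        if condition == "elongating":
            if not truth.translated.get(tid, False):
                continue
            if t.is_coding:
                ts, te = t.cds_tpos_bounds
                weighted: list[int] = []
                for j in range(ts, te + 1):
                    w = (
                        START_STOP_PILEUP
                        if j < ts + 15 or j > te - 15
                        else 1
                    )
                    weighted.extend([j] * w)
            else:
                weighted = list(range(t.length))
            targets = [rng.choice(weighted) for _ in range(depth)]
        else:
            planted_here = tis_by_tid.get(tid, [])
            if not planted_here:
                continue
            n_noise = int(round(depth * LTM_NOISE_FRACTION))
            n_signal = depth - n_noise
            for k in range(n_signal):
                p = planted_here[k % len(planted_here)]
                targets.append(p.tpos + rng.choice([-1, 0, 1]))
            for _ in range(n_noise):
                targets.append(rng.randint(0, t.length - 1))

        for i, target in enumerate(targets):
            for _ in range(30):
                length = rng.choices(READ_LENGTHS, weights=READ_LENGTH_WEIGHTS)[0]
                offset = psite_offset(length)
                t5 = target - offset
                if 0 <= t5 and t5 + length <= t.length:
                    break
            else:
                continue  # target too close to an edge for any length
            base_seq = var_seq if (var_here and rng.random() < 0.5) else seq
            fragment = base_seq[t5 : t5 + length]
            reads.append(
                _make_read(header, f"{condition[:3]}_{tid}_{i}", t, t5, length, fragment)
            )

    reads.sort(key=lambda r: (r.reference_name, r.reference_start, r.query_name))
    with pysam.AlignmentFile(str(out_sam), "w", header=header) as fh:
        for r in reads:
            fh.write(r)
    return out_sam


# ---------------------------------------------------------------------------
# variant planting
# ---------------------------------------------------------------------------


def _write_vcf(path: Path, genome: GenomeSequence, rows: list[tuple[str, int, str, str]]) -> None:
    with open(path, "w") as fh:
        fh.write("##fileformat=VCFv4.2\n")
        for chrom in sorted(genome.chromosomes()):
            fh.write(f"##contig=<ID={chrom},length={genome.length(chrom)}>\n")
        fh.write("#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\n")
        for chrom, pos, ref, alt in sorted(rows):
            fh.write(f"{chrom}\t{pos}\t.\t{ref}\t{alt}\t.\tPASS\t.\n")


def plant_variants(
    truth: FixtureTruth,
    n: int,
    seed: int,
    out_dir: str | Path,
) -> tuple[Path, Path]:
    """Plant ``n`` exonic SNVs and write sample (caller) and dbSNP VCFs.

    When ``n >= 6`` the first six variants are concentrated on a single
    translated coding transcript and appear in dbSNP only, so downstream the
    >5-per-transcript cap is exercised.  Remaining variants go to other coding
    transcripts: each lands in dbSNP with probability 0.7 and in the caller VCF
    with probability 0.5 (forced into the caller VCF when in neither).
    Updates ``truth.variants`` in place; reads simulated afterwards carry the
    alternate alleles.
    """
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    rng = random.Random(seed * 10 + 4)

    coding = [
        t for tid, t in sorted(truth.transcripts.items())
        if t.is_coding and truth.translated.get(tid, False)
        and not tid.endswith("b")
    ]
    planted: list[PlantedVariant] = []
    used_positions: set[tuple[str, int]] = set()

    def plant_on(t: TranscriptModel, in_dbsnp: bool, in_caller: bool) -> bool:
        ts, te = t.cds_tpos_bounds
        for _ in range(60):
            tpos = rng.randint(ts + 16, te - 19)
            gpos = t.tpos_to_genomic(tpos)
            if (t.chromosome, gpos) in used_positions:
                continue
            ref = truth.genome.base(t.chromosome, gpos)
            alt = rng.choice([b for b in _BASES if b != ref])
            used_positions.add((t.chromosome, gpos))
            planted.append(
                PlantedVariant(
                    t.chromosome, gpos, ref, alt, t.transcript_id, in_dbsnp, in_caller
                )
            )
            return True
        return False

    remaining = n
    if n >= 6 and coding:
        cap_target = max(
            coding,
            key=lambda t: t.cds_tpos_bounds[1] - t.cds_tpos_bounds[0],
        )
        for _ in range(6):
            if plant_on(cap_target, in_dbsnp=True, in_caller=False):
                remaining -= 1
        others = [t for t in coding if t.transcript_id != cap_target.transcript_id]
    else:
        others = coding

    for k in range(remaining):
        if not others:
            break
        t = others[k % len(others)]
        in_dbsnp = rng.random() < 0.7
        in_caller = rng.random() < 0.5
        if not in_dbsnp and not in_caller:
            in_caller = True
        plant_on(t, in_dbsnp=in_dbsnp, in_caller=in_caller)

    truth.variants = planted
    sample_path = out_dir / "sample.vcf"
    dbsnp_path = out_dir / "dbsnp.vcf"
    _write_vcf(
        sample_path,
        truth.genome,
        [(v.chromosome, v.position, v.ref, v.alt) for v in planted if v.in_caller],
    )
    _write_vcf(
        dbsnp_path,
        truth.genome,
        [(v.chromosome, v.position, v.ref, v.alt) for v in planted if v.in_dbsnp],
    )
    return sample_path, dbsnp_path


@dataclass
class FixtureBundle:
    truth: FixtureTruth
    genome_path: Path
    gtf_path: Path
    chx_sam: Path
    ltm_sam: Path
    sample_vcf: Path
    dbsnp_vcf: Path


def make_bundle(
    out_dir: str | Path,
    n_genes: int = 8,
    seed: int = 1,
    n_variants: int = 9,
    chx_depth: int = CHX_DEPTH,
    ltm_depth: int = LTM_DEPTH,
) -> FixtureBundle:
    """Generate a complete fixture bundle: genome, GTF, variant VCFs and
    SAM files for both conditions, with ground truth."""
    out_dir = Path(out_dir)
    truth = make_genome(n_genes, seed, out_dir)
    sample_vcf, dbsnp_vcf = plant_variants(truth, n_variants, seed, out_dir)
    chx = simulate_reads(
        truth, "elongating", out_dir / "chx.sam", seed, depth=chx_depth
    )
    ltm = simulate_reads(
        truth, "initiating", out_dir / "ltm.sam", seed, depth=ltm_depth
    )
    return FixtureBundle(
        truth=truth,
        genome_path=truth.genome_path,
        gtf_path=truth.gtf_path,
        chx_sam=chx,
        ltm_sam=ltm,
        sample_vcf=sample_vcf,
        dbsnp_vcf=dbsnp_vcf,
    )
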