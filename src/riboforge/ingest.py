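"""P-site profiling of aligned ribosome-protected fragments (RPFs).

Alignments are filtered to the relevant RPF length range (26-34 nt after
clipping), optionally filtered on mapping multiplicity (NH tag), and each
retained alignment is reduced to a single ribosomal P-site position using the
length-dependent 5' offset: +12 for fragments <= 30 nt, +13 for 31-33 nt and
+14 for >= 34 nt.  The offset is walked along aligned reference bases only, so
a P-site never falls inside an intron of a spliced alignment.
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Iterator

import pysam

MIN_RPF_LENGTH = 26
MAX_RPF_LENGTH = 34
MULTIMAP_CAP = 15

ELONGATING = "elongating"
INITIATING = "initiating"

UNIQUE_ONLY = "unique_only"
MULTIMAP_LEQ_15 = "multimap_leq_15"


class ReadLengthError(ValueError):
    """Fragment length outside the relevant RPF range (26-34 nt)."""


def psite_offset(read_length: int) -> int:
    """5'-end offset (nt) to the ribosomal P-site for an RPF of given length.

    Raises :class:`ReadLengthError` for lengths outside 26-34 nt; such reads
    are not relevant RPFs and are discarded (and counted) upstream.
    """
    if not MIN_RPF_LENGTH <= read_length <= MAX_RPF_LENGTH:
        raise ReadLengthError(
            f"fragment length {read_length} outside {MIN_RPF_LENGTH}-{MAX_RPF_LENGTH} nt"
        )
    if read_length <= 30:
        return 12
    if read_length <= 33:
        return 13
    return 14


@dataclass
class PsiteProfile:
    """Per-(chromosome, strand) map from genomic position (1-based) to P-site count."""

    condition: str
    multimap_policy: str
    counts: dict[tuple[str, str], Counter] = field(default_factory=dict)
    total_retained: int = 0
    total_discarded_by_length: int = 0
    total_discarded_by_multimap: int = 0
    total_unmapped: int = 0

    def add(self, chrom: str, strand: str, pos: int, n: int = 1) -> None:
        self.counts.setdefault((chrom, strand), Counter())[pos] += n
        self.total_retained += n

    def count_at(self, chrom: str, strand: str, pos: int) -> int:
        c = self.counts.get((chrom, strand))
        return 0 if c is None else c.get(pos, 0)

    def strand_total(self, strand: str) -> int:
        return sum(
            sum(c.values()) for (ch, st), c in self.counts.items() if st == strand
        )

    def total(self) -> int:
        return sum(sum(c.values()) for c in self.counts.values())

    def positions(self) -> Iterator[tuple[str, str, int, int]]:
        """Yield (chrom, strand, pos, count), sorted."""
        for (chrom, strand) in sorted(self.counts):
            c = self.counts[(chrom, strand)]
            for pos in sorted(c):
                yield chrom, strand, pos, c[pos]

    # -- flat-file persistence (stage artifact) ----------------------------

    def write_tsv(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            fh.write(
                f"#condition={self.condition}\tmultimap_policy={self.multimap_policy}\t"
                f"retained={self.total_retained}\tdiscarded_length={self.total_discarded_by_length}\t"
                f"discarded_multimap={self.total_discarded_by_multimap}\tunmapped={self.total_unmapped}\n"
            )
            fh.write("chrom\tstrand\tpos\tcount\n")
            for chrom, strand, pos, count in self.positions():
                fh.write(f"{chrom}\t{strand}\t{pos}\t{count}\n")

    @classmethod
    def read_tsv(cls, path: str | Path) -> "PsiteProfile":
        with open(path) as fh:
            header = fh.readline().lstrip("#").rstrip("\n").split("\t")
            kv = dict(item.split("=", 1) for item in header)
            prof = cls(condition=kv["condition"], multimap_policy=kv["multimap_policy"])
            prof.total_discarded_by_length = int(kv["discarded_length"])
            prof.total_discarded_by_multimap = int(kv["discarded_multimap"])
            prof.total_unmapped = int(kv["unmapped"])
            fh.readline()  # column header
            for line in fh:
                chrom, strand, pos, count = line.rstrip("\n").split("\t")
                prof.add(chrom, strand, int(pos), int(count))
        return prof


def _n_locations(read: pysam.AlignedSegment) -> int:
    try:
        return int(read.get_tag("NH"))
    except KeyError:
        return 1


def build_profile(
    alignments: str | Path | Iterable[pysam.AlignedSegment],
    policy: str = UNIQUE_ONLY,
    condition: str = ELONGATING,
) -> PsiteProfile:
    """Reduce aligned reads to a P-site profile.

    ``alignments`` may be a SAM/BAM path or an iterable of pysam records.
    Policy ``unique_only`` drops reads reported at more than one location;
    ``multimap_leq_15`` drops reads reported at more than 15.  Each retained
    alignment contributes one count at its P-site (a multimapper contributes
    one count at each of its reported alignments).
    """
    if policy not in {UNIQUE_ONLY, MULTIMAP_LEQ_15}:
        raise ValueError(f"unknown multimap policy {policy!r}")

    close_me = None
    if isinstance(alignments, (str, Path)):
        close_me = pysam.AlignmentFile(str(alignments), check_sq=False)
        records: Iterable[pysam.AlignedSegment] = close_me
    else:
        records = alignments

    profile = PsiteProfile(condition=condition, multimap_policy=policy)
    try:
        for read in records:
            if read.is_unmapped:
                profile.total_unmapped += 1
                continue
            length = read.query_alignment_length  # soft clips excluded
            try:
                offset = psite_offset(length)
            except ReadLengthError:
                profile.total_discarded_by_length += 1
                continue
            nloc = _n_locations(read)
            if policy == UNIQUE_ONLY and nloc > 1:
                profile.total_discarded_by_multimap += 1
                continue
            if policy == MULTIMAP_LEQ_15 and nloc > MULTIMAP_CAP:
                profile.total_discarded_by_multimap += 1
                continue
            refpos = read.get_reference_positions()  # 0-based, ascending, no introns
            if read.is_reverse:
                # read 5' end is the rightmost aligned base; walk the offset
                # back along aligned bases
                p0 = refpos[-1 - offset]
                strand = "-"
            else:
                p0 = refpos[offset]
                strand = "+"
            profile.add(read.reference_name, strand, p0 + 1)
    finally:
        if close_me is not None:
            close_me.close()
    return profile


def write_bedgraph(profile: PsiteProfile, out: str | Path, strand: str) -> None:
    """Write one strand of a profile as BedGraph (0-based half-open intervals),
    merging runs of adjacent positions with equal counts."""
    if strand not in {"+", "-"}:
        raise ValueError("strand must be '+' or '-'")
    with open(out, "w") as fh:
        for (chrom, st) in sorted(profile.counts):
            if st != strand:
                continue
            c = profile.counts[(chrom, st)]
            run_start = prev_pos = prev_count = None
            for pos in sorted(c):
                count = c[pos]
                if count == 0:
                    continue
                if prev_pos is not None and pos == prev_pos + 1 and count == prev_count:
                    prev_pos = pos
                    continue
                if prev_pos is not None:
                    fh.write(f"{chrom}\t{run_start - 1}\t{prev_pos}\t{prev_count}\n")
                run_start = prev_pos = pos
                prev_count = count
            if prev_pos is not None:
                fh.write(f"{chrom}\t{run_start - 1}\t{prev_pos}\t{prev_count}\n")


def read_bedgraph(path: str | Path, strand: str) -> Counter:
    """Parse a BedGraph written by :func:`write_bedgraph` back into per-position
    counts keyed by (chrom, strand, 1-based position)."""
    counts: Counter = Counter()
    with open(path) as fh:
        for line in fh:
            line = line.strip()
            if not line or line.startswith(("track", "#")):
                continue
            chrom, start, end, value = line.split("\t")
            for pos0 in range(int(start), int(end)):
                counts[(chrom, strand, pos0 + 1)] += int(float(value))
    return counts
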