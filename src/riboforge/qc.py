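"""Metagenic classification of P-sites and gene-level footprint summaries.

Each uniquely-mapped P-site is assigned to exactly one functional category.
Translation-associated categories (5'UTR, CDS exon, intron, 3'UTR) are defined
only on protein-coding transcripts; footprints not assignable to a
protein-coding transcript fall to non-coding transcripts ("other_biotypes",
with a per-biotype breakdown) and the remainder is "intergenic".
Classification is strand-aware: a P-site only matches transcripts on its own
strand.
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass, field
from pathlib import Path

import pandas as pd

from .annotation import AnnotationBundle, TranscriptModel, PROTEIN_CODING
from .ingest import PsiteProfile

CAT_5UTR = "5UTR"
CAT_EXON = "exon"
CAT_INTRON = "intron"
CAT_3UTR = "3UTR"
CAT_OTHER = "other_biotypes"
CAT_INTERGENIC = "intergenic"

CATEGORIES = (CAT_EXON, CAT_5UTR, CAT_3UTR, CAT_INTRON, CAT_OTHER, CAT_INTERGENIC)

# precedence among protein-coding assignments: CDS exon > 5'UTR > 3'UTR > intron
_PC_PRECEDENCE = {CAT_EXON: 0, CAT_5UTR: 1, CAT_3UTR: 2, CAT_INTRON: 3}


def _pc_category(t: TranscriptModel, gpos: int) -> str:
    tpos = t.genomic_to_tpos(gpos)
    if tpos is None:
        return CAT_INTRON
    if not t.is_coding:
        # protein-coding transcript without CDS rows: full exonic region
        # is treated as coding sequence
        return CAT_EXON
    ts, te = t.cds_tpos_bounds
    if tpos < ts:
        return CAT_5UTR
    if tpos > te:
        return CAT_3UTR
    return CAT_EXON


def classify_psite(
    annotation: AnnotationBundle, chrom: str, pos: int, strand: str
) -> tuple[str, str | None]:
    """Classify one P-site; returns ``(category, biotype)`` where biotype is
    set only for the other_biotypes category."""
    hits = annotation.transcripts_at(chrom, pos, strand)
    pc = [t for t in hits if t.biotype == PROTEIN_CODING]
    if pc:
        best = min((_pc_category(t, pos) for t in pc), key=_PC_PRECEDENCE.__getitem__)
        return best, None
    if hits:
        # prefer a transcript whose exon contains the position, then sorted id
        exonic = [t for t in hits if t.genomic_to_tpos(pos) is not None]
        chosen = (exonic or hits)[0]
        return CAT_OTHER, chosen.biotype
    return CAT_INTERGENIC, None


@dataclass
class MetagenicCounts:
    counts: Counter = field(default_factory=Counter)
    biotype_breakdown: Counter = field(default_factory=Counter)

    def total(self) -> int:
        return sum(self.counts.values())

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {"category": list(CATEGORIES), "count": [self.counts.get(c, 0) for c in CATEGORIES]}
        )

    def biotypes_to_frame(self) -> pd.DataFrame:
        items = sorted(self.biotype_breakdown.items())
        return pd.DataFrame({"biotype": [b for b, _ in items], "count": [n for _, n in items]})


def metagenic_classification(
    profile: PsiteProfile, annotation: AnnotationBundle
) -> MetagenicCounts:
    """Classify every P-site count of a (unique-mapper) profile."""
    out = MetagenicCounts()
    for chrom, strand, pos, count in profile.positions():
        category, biotype = classify_psite(annotation, chrom, pos, strand)
        out.counts[category] += count
        if category == CAT_OTHER:
            out.biotype_breakdown[biotype] += count
    return out


def gene_counts(profile: PsiteProfile, annotation: AnnotationBundle) -> pd.Series:
    """Uniquely-mapped P-site counts per gene (exonic, strand-matched).

    Every annotated gene appears, genes without footprints with count 0.  A
    P-site inside exons of several genes is counted for each of them.
    """
    counts: Counter = Counter()
    for chrom, strand, pos, count in profile.positions():
        genes_here = {
            t.gene_id
            for t in annotation.transcripts_at(chrom, pos, strand)
            if t.genomic_to_tpos(pos) is not None
        }
        for g in genes_here:
            counts[g] += count
    all_genes = sorted(annotation.genes())
    return pd.Series(
        [counts.get(g, 0) for g in all_genes], index=all_genes, name="count"
    )


def gene_distribution(
    profile: PsiteProfile, annotation: AnnotationBundle
) -> pd.DataFrame:
    """Ranked gene abundance table with cumulative fractions.

    Columns: gene_id, count, rank (1 = most covered), cumulative_fraction
    (running share of all gene-assigned footprints, ending at 1.0 when any
    footprints exist).
    """
    counts = gene_counts(profile, annotation).sort_values(
        ascending=False, kind="mergesort"
    )
    df = pd.DataFrame({"gene_id": counts.index, "count": counts.values})
    df["rank"] = range(1, len(df) + 1)
    total = df["count"].sum()
    df["cumulative_fraction"] = (
        df["count"].cumsum() / total if total > 0 else 0.0
    )
    return df


def plot_gene_distribution(df: pd.DataFrame, out_dir: str | Path) -> list[Path]:
    """Write the three QC figures (abundance, cumulative, density) as PNGs."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt
    import numpy as np

    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    paths = []

    fig, ax = plt.subplots()
    ax.plot(df["rank"], df["count"], drawstyle="steps-post")
    ax.set(xlabel="gene rank", ylabel="footprint count", title="Gene abundance")
    p = out_dir / "gene_abundance.png"
    fig.savefig(p, dpi=100)
    plt.close(fig)
    paths.append(p)

    fig, ax = plt.subplots()
    ax.plot(df["rank"], df["cumulative_fraction"])
    ax.set(xlabel="gene rank", ylabel="cumulative fraction", ylim=(0, 1.05),
           title="Cumulative gene distribution")
    p = out_dir / "gene_cumulative.png"
    fig.savefig(p, dpi=100)
    plt.close(fig)
    paths.append(p)

    fig, ax = plt.subplots()
    nonzero = df.loc[df["count"] > 0, "count"]
    if len(nonzero):
        ax.hist(np.log10(nonzero), bins=min(30, max(5, len(nonzero) // 2)))
    ax.set(xlabel="log10 footprint count", ylabel="genes", title="Gene density")
    p = out_dir / "gene_density.png"
    fig.savefig(p, dpi=100)
    plt.close(fig)
    paths.append(p)
    return paths
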