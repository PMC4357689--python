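"""Translation-initiation-site (TIS) calling from initiating-ribosome profiles.

Initiating-ribosome (harringtonine or lactimidomycin treated) P-sites are
accumulated at AUG and near-cognate codons over a +/-1 nt window.  A candidate
is retained when (i) its accumulated count is the local maximum within a 7 nt
window around the codon's first nucleotide, (ii) the accumulated count reaches
the category's minimum-count threshold and (iii) the normalised initiating
signal exceeds the elongating background by the category's margin:

    R_k = (X_k / N_k) * 10

with X_k the accumulated count at the candidate and N_k the total count over
the transcript's exonic positions, for k in {initiating, elongating}.

Candidates are categorised relative to the transcript's annotated CDS (5'UTR,
aTIS, CDS, 3'UTR) or as no_translation on non-protein-coding transcripts, each
category with its own thresholds.  Annotated starts (aTIS) of transcripts with
elongating ribosome occupancy are always reported, labelled TRUE / FALSE /
NO_DATA; candidates of the other categories that fail any rule are discarded.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Mapping

import pandas as pd

from .annotation import (
    AnnotationBundle,
    GenomeSequence,
    TranscriptModel,
    transcript_sequence,
)
from .ingest import PsiteProfile

NEAR_COGNATE_CODONS = frozenset(
    {"CTG", "GTG", "TTG", "AAG", "ACG", "AGG", "ATA", "ATC", "ATT"}
)
CANDIDATE_CODONS = frozenset({"ATG"}) | NEAR_COGNATE_CODONS

CAT_ATIS = "aTIS"
CAT_5UTR = "5UTR"
CAT_CDS = "CDS"
CAT_3UTR = "3UTR"
CAT_NO_TRANSLATION = "no_translation"

STATUS_TRUE = "TRUE"
STATUS_FALSE = "FALSE"
STATUS_NO_DATA = "NO_DATA"

ACCUMULATION_HALF_WINDOW = 1  # +/-1 nt accumulation
LOCAL_MAX_HALF_WINDOW = 3     # one codon up- and downstream


@dataclass(frozen=True)
class CategoryThresholds:
    min_count: int
    delta_r: float


DEFAULT_PARAMS: dict[str, CategoryThresholds] = {
    CAT_ATIS: CategoryThresholds(5, 0.01),
    CAT_5UTR: CategoryThresholds(10, 0.05),
    CAT_CDS: CategoryThresholds(15, 0.15),
    CAT_3UTR: CategoryThresholds(10, 0.05),
    CAT_NO_TRANSLATION: CategoryThresholds(10, 0.05),
}


def default_params() -> dict[str, CategoryThresholds]:
    return dict(DEFAULT_PARAMS)


@dataclass(frozen=True)
class TISCandidate:
    transcript_id: str
    tpos: int              # transcript coordinate of the codon's first nt
    genomic_pos: int       # genomic coordinate of the codon's first nt
    codon: str
    is_near_cognate: bool
    category: str


@dataclass
class TISCall:
    candidate: TISCandidate
    x_init: int
    x_elong: int
    n_init: int
    n_elong: int
    r_init: float | None
    r_elong: float
    is_local_max: bool
    status: str | None      # TRUE/FALSE/NO_DATA for aTIS, else None
    retained: bool

    @property
    def r_diff(self) -> float | None:
        return None if self.r_init is None else self.r_init - self.r_elong


def enumerate_candidates(
    t: TranscriptModel, genome: GenomeSequence, sequence: str | None = None
) -> list[TISCandidate]:
    """All AUG / near-cognate codons along the transcript, categorised by
    position relative to the annotated CDS."""
    seq = sequence if sequence is not None else transcript_sequence(t, genome)
    bounds = t.cds_tpos_bounds if t.is_coding else None
    out: list[TISCandidate] = []
    for i in range(len(seq) - 2):
        codon = seq[i : i + 3]
        if codon not in CANDIDATE_CODONS:
            continue
        if bounds is None:
            category = CAT_NO_TRANSLATION
        else:
            ts, te = bounds
            if i == ts:
                category = CAT_ATIS
            elif i < ts:
                category = CAT_5UTR
            elif i <= te:
                category = CAT_CDS
            else:
                category = CAT_3UTR
        out.append(
            TISCandidate(
                transcript_id=t.transcript_id,
                tpos=i,
                genomic_pos=t.tpos_to_genomic(i),
                codon=codon,
                is_near_cognate=codon != "ATG",
                category=category,
            )
        )
    return out


def accumulate_window(
    profile: PsiteProfile, t: TranscriptModel, tpos: int
) -> int:
    """Accumulated P-site count over the +/-1 nt window (transcript
    orientation) around a codon's first nucleotide."""
    total = 0
    for j in range(tpos - ACCUMULATION_HALF_WINDOW, tpos + ACCUMULATION_HALF_WINDOW + 1):
        if 0 <= j < t.length:
            total += profile.count_at(t.chromosome, t.strand, t.tpos_to_genomic(j))
    return total


def transcript_total(profile: PsiteProfile, t: TranscriptModel) -> int:
    """Total P-site count over all exonic positions of the transcript."""
    return sum(
        profile.count_at(t.chromosome, t.strand, g) for g in t.exonic_positions()
    )


def compute_r(x: int, n: int) -> float | None:
    """R = (X/N) * 10; undefined (None) when the transcript has no reads."""
    if n == 0:
        return None
    return (x / n) * 10


def _local_max_flags(
    t: TranscriptModel,
    candidates: list[TISCandidate],
    accumulated: Mapping[int, int],
) -> dict[int, bool]:
    """Rule (i) per candidate tpos: accumulated count is the maximum over the
    7 nt window; when two candidate positions within one codon of each other
    tie at the maximum, the 5'-most candidate wins."""

    def acc(j: int) -> int:
        return accumulated.get(j, 0)

    flags: dict[int, bool] = {}
    cand_pos = sorted(c.tpos for c in candidates)
    cand_set = set(cand_pos)
    for i in cand_pos:
        window = range(max(0, i - LOCAL_MAX_HALF_WINDOW),
                       min(t.length, i + LOCAL_MAX_HALF_WINDOW + 1))
        here = acc(i)
        flags[i] = all(here >= acc(j) for j in window)
    # tie-break: 5'-most tied candidate wins
    for i in cand_pos:
        if not flags[i]:
            continue
        for j in range(i - LOCAL_MAX_HALF_WINDOW, i):
            if j in cand_set and flags.get(j) and acc(j) == acc(i):
                flags[i] = False
                break
    return flags


def call_tis_transcript(
    t: TranscriptModel,
    genome: GenomeSequence,
    init_profile: PsiteProfile,
    elong_profile: PsiteProfile | None,
    params: Mapping[str, CategoryThresholds],
    translated: bool,
    sequence: str | None = None,
) -> list[TISCall]:
    candidates = enumerate_candidates(t, genome, sequence=sequence)
    if not candidates:
        return []
    n_init = transcript_total(init_profile, t)
    n_elong = transcript_total(elong_profile, t) if elong_profile is not None else 0

    accumulated = {
        c.tpos: accumulate_window(init_profile, t, c.tpos) for c in candidates
    }
    # positions between candidates also compete for the window maximum
    extra = set()
    for c in candidates:
        extra.update(
            j
            for j in range(c.tpos - LOCAL_MAX_HALF_WINDOW, c.tpos + LOCAL_MAX_HALF_WINDOW + 1)
            if 0 <= j < t.length and j not in accumulated
        )
    for j in extra:
        accumulated[j] = accumulate_window(init_profile, t, j)

    local_max = _local_max_flags(t, candidates, accumulated)

    calls: list[TISCall] = []
    for c in candidates:
        x_init = accumulated[c.tpos]
        x_elong = (
            accumulate_window(elong_profile, t, c.tpos)
            if elong_profile is not None
            else 0
        )
        r_init = compute_r(x_init, n_init)
        r_elong_val = compute_r(x_elong, n_elong)
        r_elong = 0.0 if r_elong_val is None else r_elong_val
        thr = params[c.category]
        passes = (
            local_max[c.tpos]
            and x_init >= thr.min_count
            and r_init is not None
            and (r_init - r_elong) >= thr.delta_r
        )
        if c.category == CAT_ATIS:
            if translated:
                if x_init == 0 or n_init == 0:
                    status, retained = STATUS_NO_DATA, True
                elif passes:
                    status, retained = STATUS_TRUE, True
                else:
                    status, retained = STATUS_FALSE, True
            elif passes:
                status, retained = STATUS_TRUE, True
            else:
                continue
        else:
            if not passes:
                continue
            status, retained = None, True
        calls.append(
            TISCall(
                candidate=c,
                x_init=x_init,
                x_elong=x_elong,
                n_init=n_init,
                n_elong=n_elong,
                r_init=r_init,
                r_elong=r_elong,
                is_local_max=local_max[c.tpos],
                status=status,
                retained=retained,
            )
        )
    return calls


def call_tis(
    annotation: AnnotationBundle,
    init_profile: PsiteProfile,
    elong_profile: PsiteProfile | None,
    params: Mapping[str, CategoryThresholds] | None = None,
    translated_ids: Iterable[str] = (),
) -> list[TISCall]:
    """Call TIS across all transcripts of the annotation.

    Candidates are evaluated per transcript; the same genomic position may be
    called in several isoforms (deduplication happens at assembly).
    """
    params = dict(DEFAULT_PARAMS) if params is None else dict(params)
    translated = set(translated_ids)
    calls: list[TISCall] = []
    for tid in sorted(annotation.transcripts):
        t = annotation.transcripts[tid]
        calls.extend(
            call_tis_transcript(
                t,
                annotation.genome,
                init_profile,
                elong_profile,
                params,
                translated=tid in translated,
            )
        )
    return calls


def calls_to_frame(calls: list[TISCall]) -> pd.DataFrame:
    rows = []
    for call in calls:
        c = call.candidate
        rows.append(
            {
                "transcript_id": c.transcript_id,
                "tpos": c.tpos,
                "genomic_pos": c.genomic_pos,
                "codon": c.codon,
                "near_cognate": c.is_near_cognate,
                "category": c.category,
                "x_init": call.x_init,
                "x_elong": call.x_elong,
                "n_init": call.n_init,
                "n_elong": call.n_elong,
                "r_init": call.r_init,
                "r_elong": call.r_elong,
                "status": call.status if call.status is not None else "",
                "retained": call.retained,
            }
        )
    return pd.DataFrame(
        rows,
        columns=[
            "transcript_id", "tpos", "genomic_pos", "codon", "near_cognate",
            "category", "x_init", "x_elong", "n_init", "n_elong",
            "r_init", "r_elong", "status", "retained",
        ],
    )


def write_calls_tsv(calls: list[TISCall], path: str | Path) -> None:
    calls_to_frame(calls).to_csv(path, sep="\t", index=False)
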