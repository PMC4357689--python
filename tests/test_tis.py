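"""TIS candidate enumeration, window accumulation, R statistic and the
three-rule caller with per-category thresholds."""

import pytest

from riboforge.annotation import AnnotationBundle, GenomeSequence
from riboforge.tis import (
    CAT_5UTR,
    CAT_ATIS,
    CAT_CDS,
    CAT_NO_TRANSLATION,
    CANDIDATE_CODONS,
    NEAR_COGNATE_CODONS,
    CategoryThresholds,
    accumulate_window,
    call_tis,
    call_tis_transcript,
    compute_r,
    default_params,
    enumerate_candidates,
    transcript_total,
)

from conftest import make_profile, make_transcript


def test_near_cognate_set_is_single_edits_of_atg():
    expected = set()
    for i in range(3):
        for b in "ACGT":
            codon = list("ATG")
            if codon[i] == b:
                continue
            codon[i] = b
            expected.add("".join(codon))
    assert NEAR_COGNATE_CODONS == expected
    assert "GGG" not in CANDIDATE_CODONS  # two edits away


@pytest.fixture()
def coding_toy():
    #            0123456789...
    seq = "CCCCCTGCCCATGGCTATGAAGTAACCACCC"
    # candidates: CTG at tpos 4 (5'UTR), ATG at 10 (aTIS), ATG at 16 and
    # AAG at 19 (CDS); stop TAA at tpos 22; CDS genomic 11..25
    genome = GenomeSequence({"chr": seq})
    t = make_transcript(exons=[(1, len(seq))], cds=(11, 25))
    return AnnotationBundle(transcripts={"t1": t}, genome=genome), t


class TestEnumerate:
    def test_categories_and_near_cognate_flags(self, coding_toy):
        ann, t = coding_toy
        cands = {c.tpos: c for c in enumerate_candidates(t, ann.genome)}
        assert cands[4].codon == "CTG" and cands[4].category == CAT_5UTR
        assert cands[4].is_near_cognate
        assert cands[10].codon == "ATG" and cands[10].category == CAT_ATIS
        assert not cands[10].is_near_cognate
        assert cands[16].category == CAT_CDS

    def test_noncoding_transcript_is_no_translation(self):
        genome = GenomeSequence({"chr": "CCATGCCCCC"})
        t = make_transcript(biotype="lincRNA", exons=[(1, 10)])
        cands = enumerate_candidates(t, genome)
        assert all(c.category == CAT_NO_TRANSLATION for c in cands)

    def test_genomic_position_on_minus_strand(self):
        # transcript reads ATG... -> genome carries reverse complement
        genome = GenomeSequence({"chr": "CCCCCCCAT"})  # revcomp -> ATGGGGGGG
        t = make_transcript(strand="-", exons=[(1, 9)])
        cands = enumerate_candidates(t, genome)
        atg = [c for c in cands if c.codon == "ATG"]
        assert atg and atg[0].tpos == 0 and atg[0].genomic_pos == 9


class TestAccumulateWindow:
    def test_sums_plus_minus_one(self, coding_toy):
        ann, t = coding_toy
        prof = make_profile({("chr", "+", 10): 1, ("chr", "+", 11): 5, ("chr", "+", 12): 2})
        # codon first nt at tpos 10 = genomic 11
        assert accumulate_window(prof, t, 10) == 8

    def test_counts_outside_window_disregarded(self, coding_toy):
        ann, t = coding_toy
        prof = make_profile({("chr", "+", 13): 9})  # tpos 12 = first+2
        assert accumulate_window(prof, t, 10) == 0

    def test_empty_window(self, coding_toy):
        ann, t = coding_toy
        assert accumulate_window(make_profile({}), t, 10) == 0


class TestComputeR:
    def test_formula(self):
        assert compute_r(1, 10) == 1.0
        assert compute_r(10, 10) == 10.0
        assert compute_r(0, 7) == 0.0

    def test_undefined_without_reads(self):
        assert compute_r(0, 0) is None


def _run_single(t, genome, init_counts, elong_counts, translated=True, params=None):
    init = make_profile(init_counts, condition="initiating")
    elong = make_profile(elong_counts)
    return call_tis_transcript(
        t, genome, init, elong, params or default_params(), translated=translated
    )


class TestCallRules:
    def test_atis_true_when_all_rules_pass(self, coding_toy):
        ann, t = coding_toy
        # X_init=20 at the aTIS (genomic 11), plus 80 reads far away
        init = {("chr", "+", 11): 20, ("chr", "+", 29): 80}
        elong = {("chr", "+", 11): 1, ("chr", "+", 29): 999}
        calls = _run_single(t, ann.genome, init, elong)
        atis = next(c for c in calls if c.candidate.category == CAT_ATIS)
        assert atis.status == "TRUE" and atis.retained
        assert atis.r_init == pytest.approx((20 / 100) * 10)
        assert atis.r_elong == pytest.approx((1 / 1000) * 10)

    def test_atis_no_data_without_initiating_coverage(self, coding_toy):
        ann, t = coding_toy
        calls = _run_single(t, ann.genome, {("chr", "+", 29): 50}, {})
        atis = next(c for c in calls if c.candidate.category == CAT_ATIS)
        assert atis.status == "NO_DATA" and atis.retained and atis.x_init == 0

    def test_atis_false_when_rule_fails_but_covered(self, coding_toy):
        ann, t = coding_toy
        # covered (X=4) but below the aTIS min count of 5
        calls = _run_single(t, ann.genome,
                            {("chr", "+", 11): 4, ("chr", "+", 29): 96}, {})
        atis = next(c for c in calls if c.candidate.category == CAT_ATIS)
        assert atis.status == "FALSE" and atis.retained

    def test_atis_of_untranslated_transcript_needs_all_rules(self, coding_toy):
        ann, t = coding_toy
        calls = _run_single(t, ann.genome, {("chr", "+", 29): 50}, {},
                            translated=False)
        assert not any(c.candidate.category == CAT_ATIS for c in calls)

    def test_5utr_below_min_count_discarded(self, coding_toy):
        ann, t = coding_toy
        # CTG at tpos 4 (genomic 5): 9 reads < min_count 10
        calls = _run_single(t, ann.genome,
                            {("chr", "+", 5): 9, ("chr", "+", 29): 1}, {})
        assert not any(c.candidate.category == CAT_5UTR for c in calls)
        calls = _run_single(t, ann.genome,
                            {("chr", "+", 5): 10, ("chr", "+", 29): 1}, {})
        assert any(c.candidate.category == CAT_5UTR for c in calls)

    def test_cds_category_uses_stricter_thresholds(self, coding_toy):
        ann, t = coding_toy
        # dTIS ATG at tpos 16 (genomic 17): 10 reads pass aTIS thresholds
        # but fail the CDS minimum of 15
        calls = _run_single(t, ann.genome, {("chr", "+", 17): 10}, {})
        assert not any(c.candidate.category == CAT_CDS for c in calls)
        calls = _run_single(t, ann.genome, {("chr", "+", 17): 15}, {})
        assert any(c.candidate.category == CAT_CDS for c in calls)

    def test_local_maximum_rule(self, coding_toy):
        ann, t = coding_toy
        # a larger accumulated peak 3 nt downstream kills rule (i) for the
        # ATG at tpos 16 even though its own count passes every threshold
        init = {("chr", "+", 17): 15, ("chr", "+", 20): 40}
        calls = _run_single(t, ann.genome, init, {})
        assert not any(c.candidate.tpos == 16 for c in calls)

    def test_tie_break_prefers_5prime_candidate(self):
        # two ATGs 3 nt apart with identical accumulated counts
        genome = GenomeSequence({"chr": "CCCCCCCCCCATGATGCCCCCCCCCCCCCC"})
        t = make_transcript(biotype="lincRNA", exons=[(1, 30)])
        init = make_profile({("chr", "+", 11): 20, ("chr", "+", 14): 20},
                            condition="initiating")
        calls = call_tis_transcript(
            t, genome, init, None, default_params(), translated=False
        )
        assert [c.candidate.tpos for c in calls] == [10]

    def test_r_delta_rule(self, coding_toy):
        ann, t = coding_toy
        # 5'UTR: R_init - R_elong must reach 0.05
        init = {("chr", "+", 5): 50, ("chr", "+", 29): 50}   # R_init = 5.0
        elong = {("chr", "+", 5): 99, ("chr", "+", 29): 1}   # R_elong = 9.9
        calls = _run_single(t, ann.genome, init, elong)
        assert not any(c.candidate.category == CAT_5UTR for c in calls)


class TestOnFixtures:
    def test_planted_recovery_and_no_off_target(self, bundle, annotation,
                                                chx_profile, ltm_profile):
        translated = {
            tid for tid, flag in bundle.truth.translated.items() if flag
        }
        calls = call_tis(annotation, ltm_profile, chx_profile,
                         translated_ids=translated)
        retained = [c for c in calls if c.retained and c.status != "NO_DATA"]
        planted_gpos = {p.genomic_pos for p in bundle.truth.planted_tis}
        planted_keys = {(p.transcript_id, p.genomic_pos)
                        for p in bundle.truth.planted_tis}
        called_keys = {(c.candidate.transcript_id, c.candidate.genomic_pos)
                       for c in retained}
        # 100% recall of planted sites
        assert planted_keys <= called_keys
        # zero calls at genomic positions where nothing was planted
        assert {c.candidate.genomic_pos for c in retained} <= planted_gpos

    def test_r_values_match_brute_force(self, bundle, annotation,
                                        chx_profile, ltm_profile):
        translated = {tid for tid, f in bundle.truth.translated.items() if f}
        calls = call_tis(annotation, ltm_profile, chx_profile,
                         translated_ids=translated)
        for c in calls:
            t = annotation.transcripts[c.candidate.transcript_id]
            gmap = t.exonic_positions()
            n_init = sum(ltm_profile.count_at(t.chromosome, t.strand, g) for g in gmap)
            window = [
                gmap[j]
                for j in range(c.candidate.tpos - 1, c.candidate.tpos + 2)
                if 0 <= j < t.length
            ]
            x_init = sum(ltm_profile.count_at(t.chromosome, t.strand, g) for g in window)
            assert c.x_init == x_init and c.n_init == n_init
            if n_init:
                assert c.r_init == (x_init / n_init) * 10  # full precision
            x_elong = sum(chx_profile.count_at(t.chromosome, t.strand, g) for g in window)
            n_elong = sum(chx_profile.count_at(t.chromosome, t.strand, g) for g in gmap)
            assert c.x_elong == x_elong and c.n_elong == n_elong
            if n_elong:
                assert c.r_elong == (x_elong / n_elong) * 10

    def test_threshold_monotonicity(self, annotation, bundle,
                                    chx_profile, ltm_profile):
        """Raising min_count or delta_R never increases non-aTIS call counts."""
        translated = {tid for tid, f in bundle.truth.translated.items() if f}

        def n_non_atis(scale_count, scale_r):
            params = {
                cat: CategoryThresholds(
                    thr.min_count * scale_count, thr.delta_r * scale_r
                )
                for cat, thr in default_params().items()
            }
            calls = call_tis(annotation, ltm_profile, chx_profile,
                             params=params, translated_ids=translated)
            return sum(1 for c in calls
                       if c.retained and c.candidate.category != CAT_ATIS)

        base = n_non_atis(1, 1)
        assert n_non_atis(3, 1) <= base
        assert n_non_atis(1, 40) <= base
        assert n_non_atis(10, 100) <= n_non_atis(3, 40) <= base
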