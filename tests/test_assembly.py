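"""Translation from TIS, redundancy elimination, canonical mapping and FASTA."""

import pytest

from riboforge.annotation import GenomeSequence
from riboforge.assembly import (
    ProteoformRecord,
    deduplicate,
    map_canonical,
    read_id_map,
    read_proteoform_fasta,
    translate_from_tis,
    write_fasta,
)
from riboforge.tis import TISCall, TISCandidate
from riboforge.variants import SOURCE_CALLER, VariantRecord

from conftest import make_transcript


def _tis_call(t, tpos, codon, category="aTIS", status="TRUE"):
    cand = TISCandidate(
        transcript_id=t.transcript_id,
        tpos=tpos,
        genomic_pos=t.tpos_to_genomic(tpos),
        codon=codon,
        is_near_cognate=codon != "ATG",
        category=category,
    )
    return TISCall(
        candidate=cand, x_init=50, x_elong=0, n_init=100, n_elong=100,
        r_init=5.0, r_elong=0.0, is_local_max=True, status=status, retained=True,
    )


def _variant(pos, ref, alt, tid="t1"):
    return VariantRecord("chr", pos, ref, alt, SOURCE_CALLER,
                         transcript_ids=frozenset({tid}))


class TestTranslate:
    def test_atg_orf(self):
        g = GenomeSequence({"chr": "ATGGCTTAA"})
        t = make_transcript(exons=[(1, 9)], cds=(1, 9))
        recs = translate_from_tis(t, _tis_call(t, 0, "ATG"), g, min_protein_length=1)
        assert [r.sequence for r in recs] == ["MA"]
        assert not recs[0].truncated

    def test_near_cognate_recoded_to_methionine(self):
        g = GenomeSequence({"chr": "CTGGCTTAA"})
        t = make_transcript(exons=[(1, 9)], cds=(1, 9))
        recs = translate_from_tis(
            t, _tis_call(t, 0, "CTG", category="5UTR", status=None), g,
            min_protein_length=1,
        )
        assert recs[0].sequence == "MA"

    def test_nonsynonymous_variant_in_descriptor(self):
        g = GenomeSequence({"chr": "ATGGCTTAA"})
        t = make_transcript(exons=[(1, 9)], cds=(1, 9))
        recs = translate_from_tis(
            t, _tis_call(t, 0, "ATG"), g,
            variants=[_variant(5, "C", "T")],  # GCT -> GTT: A -> V
            min_protein_length=1,
        )
        assert [r.sequence for r in recs] == ["MA", "MV"]
        var_rec = recs[1]
        assert [v.is_nonsynonymous for v in var_rec.applied_variants] == [True]
        assert "snv=chr:5C>T(A2V)" in var_rec.descriptor()

    def test_synonymous_variant_suppressed(self):
        g = GenomeSequence({"chr": "ATGGCTTAA"})
        t = make_transcript(exons=[(1, 9)], cds=(1, 9))
        recs = translate_from_tis(
            t, _tis_call(t, 0, "ATG"), g,
            variants=[_variant(6, "T", "C")],  # GCT -> GCC: still A
            min_protein_length=1,
        )
        # the variant product equals the reference: only one record emitted
        assert [r.sequence for r in recs] == ["MA"]
        assert "snv" not in recs[0].descriptor()

    def test_no_stop_truncates_and_flags(self):
        g = GenomeSequence({"chr": "ATGGCTGCA"})
        t = make_transcript(exons=[(1, 9)], cds=(1, 9))
        recs = translate_from_tis(t, _tis_call(t, 0, "ATG"), g, min_protein_length=1)
        assert recs[0].sequence == "MAA" and recs[0].truncated
        assert "partial=true" in recs[0].descriptor()

    def test_n_codon_translates_to_x(self):
        g = GenomeSequence({"chr": "ATGGNTTAA"})
        t = make_transcript(exons=[(1, 9)], cds=(1, 9))
        recs = translate_from_tis(t, _tis_call(t, 0, "ATG"), g, min_protein_length=1)
        assert recs[0].sequence == "MX" and recs[0].ambiguous

    def test_minimum_length_filter(self):
        g = GenomeSequence({"chr": "ATGGCTTAA"})
        t = make_transcript(exons=[(1, 9)], cds=(1, 9))
        assert translate_from_tis(t, _tis_call(t, 0, "ATG"), g) == []  # default >= 6

    def test_minus_strand_with_variant(self):
        # transcript ATGGCTTAA on the minus strand
        g = GenomeSequence({"chr": "TTAAGCCAT"})
        t = make_transcript(strand="-", exons=[(1, 9)], cds=(9, 1))
        recs = translate_from_tis(
            t, _tis_call(t, 0, "ATG"), g,
            # genomic G>A at pos 5 = transcript C>T in codon 2: GCT -> GTT
            variants=[_variant(5, "G", "A")],
            min_protein_length=1,
        )
        assert [r.sequence for r in recs] == ["MA", "MV"]


def _rec(seq, tid="t1", category="aTIS", variants=(), tis=100):
    return ProteoformRecord(
        transcript_id=tid, tis_genomic_pos=tis, tis_tpos=0, codon="ATG",
        category=category, atis_status=None, sequence=seq,
        applied_variants=tuple(variants),
    )


class TestDeduplicate:
    def test_annotation_ranking(self):
        out = deduplicate([_rec("MAKAAA", "a", "CDS"), _rec("MAKAAA", "b", "aTIS")])
        assert len(out) == 1 and out[0].category == "aTIS"

    def test_subsequence_removed(self):
        out = deduplicate([_rec("MAKWWW"), _rec("MAKWWWK", "t2")])
        assert [r.sequence for r in out] == ["MAKWWWK"]

    def test_snp_tie_rule(self):
        from riboforge.assembly import AppliedVariant

        av = AppliedVariant("chr", 5, "C", "T", 1, "A", "V")
        plain = _rec("MVKAAA", "a")
        with_snp = _rec("MVKAAA", "b", variants=[av])
        out = deduplicate([plain, with_snp])
        assert len(out) == 1 and out[0].transcript_id == "b"

    def test_seeded_tie_is_deterministic_and_order_free(self):
        a, b = _rec("MAKAAA", "a"), _rec("MAKAAA", "b")
        pick1 = deduplicate([a, b], seed=7)[0].transcript_id
        pick2 = deduplicate([b, a], seed=7)[0].transcript_id
        assert pick1 == pick2

    def test_survivor_rank_never_below_losers(self):
        ranks = {"aTIS": 0, "5UTR": 1, "CDS": 2, "3UTR": 3, "no_translation": 4}
        pool = [
            _rec("MAKAAA", f"t{i}", cat)
            for i, cat in enumerate(["CDS", "3UTR", "5UTR", "no_translation"])
        ]
        out = deduplicate(pool)
        assert len(out) == 1
        assert ranks[out[0].category] == min(ranks[r.category] for r in pool)


class TestCanonicalMapping:
    def test_atis_maps_by_id(self, tmp_path):
        id_map = tmp_path / "map.tsv"
        id_map.write_text("t1\tP12345\n")
        out = map_canonical([_rec("MAKAAA")], id_map=read_id_map(str(id_map)))
        assert out[0].canonical_id == "P12345"

    def test_cds_maps_by_containment(self):
        out = map_canonical(
            [_rec("KWWWK", category="CDS")],
            canonical_seqs={"P1": "MAKWWWK"},
        )
        assert out[0].canonical_id == "P1"

    def test_unmatched_stays_empty(self):
        out = map_canonical(
            [_rec("MHHHHH", category="CDS")], canonical_seqs={"P1": "MAKWWWK"}
        )
        assert out[0].canonical_id is None

    def test_blast_import_overrides_containment(self, tmp_path):
        from riboforge.assembly import read_blast_tabular

        tab = tmp_path / "hits.tsv"
        tab.write_text(
            "t1\tP9\t100\t10\t0\t0\t1\t10\t1\t10\t1e-5\t50\n"
            "t1\tP8\t100\t10\t0\t0\t1\t10\t1\t10\t1e-5\t40\n"
        )
        hits = read_blast_tabular(str(tab))
        out = map_canonical(
            [_rec("KWWWK", category="CDS")],
            canonical_seqs={"P1": "MAKWWWK"},
            blast_hits=hits,
        )
        assert out[0].canonical_id == "P9"


class TestFasta:
    def test_round_trip(self, tmp_path):
        recs = [_rec("MAKAAA", "a"), _rec("MWWWWW", "b", "CDS"), _rec("MHHHHH", "c", "5UTR")]
        out = tmp_path / "db.fasta"
        write_fasta(recs, out)
        back = read_proteoform_fasta(out)
        assert len(back) == 3
        assert {seq for _, _, seq in back} == {"MAKAAA", "MWWWWW", "MHHHHH"}
        assert all(fields["tid"] in "abc" for _, fields, _ in back)

    def test_combined_mode_appends_unmatched_canonical(self, tmp_path):
        canonical = {"P1": "MAKAAA", "P2": "MCCCCC", "P3": "MDDDDD"}
        recs = map_canonical(
            [_rec("MAKAAA", category="CDS")], canonical_seqs=canonical
        )
        out = tmp_path / "db.fasta"
        write_fasta(recs, out, canonical_seqs=canonical, include_canonical_db=True)
        back = read_proteoform_fasta(out)
        assert len(back) == 3  # 1 record + 2 unmatched canonical entries

    def test_empty_records_combined_is_passthrough(self, tmp_path):
        canonical = {"P1": "MAKAAA", "P2": "MCCCCC"}
        out = tmp_path / "db.fasta"
        write_fasta([], out, canonical_seqs=canonical, include_canonical_db=True)
        assert {i for i, _, _ in read_proteoform_fasta(out)} == {"P1", "P2"}


def test_back_translation_consistency(bundle, annotation, chx_profile, ltm_profile):
    """Every emitted protein is reproduced exactly by re-deriving it from its
    transcript + TIS + variants."""
    from riboforge.assembly import assemble
    from riboforge.tis import call_tis
    from riboforge.transcripts import call_all
    from riboforge.variants import integrate_variants

    translated = {
        tid for tid, c in call_all(annotation, chx_profile).items() if c.is_translated
    }
    tis_calls = call_tis(annotation, ltm_profile, chx_profile,
                         translated_ids=translated)
    variants = integrate_variants(annotation, bundle.chx_sam,
                                  bundle.sample_vcf, bundle.dbsnp_vcf)
    records = assemble(annotation.transcripts, annotation.genome, tis_calls,
                       variants=variants, seed=1)
    assert records
    by_key = {
        (c.candidate.transcript_id, c.candidate.genomic_pos): c for c in tis_calls
    }
    for r in records:
        call = by_key[(r.transcript_id, r.tis_genomic_pos)]
        t = annotation.transcripts[r.transcript_id]
        rederived = translate_from_tis(
            t, call, annotation.genome,
            variants=variants if r.has_variants else (),
            min_protein_length=1,
        )
        assert r.sequence in [x.sequence for x in rederived]
        assert r.sequence[0] == "M" and "*" not in r.sequence


from hypothesis import given, settings, strategies as st

_cats = ["aTIS", "5UTR", "CDS", "3UTR", "no_translation"]


@settings(max_examples=40, deadline=None, derandomize=True)
@given(
    st.lists(
        st.tuples(
            st.text(alphabet="MAKW", min_size=1, max_size=6),
            st.sampled_from(_cats),
        ),
        min_size=1,
        max_size=12,
    ),
    st.randoms(use_true_random=False),
)
def test_deduplicate_properties(pool, rnd):
    """Output is duplicate- and substring-free, drawn from the input, keeps the
    best rank per sequence, and ignores input order."""
    ranks = {c: i for i, c in enumerate(_cats)}
    records = [
        _rec("M" + seq, f"t{i}", cat, tis=i) for i, (seq, cat) in enumerate(pool)
    ]
    out = deduplicate(records, seed=3)
    seqs = [r.sequence for r in out]
    assert len(seqs) == len(set(seqs))
    assert all(a == b or a not in b for a in seqs for b in seqs)
    in_keys = {(r.transcript_id, r.sequence) for r in records}
    assert all((r.transcript_id, r.sequence) in in_keys for r in out)
    for r in out:
        best = min(ranks[x.category] for x in records if x.sequence == r.sequence)
        assert ranks[r.category] == best
    shuffled = list(records)
    rnd.shuffle(shuffled)
    again = deduplicate(shuffled, seed=3)
    assert [(r.transcript_id, r.sequence) for r in again] == [
        (r.transcript_id, r.sequence) for r in out
    ]
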