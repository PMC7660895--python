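"""Haplotype encoding: length invariance, one-hot validity, channel modes."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

import starfunc as sf
from starfunc.encoder import EncodingConfig


def _ref(seq, contig="c"):
    return sf.ReferenceWindow(sf.GenomicWindow(contig, 0, len(seq)), seq)


@pytest.fixture(scope="module")
def empty_context():
    ref = _ref("ACGTACGTACGTACGTACGT")
    tracks = sf.AnnotationTrackSet(ref.window)
    flags = sf.VariantFlagTable()
    return ref, tracks, flags


class TestMaterialize:
    def test_reference_haplotype(self, empty_context):
        ref, _, _ = empty_context
        bases, indel = sf.materialize_haplotype(ref, [])
        assert "".join("ACGT"[i] for i in bases) == ref.sequence
        assert not indel.any()

    def test_snv_substitutes(self, empty_context):
        ref, _, _ = empty_context
        v = sf.VariantRecord("c", 2, "G", "T")
        bases, indel = sf.materialize_haplotype(ref, [v])
        assert "ACGT"[bases[2]] == "T"
        assert not indel.any()
        assert len(bases) == ref.window.length

    def test_insertion_keeps_length_and_flags(self, empty_context):
        ref, _, _ = empty_context
        v = sf.VariantRecord("c", 3, "T", "TA")
        bases, indel = sf.materialize_haplotype(ref, [v])
        assert len(bases) == ref.window.length
        assert "ACGT"[bases[3]] == "A"  # first inserted base at the anchor
        assert indel[3] and indel.sum() == 1

    def test_deletion_keeps_length_and_reference_bases(self, empty_context):
        ref, _, _ = empty_context
        v = sf.VariantRecord("c", 4, "AC", "A")
        bases, indel = sf.materialize_haplotype(ref, [v])
        assert len(bases) == ref.window.length
        assert "".join("ACGT"[i] for i in bases) == ref.sequence
        assert indel[4] and indel.sum() == 1

    def test_same_site_conflict_rejected(self, empty_context):
        ref, _, _ = empty_context
        vs = [sf.VariantRecord("c", 2, "G", "T"),
              sf.VariantRecord("c", 2, "G", "A")]
        with pytest.raises(ValueError, match="overlap"):
            sf.materialize_haplotype(ref, vs)

    def test_overlapping_deletion_rejected(self, empty_context):
        ref, _, _ = empty_context
        vs = [sf.VariantRecord("c", 2, "GT", "G"),
              sf.VariantRecord("c", 3, "T", "C")]
        with pytest.raises(ValueError, match="overlap"):
            sf.materialize_haplotype(ref, vs)

    def test_reference_mismatch_rejected(self, empty_context):
        ref, _, _ = empty_context
        with pytest.raises(ValueError, match="mismatch"):
            sf.materialize_haplotype(ref, [sf.VariantRecord("c", 2, "A", "T")])


class TestAnnotationVector:
    def test_track_bit_at_nonvariant_position(self):
        ref = _ref("ACGTACGTAC")
        tracks = sf.AnnotationTrackSet(ref.window, {"coding": [(0, 5)]})
        flags = sf.VariantFlagTable()
        bits = sf.annotation_vector(2, None, tracks, flags)
        names = EncodingConfig().annotations
        assert bits[names.index("coding")] == 1
        assert bits.sum() == 1

    def test_variant_flags_take_authority(self):
        ref = _ref("ACGTACGTAC")
        tracks = sf.AnnotationTrackSet(ref.window)
        v = sf.VariantRecord("c", 2, "G", "T")
        flags = sf.VariantFlagTable({(2, "G", "T"): (True, True)})
        bits = sf.annotation_vector(2, v, tracks, flags)
        names = EncodingConfig().annotations
        assert bits[names.index("rare")] == 1
        assert bits[names.index("deleterious")] == 1
        assert bits.sum() == 2

    def test_missing_flag_entry_is_an_error(self):
        ref = _ref("ACGTACGTAC")
        tracks = sf.AnnotationTrackSet(ref.window)
        v = sf.VariantRecord("c", 2, "G", "T")
        with pytest.raises(KeyError, match="c:2:G:T"):
            sf.annotation_vector(2, v, tracks, sf.VariantFlagTable())


class TestEncodeHaplotype:
    def test_locus_scale_shape(self, rng):
        seq = "".join(rng.choice(list("ACGT"), size=7417))
        ref = sf.ReferenceWindow(sf.GenomicWindow("chr22", 42_521_567,
                                                  42_528_984), seq)
        tracks = sf.AnnotationTrackSet(ref.window)
        enc = sf.encode_haplotype(ref, [], tracks, sf.VariantFlagTable())
        assert enc.matrix.shape == (7417, 12)

    def test_reference_with_empty_tracks_is_pure_onehot(self, empty_context):
        ref, tracks, flags = empty_context
        enc = sf.encode_haplotype(ref, [], tracks, flags)
        assert (enc.matrix[:, 4:] == 0).all()
        assert (enc.matrix[:, :4].sum(axis=1) == 1).all()

    def test_full13_extends_paper12(self, locus, curated):
        d = curated[0]
        enc12 = sf.encode_haplotype(locus.reference, d.variants, locus.tracks,
                                    locus.flags, EncodingConfig("paper12"))
        enc13 = sf.encode_haplotype(locus.reference, d.variants, locus.tracks,
                                    locus.flags, EncodingConfig("full13"))
        assert enc13.matrix.shape[1] == 13
        assert enc12.matrix.shape[1] == 12
        # the first 12 columns coincide; active_site is the extra column
        np.testing.assert_array_equal(enc12.matrix, enc13.matrix[:, :12])

    def test_variant_only_track_scope(self, locus, curated):
        """With tracks_everywhere off, track bits appear only at variant
        anchors."""
        d = next(d for d in curated
                 if d.function is sf.Function.NONE)  # has a coding variant
        cfg = EncodingConfig(tracks_everywhere=False)
        enc = sf.encode_haplotype(locus.reference, d.variants, locus.tracks,
                                  locus.flags, cfg)
        names = cfg.annotations
        coding = enc.matrix[:, 4 + names.index("coding")]
        anchors = {locus.reference.window.to_local(v.pos)
                   for v in d.variants}
        assert set(np.flatnonzero(coding)) <= anchors
        assert coding.sum() >= 1  # the coding lesion is marked

    def test_locality_against_reference_encoding(self, locus, curated):
        d = curated[0]
        base = sf.encode_haplotype(locus.reference, [], locus.tracks,
                                   locus.flags)
        enc = sf.encode_haplotype(locus.reference, d.variants, locus.tracks,
                                  locus.flags)
        diff_rows = np.flatnonzero((base.matrix != enc.matrix).any(axis=1))
        anchors = {locus.reference.window.to_local(v.pos) for v in d.variants}
        assert set(diff_rows.tolist()) == anchors

    @settings(deadline=None, max_examples=25, derandomize=True)
    @given(data=st.data())
    def test_length_and_onehot_invariants(self, locus, curated, data):
        """Any subset of allele variants keeps L rows and valid one-hot."""
        pool = sorted({v for d in curated for v in d.variants})
        chosen = data.draw(st.lists(st.sampled_from(pool), unique=True,
                                    max_size=6))
        by_pos = {}
        for v in chosen:  # drop site collisions
            by_pos.setdefault(v.pos, v)
        enc = sf.encode_haplotype(locus.reference, list(by_pos.values()),
                                  locus.tracks, locus.flags)
        assert enc.matrix.shape[0] == locus.reference.window.length
        assert (enc.matrix[:, :4].sum(axis=1) == 1).all()
        assert set(np.unique(enc.matrix)) <= {0, 1}


class TestEncodeDiplotype:
    def test_channel_concatenation_shape(self, locus, curated):
        e1 = sf.encode_haplotype(locus.reference, curated[0].variants,
                                 locus.tracks, locus.flags)
        e2 = sf.encode_haplotype(locus.reference, curated[1].variants,
                                 locus.tracks, locus.flags)
        d = sf.encode_diplotype(e1, e2)
        assert d.matrix.shape == (e1.length, 24)
        np.testing.assert_array_equal(d.matrix[:, :12], e1.matrix)
        np.testing.assert_array_equal(d.matrix[:, 12:], e2.matrix)

    def test_duplicated_haplotype_halves_identical(self, locus, curated):
        e = sf.encode_haplotype(locus.reference, curated[0].variants,
                                locus.tracks, locus.flags)
        d = sf.encode_diplotype(e, e)
        np.testing.assert_array_equal(d.matrix[:, :12], d.matrix[:, 12:])

    def test_swap_permutes_halves(self, locus, curated):
        e1 = sf.encode_haplotype(locus.reference, curated[0].variants,
                                 locus.tracks, locus.flags)
        e2 = sf.encode_haplotype(locus.reference, curated[1].variants,
                                 locus.tracks, locus.flags)
        d12 = sf.encode_diplotype(e1, e2)
        d21 = sf.encode_diplotype(e2, e1)
        np.testing.assert_array_equal(d12.matrix[:, :12], d21.matrix[:, 12:])

    def test_shape_mismatch_rejected(self, locus, curated):
        e1 = sf.encode_haplotype(locus.reference, [], locus.tracks,
                                 locus.flags, EncodingConfig("paper12"))
        e2 = sf.encode_haplotype(locus.reference, [], locus.tracks,
                                 locus.flags, EncodingConfig("full13"))
        with pytest.raises(ValueError):
            sf.encode_diplotype(e1, e2)


class TestAnnotationCounts:
    def test_zero_variants_zero_vector(self, locus):
        counts = sf.annotation_counts([], locus.tracks, locus.flags)
        assert counts.shape == (9,)
        assert (counts == 0).all()

    def test_counts_match_flags_and_tracks(self):
        ref = _ref("ACGTACGTACGTACGTACGT")
        tracks = sf.AnnotationTrackSet(ref.window, {"coding": [(0, 10)]})
        flags = sf.VariantFlagTable({
            (2, "G", "T"): (True, False),
            (5, "C", "A"): (True, True),
            (15, "T", "A"): (False, False),
        })
        vs = [sf.VariantRecord("c", 2, "G", "T"),
              sf.VariantRecord("c", 5, "C", "A"),
              sf.VariantRecord("c", 15, "T", "A")]
        counts = sf.annotation_counts(vs, tracks, flags)
        idx = {n: i for i, n in enumerate(sf.ANNOTATION_NAMES)}
        assert counts[idx["rare"]] == 2
        assert counts[idx["deleterious"]] == 1
        assert counts[idx["coding"]] == 2
        assert counts[idx["indel"]] == 0

    def test_order_invariance(self, locus, curated):
        vs = sorted({v for d in curated[:3] for v in d.variants})
        fwd = sf.annotation_counts(vs, locus.tracks, locus.flags)
        rev = sf.annotation_counts(vs[::-1], locus.tracks, locus.flags)
        np.testing.assert_array_equal(fwd, rev)
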