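import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from antioxpred.features import (
    CTD_DIM,
    HYBRID_DIM,
    PSSM_DIM,
    RSA_DIM,
    SSI_DIM,
    encode_ctd,
    encode_hybrid,
    encode_pssm400,
    encode_rsa,
    encode_ssi,
    segments,
)
from antioxpred.io_formats import (
    AMINO_ACIDS,
    ProteinRecord,
    PssmMatrix,
    RsaAnnotation,
    SsAnnotation,
)

ss_strings = st.text(alphabet="HEC", min_size=2, max_size=60)
aa_strings = st.text(alphabet=AMINO_ACIDS, min_size=2, max_size=60)


def by_name(fv):
    return dict(zip(fv.names, fv.values))


class TestSegments:
    def test_runs_tile_string(self):
        runs = segments("HHECCC")
        assert runs == [("H", 1, 2), ("E", 3, 1), ("C", 4, 3)]

    @given(ss_strings)
    @settings(deadline=None)
    def test_runs_conserve_counts_and_alternate(self, s):
        runs = segments(s)
        assert sum(r[2] for r in runs) == len(s)
        assert all(a[0] != b[0] for a, b in zip(runs, runs[1:]))


class TestSsi:
    def test_single_state_hand_example(self):
        f = by_name(encode_ssi(SsAnnotation("HHHH")))
        assert f["ssi.content.H"] == 1.0 and f["ssi.content.E"] == 0.0
        assert f["ssi.trans.HH"] == 1.0
        assert sum(v for k, v in f.items() if k.startswith("ssi.trans.") and k != "ssi.trans.HH") == 0
        assert f["ssi.avgseg.H"] == 4.0 and f["ssi.nmaxseg.H"] == 1.0
        assert f["ssi.avgseg.E"] == f["ssi.nmaxseg.C"] == 0.0
        assert f["ssi.order.H"] == pytest.approx((1 + 2 + 3 + 4) / (4 * 3))
        assert f["ssi.order.E"] == f["ssi.order.C"] == 0.0

    def test_three_state_hand_example(self):
        f = by_name(encode_ssi(SsAnnotation("HEC")))
        for s in "HEC":
            assert f[f"ssi.content.{s}"] == pytest.approx(1 / 3)
            assert f[f"ssi.avgseg.{s}"] == 1.0
            assert f[f"ssi.nmaxseg.{s}"] == pytest.approx(1 / 3)
        assert f["ssi.trans.HE"] == f["ssi.trans.EC"] == 0.5
        assert f["ssi.order.H"] == pytest.approx(1 / 6)
        assert f["ssi.order.E"] == pytest.approx(2 / 6)
        assert f["ssi.order.C"] == pytest.approx(3 / 6)

    def test_length_one_rejected(self):
        with pytest.raises(ValueError):
            encode_ssi(SsAnnotation("H"))

    @given(ss_strings)
    @settings(deadline=None)
    def test_content_and_transition_sums(self, s):
        fv = encode_ssi(SsAnnotation(s))
        assert len(fv) == SSI_DIM
        f = by_name(fv)
        content = sum(f[f"ssi.content.{x}"] for x in "HEC")
        trans = sum(v for k, v in f.items() if k.startswith("ssi.trans."))
        assert content == pytest.approx(1.0)
        assert trans == pytest.approx(1.0)

    @given(ss_strings)
    @settings(deadline=None)
    def test_segment_lengths_conserve_element_counts(self, s):
        f = by_name(encode_ssi(SsAnnotation(s)))
        for x in "HEC":
            n_runs = sum(1 for r in segments(s) if r[0] == x)
            assert f[f"ssi.avgseg.{x}"] * n_runs == pytest.approx(s.count(x))


class TestRsa:
    def test_uniform_exposed_hand_example(self):
        rec = ProteinRecord("p", "AAAA")
        rsa = RsaAnnotation((0.5, 0.5, 0.5, 0.5), threshold=0.25)
        f = by_name(encode_rsa(rsa, rec))
        assert f["rsa.mean"] == 0.5 and f["rsa.std"] == 0.0
        assert f["rsa.nseg.exposed"] == 1 and f["rsa.nseg.buried"] == 0
        assert f["rsa.minseg.exposed"] == f["rsa.maxseg.exposed"] == 4
        assert f["rsa.minseg.buried"] == f["rsa.maxseg.buried"] == 0
        assert f["rsa.aamean.A"] == 0.5
        assert all(f[f"rsa.aamean.{a}"] == 0.0 for a in AMINO_ACIDS if a != "A")

    def test_all_buried_degenerate_case(self):
        rec = ProteinRecord("p", "ACDE")
        f = by_name(encode_rsa(RsaAnnotation((0.0,) * 4), rec))
        assert f["rsa.nseg.buried"] == 1
        assert f["rsa.maxseg.buried"] == 4
        assert f["rsa.nseg.exposed"] == f["rsa.minseg.exposed"] == 0

    def test_threshold_is_inclusive_for_exposed(self):
        rec = ProteinRecord("p", "AA")
        f = by_name(encode_rsa(RsaAnnotation((0.25, 0.24), threshold=0.25), rec))
        assert f["rsa.nseg.exposed"] == 1 and f["rsa.nseg.buried"] == 1

    @given(st.lists(st.floats(0, 1), min_size=2, max_size=40))
    @settings(deadline=None)
    def test_dimension_and_finiteness(self, values):
        rec = ProteinRecord("p", "A" * len(values))
        fv = encode_rsa(RsaAnnotation(tuple(values)), rec)
        assert len(fv) == RSA_DIM
        assert np.all(np.isfinite(fv.values))


class TestCtd:
    def test_homopolymer_hand_example(self):
        f = by_name(encode_ctd(ProteinRecord("p", "AAAA")))
        assert f["ctd.c.A"] == 1.0
        assert all(v == 0 for k, v in f.items() if k.startswith("ctd.t."))
        d = [f[f"ctd.d.A.{q}"] for q in ("p0", "p25", "p50", "p75", "p100")]
        assert d == [0.25, 0.25, 0.50, 0.75, 1.0]

    def test_alternating_hand_example(self):
        f = by_name(encode_ctd(ProteinRecord("p", "ACAC")))
        assert f["ctd.c.A"] == f["ctd.c.C"] == 0.5
        assert f["ctd.t.AC"] == 1.0
        d = [f[f"ctd.d.A.{q}"] for q in ("p0", "p25", "p50", "p75", "p100")]
        assert d == [0.25, 0.25, 0.25, 0.75, 0.75]

    @given(aa_strings)
    @settings(deadline=None)
    def test_composition_sums_to_one_and_transition_bounded(self, seq):
        fv = encode_ctd(ProteinRecord("p", seq))
        assert len(fv) == CTD_DIM
        f = by_name(fv)
        comp = sum(f[f"ctd.c.{a}"] for a in AMINO_ACIDS)
        trans = sum(v for k, v in f.items() if k.startswith("ctd.t."))
        assert comp == pytest.approx(1.0)
        assert trans <= 1.0 + 1e-12

    @given(aa_strings)
    @settings(deadline=None)
    def test_distribution_tuples_monotone_in_unit_range(self, seq):
        f = by_name(encode_ctd(ProteinRecord("p", seq)))
        L = len(seq)
        for a in AMINO_ACIDS:
            d = [f[f"ctd.d.{a}.{q}"] for q in ("p0", "p25", "p50", "p75", "p100")]
            if seq.count(a) == 0:
                assert d == [0.0] * 5
            else:
                assert all(x <= y + 1e-12 for x, y in zip(d, d[1:]))
                assert all(1 / L - 1e-12 <= x <= 1.0 + 1e-12 for x in d)


class TestPssm400:
    def test_zero_matrix(self):
        fv = encode_pssm400(PssmMatrix("AC", np.zeros((2, 20), dtype=int)))
        assert len(fv) == PSSM_DIM
        assert np.all(fv.values == 0)

    def test_rows_summed_per_residue(self):
        rng = np.random.default_rng(1)
        scores = rng.integers(-5, 6, size=(3, 20))
        fv = encode_pssm400(PssmMatrix("AAC", scores))
        M = fv.values.reshape(20, 20)
        np.testing.assert_array_equal(M[0], scores[0] + scores[1])  # A row
        np.testing.assert_array_equal(M[1], scores[2])  # C row
        assert np.all(M[2:] == 0)

    def test_additive_over_profile_split(self):
        rng = np.random.default_rng(2)
        seq = "ACDEACDE"
        scores = rng.integers(-7, 8, size=(8, 20))
        whole = encode_pssm400(PssmMatrix(seq, scores)).values
        first = encode_pssm400(PssmMatrix(seq[:4], scores[:4])).values
        second = encode_pssm400(PssmMatrix(seq[4:], scores[4:])).values
        np.testing.assert_allclose(whole, first + second)


class TestHybrid:
    def test_dimension_and_group_layout(self, record4):
        fv = encode_hybrid(
            record4,
            SsAnnotation("HHEC"),
            RsaAnnotation((0.1, 0.9, 0.5, 0.0)),
            PssmMatrix("ACDE", np.zeros((4, 20), dtype=int)),
        )
        assert len(fv) == HYBRID_DIM
        groups = np.asarray(fv.groups)
        assert (groups[:21] == "SSI").all()
        assert (groups[21:49] == "RSA").all()
        assert (groups[49:359] == "CTD").all()
        assert (groups[359:] == "PSSM").all()

    def test_equals_concatenation_of_components(self, record4):
        ss = SsAnnotation("CCCC")
        rsa = RsaAnnotation((0.5,) * 4)
        pssm = PssmMatrix("ACDE", np.zeros((4, 20), dtype=int))
        fv = encode_hybrid(record4, ss, rsa, pssm)
        expected = np.concatenate([
            encode_ssi(ss).values,
            encode_rsa(rsa, record4).values,
            encode_ctd(record4).values,
            encode_pssm400(pssm).values,
        ])
        np.testing.assert_array_equal(fv.values, expected)

    def test_misaligned_channels_name_the_record(self, record4):
        with pytest.raises(ValueError, match="p1"):
            encode_hybrid(
                record4,
                SsAnnotation("HHE"),
                RsaAnnotation((0.5,) * 4),
                PssmMatrix("ACDE", np.zeros((4, 20), dtype=int)),
            )
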