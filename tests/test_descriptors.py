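"""Descriptor encoders: worked examples, normalization identities, and
equivalence with naive brute-force transcriptions of the defining
formulas."""

import numpy as np
import pytest

import oracles
from conftest import make_dataset

from augur import (
    DescriptorConfig,
    composition_report,
    encode_aac,
    encode_apaac,
    encode_asdc,
    encode_cksaap,
    encode_ctd,
    encode_dde,
    encode_fused,
    encode_qso,
)
from augur._tables import (
    ALPHABET,
    CODON_COUNTS,
    CODON_TOTAL,
    CTD_PROPERTIES_13,
    GRANTHAM,
    H1,
    H2,
    HYDROPHILICITY_RAW,
    HYDROPHOBICITY_RAW,
    PHYSCHEM,
)
from augur.descriptors import EncodingLengthError


class TestTables:
    def test_codon_counts_standard_code(self):
        assert CODON_TOTAL == 61
        assert CODON_COUNTS["A"] == 4 and CODON_COUNTS["C"] == 2
        assert CODON_COUNTS["L"] == 6 and CODON_COUNTS["W"] == 1

    def test_hydropathy_scales_standardized(self):
        for scale in (H1, H2):
            assert abs(scale.mean()) < 1e-12
            assert abs(scale.std() - 1.0) < 1e-12

    @pytest.mark.parametrize("mat", [GRANTHAM, PHYSCHEM], ids=["grantham", "physchem"])
    def test_distance_matrix_invariants(self, mat):
        assert mat.shape == (20, 20)
        assert np.allclose(mat, mat.T)
        assert np.allclose(np.diag(mat), 0.0)
        assert (mat >= 0).all()

    def test_grantham_known_extremes(self):
        # cysteine/tryptophan is famously the largest distance (~215),
        # leucine/isoleucine among the smallest (~5)
        c, w = ALPHABET.index("C"), ALPHABET.index("W")
        l, i = ALPHABET.index("L"), ALPHABET.index("I")
        assert GRANTHAM[c, w] == GRANTHAM.max()
        assert 205 < GRANTHAM[c, w] < 225
        assert GRANTHAM[l, i] < 10

    def test_ctd_groupings_partition_alphabet(self):
        for groups in CTD_PROPERTIES_13.values():
            assert sorted("".join(groups)) == sorted(ALPHABET)


class TestWorkedExamples:
    def test_aac_homopolymer(self):
        v = encode_aac("AAAAA")
        assert v[0] == 1.0 and v[1:].sum() == 0.0

    def test_aac_uniform(self):
        v = encode_aac("ACDEF")
        assert np.allclose(v[:5], 0.2) and v[5:].sum() == 0

    def test_cksaap_homopolymer_gap0(self):
        v = encode_cksaap("AAAAA", kmax=0)
        assert v[0] == 1.0 and v.sum() == 1.0

    def test_cksaap_gap1_by_hand(self):
        # "ACACA" gap 1: pairs (A,A),(C,C),(A,A) -> f(AA)=2/3, f(CC)=1/3
        v = encode_cksaap("ACACA", kmax=1)[400:]
        aa = ALPHABET.index("A") * 20 + ALPHABET.index("A")
        cc = ALPHABET.index("C") * 20 + ALPHABET.index("C")
        assert v[aa] == pytest.approx(2 / 3)
        assert v[cc] == pytest.approx(1 / 3)
        assert v.sum() == pytest.approx(1.0)

    def test_cksaap_too_short(self):
        with pytest.raises(EncodingLengthError):
            encode_cksaap("ACDEF", kmax=4)

    def test_dde_single_dipeptide(self):
        # "AC...": D_c(A,C)=1/(L-1) at L=2 would be 1; check via the
        # standardization identity on a padded valid-length sequence
        tm_ac = (4 / 61) * (2 / 61)
        assert tm_ac == pytest.approx(8 / 3721)
        v = encode_dde("ACACA")
        idx = ALPHABET.index("A") * 20 + ALPHABET.index("C")
        dc = 2 / 4
        tv = tm_ac * (1 - tm_ac) / 4
        assert v[idx] == pytest.approx((dc - tm_ac) / np.sqrt(tv))

    def test_apaac_homopolymer_taus(self):
        # lag-constant sequence: every tau_{2k-1}=H1(A)^2, tau_{2k}=H2(A)^2
        lam, w = 2, 0.5
        a = ALPHABET.index("A")
        taus = [H1[a] ** 2, H2[a] ** 2] * lam
        denom = 1.0 + w * sum(taus)
        v = encode_apaac("AAAAAA", lam, w)
        assert v[a] == pytest.approx(1.0 / denom)
        assert v[20:] == pytest.approx(np.array(taus) * w / denom)

    def test_apaac_weight_zero_limit_is_aac(self):
        seq = "RRGKLY"
        v = encode_apaac(seq, 2, 1e-300)
        assert np.allclose(v[:20], encode_aac(seq), atol=1e-12)
        assert np.allclose(v[20:], 0.0)

    def test_asdc_by_hand(self):
        # "ACA": skip pairs AC, AA, CA once each
        v = encode_asdc("ACA")
        nz = {i: x for i, x in enumerate(v) if x}
        a, c = ALPHABET.index("A"), ALPHABET.index("C")
        assert nz == {
            a * 20 + c: pytest.approx(1 / 3),
            a * 20 + a: pytest.approx(1 / 3),
            c * 20 + a: pytest.approx(1 / 3),
        }

    def test_asdc_homopolymer(self):
        v = encode_asdc("AAAA")
        assert v[0] == 1.0 and v.sum() == 1.0

    def test_ctd_single_group_sequence(self):
        # all-K sequence is entirely group 1 of the charge property
        props = {"charge": CTD_PROPERTIES_13["charge"]}
        v = encode_ctd("KKKKK", props)
        comp, trans, dist = v[:3], v[3:6], v[6:]
        assert list(comp) == [1.0, 0.0, 0.0]
        assert list(trans) == [0.0, 0.0, 0.0]
        assert dist[0] == pytest.approx(1 / 5)  # first occurrence
        assert dist[4] == pytest.approx(1.0)  # 100% occurrence
        assert dist[5:].sum() == 0.0

    def test_ctd_transition_by_hand(self):
        # "ADADA" with A in group 1 and D in group 2 encodes as 12121:
        # every adjacent pair is a 1<->2 transition, so T(1,2) = 4/4
        props = {"toy": ("ACFGHILMNPQSTVWY", "DE", "KR")}
        v = encode_ctd("ADADA", props)
        trans = v[3:6]
        assert trans[0] == pytest.approx(4 / 4)  # T(1,2)
        assert trans[1] == 0.0 and trans[2] == 0.0

    def test_ctd_rejects_non_partition(self):
        with pytest.raises(ValueError, match="partition"):
            encode_ctd("ADADA", {"broken": ("ACDEF", "GHIKL", "MNPQR")})

    def test_qso_homopolymer(self):
        v = encode_qso("AAAAA")
        a = ALPHABET.index("A")
        for block in (v[:22], v[22:]):
            assert block[a] == pytest.approx(1.0)
            assert block.sum() == pytest.approx(1.0)

    def test_qso_block_sums(self, rng):
        for _ in range(10):
            seq = oracles.random_sequence(rng)
            v = encode_qso(seq)
            assert v[:22].sum() == pytest.approx(1.0, abs=1e-9)
            assert v[22:].sum() == pytest.approx(1.0, abs=1e-9)


# closed-form dimension and normalization identities -----------------------


@pytest.mark.parametrize(
    "encoder,dim",
    [
        (encode_aac, 20),
        (lambda s: encode_cksaap(s, 3), 1600),
        (encode_dde, 400),
        (lambda s: encode_apaac(s, 2, 0.5), 24),
        (encode_asdc, 400),
        (encode_ctd, 273),
        (lambda s: encode_qso(s, 2, 0.05), 44),
    ],
    ids=["aac", "cksaap", "dde", "apaac", "asdc", "ctd", "qso"],
)
def test_default_dimensions(encoder, dim, rng):
    seq = oracles.random_sequence(rng)
    assert len(encoder(seq)) == dim


def test_dimension_formulas_random_configs(rng):
    for _ in range(20):
        cfg = DescriptorConfig(
            cksaap_kmax=int(rng.integers(0, 4)),
            apaac_lambda=int(rng.integers(1, 5)),
            qso_nlag=int(rng.integers(1, 5)),
            ctd_property_set=str(rng.choice(["7", "13"])),
        )
        seq = oracles.random_sequence(rng, lo=10)
        dims = cfg.dimensions
        assert len(encode_cksaap(seq, cfg.cksaap_kmax)) == dims["CKSAAP"]
        assert len(encode_apaac(seq, cfg.apaac_lambda)) == dims["APAAC"]
        assert len(encode_qso(seq, cfg.qso_nlag)) == dims["QSO"]
        assert len(encode_ctd(seq, cfg.ctd_properties)) == dims["CTD"]
        assert cfg.fused_dimension == sum(dims.values())


def test_normalization_identities(rng):
    for _ in range(25):
        seq = oracles.random_sequence(rng)
        assert encode_aac(seq).sum() == pytest.approx(1.0, abs=1e-9)
        assert encode_cksaap(seq, 3).sum() == pytest.approx(4.0, abs=1e-9)
        assert encode_asdc(seq).sum() == pytest.approx(1.0, abs=1e-9)


def test_order_sensitivity(rng):
    """Permuting a sequence preserves AAC but generally changes the
    order-aware encoders."""
    seq = "ARNDCEQGHILKMFPSTWYVAR"
    perm = "".join(rng.permutation(list(seq)))
    assert np.allclose(encode_aac(seq), encode_aac(perm))
    assert not np.allclose(encode_cksaap(seq, 3), encode_cksaap(perm, 3))
    assert not np.allclose(encode_apaac(seq, 2, 0.5), encode_apaac(perm, 2, 0.5))
    assert not np.allclose(encode_qso(seq), encode_qso(perm))


# brute-force oracle equivalence -------------------------------------------


def test_encoders_match_bruteforce_oracles(rng):
    h1 = dict(zip(ALPHABET, H1))
    h2 = dict(zip(ALPHABET, H2))
    for _ in range(100):
        seq = oracles.random_sequence(rng)
        np.testing.assert_allclose(encode_aac(seq), oracles.aac(seq), atol=1e-9)
        np.testing.assert_allclose(
            encode_cksaap(seq, 3), oracles.cksaap(seq, 3), atol=1e-9
        )
        np.testing.assert_allclose(
            encode_dde(seq), oracles.dde(seq, CODON_COUNTS), atol=1e-9
        )
        np.testing.assert_allclose(
            encode_apaac(seq, 2, 0.5), oracles.apaac(seq, 2, 0.5, h1, h2), atol=1e-9
        )
        np.testing.assert_allclose(encode_asdc(seq), oracles.asdc(seq), atol=1e-9)
        np.testing.assert_allclose(
            encode_ctd(seq), oracles.ctd(seq, CTD_PROPERTIES_13), atol=1e-9
        )
        np.testing.assert_allclose(
            encode_qso(seq), oracles.qso(seq, 2, 0.05, [PHYSCHEM, GRANTHAM]),
            atol=1e-9,
        )


class TestFusion:
    def test_fused_default_2761(self, small_dataset):
        X = encode_fused(small_dataset)
        assert X.shape == (len(small_dataset), 2761)
        assert X.columns[0] == "AAC_1"
        assert X.columns[-1] == "QSO_44"
        assert list(X.index) == small_dataset.ids
        assert np.isfinite(X.to_numpy()).all()

    def test_fused_deterministic(self, small_dataset):
        X1 = encode_fused(small_dataset)
        X2 = encode_fused(small_dataset)
        assert X1.equals(X2)

    def test_family_order_fixed(self, small_dataset):
        X = encode_fused(small_dataset, families=["QSO", "AAC"])
        # fixed fusion order, regardless of request order
        assert list(X.columns[:20]) == [f"AAC_{i}" for i in range(1, 21)]

    def test_error_names_record(self):
        data = make_dataset(["ACDEF"])  # length 5 < nlag needs > 10
        cfg = DescriptorConfig(qso_nlag=10)
        with pytest.raises(EncodingLengthError, match="p1"):
            encode_fused(data, cfg, families=["QSO"])


class TestCompositionReport:
    def test_extreme_composition(self):
        pos = make_dataset(["RRRRR"] * 3, "positive", "p")
        neg = make_dataset(["GGGGG"] * 3, "negative", "n")
        rep = composition_report(pos, neg)
        assert rep.loc["R", "difference"] == pytest.approx(1.0)
        assert rep.loc["G", "difference"] == pytest.approx(-1.0)
        assert rep["positive"].sum() == pytest.approx(1.0)
        assert rep["negative"].sum() == pytest.approx(1.0)

    def test_identical_classes_zero_difference(self):
        pos = make_dataset(["ACDEF", "RRGKL"], "positive", "p")
        neg = make_dataset(["ACDEF", "RRGKL"], "negative", "n")
        rep = composition_report(pos, neg)
        assert np.allclose(rep["difference"], 0.0)

    def test_generator_enrichment(self, small_dataset):
        pos = small_dataset.subset(
            [i for i, r in enumerate(small_dataset) if r.label == "positive"]
        )
        neg = small_dataset.subset(
            [i for i, r in enumerate(small_dataset) if r.label == "negative"]
        )
        rep = composition_report(pos, neg)
        assert rep.loc["R", "difference"] > 0.02
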