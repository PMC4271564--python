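import numpy as np
import pytest
from hypothesis import given, strategies as st

from seqbind._alphabet import CANONICAL_AA, CANONICAL_INDEX
from seqbind.features import (
    FeatureMatrix,
    ProfileMatrix,
    PropertyScale,
    PropertySet,
    encode_chain,
    parse_aaindex,
    parse_pssm,
    property_std_profile,
    pseudo_profile,
    select_properties,
    write_pssm,
)

from conftest import random_property_set


def make_scale(accession, values):
    return PropertyScale(accession, "test", tuple(values))


class TestAAindexParsing:
    def test_fixture_entries(self, aaindex_text):
        scales = parse_aaindex(aaindex_text)
        # the NA-containing entry is dropped under the default policy
        assert [s.accession for s in scales] == ["TEST000101", "TEST000301"]
        # Kyte-Doolittle-style values land at the right canonical positions
        kd = scales[0]
        assert kd.values[CANONICAL_INDEX["A"]] == pytest.approx(1.80)
        assert kd.values[CANONICAL_INDEX["R"]] == pytest.approx(-4.50)
        assert kd.values[CANONICAL_INDEX["V"]] == pytest.approx(4.20)
        assert kd.values[CANONICAL_INDEX["L"]] == pytest.approx(3.80)

    def test_na_mean_imputation(self, aaindex_text):
        scales = parse_aaindex(aaindex_text, na_policy="mean")
        assert len(scales) == 3
        na_scale = [s for s in scales if s.accession == "TEST000201"][0]
        others = [v for aa, v in zip(CANONICAL_AA, na_scale.values) if aa != "N"]
        assert na_scale.values[CANONICAL_INDEX["N"]] == pytest.approx(np.mean(others))

    def test_empty_file(self):
        assert parse_aaindex("") == []

    def test_malformed_block_errors(self):
        bad = "H BADENTRY\nD broken\nI    A/L\n  1.0 2.0\n  3.0\n//\n"
        with pytest.raises(ValueError, match="BADENTRY"):
            parse_aaindex(bad)


class TestPropertySelection:
    def test_duplicate_pair_collapses(self):
        rng = np.random.default_rng(0)
        a = rng.standard_normal(20)
        c = rng.standard_normal(20)
        # force |CC(a, c)| below threshold
        c -= a * np.corrcoef(a, c)[0, 1] * np.std(c) / np.std(a)
        scales = [make_scale("AAA", a), make_scale("BBB", 2 * a + 1), make_scale("CCC", c)]
        result = select_properties(scales, threshold=0.5)
        assert len(result) == 2
        kept = set(result.accessions)
        assert "CCC" in kept
        assert len(kept & {"AAA", "BBB"}) == 1

    def test_unrelated_scales_all_survive(self):
        props = random_property_set(6, seed=1)
        cc = np.corrcoef(props.matrix)
        assume_ok = (np.abs(cc - np.eye(6)) < 0.5).all()
        assert assume_ok, "fixture scales must be mutually unrelated"
        result = select_properties(props.scales, threshold=0.5)
        assert set(result.accessions) == set(props.accessions)

    def test_negation_counts_as_related(self):
        rng = np.random.default_rng(2)
        a = rng.standard_normal(20)
        result = select_properties([make_scale("POS", a), make_scale("NEG", -a)], threshold=0.5)
        assert len(result) == 1

    def test_fixed_point(self):
        rng = np.random.default_rng(3)
        base = [rng.standard_normal(20) for _ in range(4)]
        scales = []
        for i, b in enumerate(base):
            scales.append(make_scale(f"S{i}A", b))
            scales.append(make_scale(f"S{i}B", b + 0.05 * rng.standard_normal(20)))
        once = select_properties(scales, threshold=0.5)
        twice = select_properties(once.scales, threshold=0.5)
        assert once.accessions == twice.accessions

    def test_constant_scale_dropped_with_warning(self):
        rng = np.random.default_rng(4)
        scales = [make_scale("FLAT", np.ones(20)), make_scale("VAR", rng.standard_normal(20))]
        with pytest.warns(UserWarning, match="FLAT"):
            result = select_properties(scales)
        assert result.accessions == ("VAR",)

    def test_all_constant_errors(self):
        with pytest.raises(ValueError):
            select_properties([make_scale("F1", np.ones(20)), make_scale("F2", np.zeros(20))])


PSSM_HEADER = (
    "\nLast position-specific scoring matrix computed\n"
    "         " + " ".join(f"{a:>3}" for a in "ARNDCQEGHILKMFPSTWYV") * 2 + "\n"
)


def pssm_row(idx, aa, pcts):
    lod = " ".join(" 0" for _ in range(20))
    pct = " ".join(f"{p:>3d}" for p in pcts)
    return f"{idx:>5d} {aa}  {lod}  {pct}  0.50 0.25"


class TestPSSMParsing:
    def test_percentage_rows(self):
        pcts_f = [0] * 20
        # PSSM column order A R N D C Q E G H I L K M F P S T W Y V:
        # put 59 under C (index 4) and 41 under I (index 9)
        pcts_f[4], pcts_f[9] = 59, 41
        one_hot_g = [0] * 20
        one_hot_g[7] = 100  # column G
        text = PSSM_HEADER + "\n".join(
            [pssm_row(1, "G", one_hot_g), pssm_row(2, "C", pcts_f), pssm_row(3, "A", [0] * 20)]
        )
        prof = parse_pssm(text)
        assert len(prof) == 3
        np.testing.assert_allclose(prof.matrix.sum(axis=1), 1.0, atol=1e-9)
        assert prof.matrix[0, CANONICAL_INDEX["G"]] == pytest.approx(1.0)
        assert prof.matrix[1, CANONICAL_INDEX["C"]] == pytest.approx(0.59)
        assert prof.matrix[1, CANONICAL_INDEX["I"]] == pytest.approx(0.41)
        # all-zero row falls back to the one-hot of the query residue
        assert prof.matrix[2, CANONICAL_INDEX["A"]] == pytest.approx(1.0)

    def test_length_check(self):
        text = PSSM_HEADER + pssm_row(1, "A", [100] + [0] * 19)
        with pytest.raises(ValueError, match="declares"):
            parse_pssm(text, expected_length=5)

    def test_non_numeric_cell(self):
        row = pssm_row(1, "A", [100] + [0] * 19).replace("100", "1x0")
        with pytest.raises(ValueError, match="line"):
            parse_pssm(PSSM_HEADER + row)

    def test_write_parse_roundtrip(self, tmp_path):
        rng = np.random.default_rng(8)
        mat = rng.dirichlet(np.ones(20), size=12)
        prof = ProfileMatrix(matrix=mat, source="pseudo", sequence="ACDEFGHIKLMN")
        path = tmp_path / "test.pssm"
        write_pssm(prof, path, decimals=9)
        back = parse_pssm(path.read_text())
        np.testing.assert_allclose(back.matrix, mat, atol=1e-9)
        assert back.sequence == prof.sequence

    def test_integer_quantized_roundtrip(self, tmp_path):
        rng = np.random.default_rng(9)
        mat = rng.dirichlet(np.full(20, 0.5), size=5)
        prof = ProfileMatrix(matrix=mat, sequence="ACDEF")
        path = tmp_path / "q.pssm"
        write_pssm(prof, path, decimals=0)
        back = parse_pssm(path.read_text())
        np.testing.assert_allclose(back.matrix, mat, atol=1e-2)


class TestPseudoProfile:
    def test_zero_eps_is_one_hot(self):
        prof = pseudo_profile("A", eps=0.0)
        expected = np.zeros(20)
        expected[CANONICAL_INDEX["A"]] = 1.0
        np.testing.assert_allclose(prof.matrix[0], expected)

    def test_rows_stochastic(self):
        prof = pseudo_profile("ACDEFGHIKLMNPQRSTVWYX")
        np.testing.assert_allclose(prof.matrix.sum(axis=1), 1.0, atol=1e-9)

    def test_x_is_uniform(self):
        prof = pseudo_profile("X")
        np.testing.assert_allclose(prof.matrix[0], 0.05)

    def test_empty_sequence(self):
        with pytest.raises(ValueError):
            pseudo_profile("")


class TestEncoding:
    def test_dimensionality_238(self):
        props = random_property_set(34)
        prof = pseudo_profile("ACDEFGHIKL")
        fm = encode_chain(prof, props, window=7)
        assert fm.values.shape == (10, 238)

    def test_uniform_row_scales_property_std(self):
        props = random_property_set(3)
        prof = ProfileMatrix(matrix=np.full((1, 20), 0.05), sequence="X")
        S = property_std_profile(prof, props)
        for j, scale in enumerate(props.scales):
            assert S[0, j] == pytest.approx(0.05 * np.std(scale.array))

    def test_constant_scale_gives_zero_feature(self):
        props = PropertySet(scales=[PropertyScale("CONST", "", tuple([2.0] * 20))], threshold=0.5)
        # uniform profile x constant scale: all 20 products equal -> std 0
        uniform = ProfileMatrix(matrix=np.full((1, 20), 0.05), sequence="X")
        assert property_std_profile(uniform, props)[0, 0] == pytest.approx(0.0, abs=1e-12)

    def test_one_hot_closed_form(self):
        """std of a vector with one nonzero entry a_r is |a_r|*sqrt(19)/20."""
        props = random_property_set(5, seed=7)
        prof = pseudo_profile("C", eps=0.0)
        S = property_std_profile(prof, props)
        r = CANONICAL_INDEX["C"]
        for j, scale in enumerate(props.scales):
            a_r = scale.array[r]
            expected = abs(a_r) * np.sqrt(19) / 20
            assert S[0, j] == pytest.approx(expected, rel=1e-12)
            # independent direct 20-element computation
            vec = np.zeros(20)
            vec[r] = a_r
            assert S[0, j] == pytest.approx(np.std(vec), rel=1e-12)

    def test_even_window_rejected(self):
        with pytest.raises(ValueError):
            encode_chain(pseudo_profile("ACD"), random_property_set(2), window=4)

    def test_zero_padding_at_termini(self):
        props = random_property_set(2)
        prof = pseudo_profile("ACDEF")
        fm = encode_chain(prof, props, window=5)
        P = 2
        # first residue: offsets -2 and -1 fall off the chain -> zero blocks
        assert (fm.values[0, : 2 * P] == 0).all()
        assert (fm.values[0, 2 * P :] != 0).any()

    @given(st.integers(min_value=0, max_value=10_000))
    def test_permutation_equivariance(self, seed):
        """Permuting the amino-acid axis of profiles and scales together
        leaves the features unchanged."""
        rng = np.random.default_rng(seed)
        perm = rng.permutation(20)
        mat = rng.dirichlet(np.ones(20), size=4)
        props = random_property_set(3, seed=seed + 1)
        fm = encode_chain(ProfileMatrix(matrix=mat), props, window=3)
        props_p = PropertySet(
            scales=[PropertyScale(s.accession, s.description, tuple(s.array[perm]))
                    for s in props.scales],
            threshold=0.5,
        )
        fm_p = encode_chain(ProfileMatrix(matrix=mat[:, perm]), props_p, window=3)
        np.testing.assert_allclose(fm.values, fm_p.values, atol=1e-12)

    @given(st.floats(min_value=-10, max_value=10, allow_nan=False))
    def test_homogeneity(self, c):
        """Multiplying one scale by c multiplies its features by |c|."""
        props = random_property_set(1, seed=3)
        scaled = PropertySet(
            scales=[PropertyScale("SCL", "", tuple(c * props.scales[0].array))],
            threshold=0.5,
        )
        prof = pseudo_profile("ACDEFG")
        base = encode_chain(prof, props, window=3).values
        mult = encode_chain(prof, scaled, window=3).values
        np.testing.assert_allclose(mult, abs(c) * base, atol=1e-9)

    def test_features_nonnegative_and_shaped(self):
        for w, p in [(3, 2), (5, 4), (9, 7)]:
            props = random_property_set(p, seed=w)
            fm = encode_chain(pseudo_profile("ACDEFGHIKLMN"), props, window=w)
            assert fm.values.shape == (12, w * p)
            assert (fm.values >= 0).all()

    def test_fingerprint_tracks_layout(self):
        props = random_property_set(3)
        prof = pseudo_profile("ACDEF")
        a = encode_chain(prof, props, window=5)
        b = encode_chain(prof, props, window=7)
        assert a.fingerprint != b.fingerprint
        assert a.fingerprint == encode_chain(prof, props, window=5).fingerprint
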