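"""SMILES parsing, tokenization, descriptors, fingerprints and I/O."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from hitgen.chem import (
    DescriptorError,
    FingerprintVector,
    canonicalize,
    compute_descriptors,
    ecfp,
    filter_training_set,
    read_smiles_file,
    sas_score,
    tanimoto,
    write_smiles_file,
)
from hitgen.fixtures import FixtureSpec, make_corpus
from hitgen.tokenizer import (
    EOS,
    GO,
    PAD,
    UNK,
    TokenVocabulary,
    decode,
    detokenize,
    pad_encode,
    tokenize,
)


def greedy_longest_match(smiles, tokens):
    """Reference tokenizer: scan left to right, take the longest match."""
    out, pos = [], 0
    by_len = sorted(tokens, key=len, reverse=True)
    while pos < len(smiles):
        for t in by_len:
            if smiles.startswith(t, pos):
                out.append(t)
                pos += len(t)
                break
        else:
            out.append(UNK)
            pos += 1
    return out


class TestCanonicalize:
    def test_same_molecule_one_canonical_form(self):
        assert canonicalize("OCC").smiles_canonical == canonicalize("CCO").smiles_canonical

    def test_unbalanced_parenthesis_invalid(self):
        rec = canonicalize("C(")
        assert not rec.valid
        assert rec.smiles_raw == "C("
        assert rec.smiles_canonical is None

    def test_benzene_valid(self):
        assert canonicalize("c1ccccc1").valid

    def test_idempotent(self):
        first = canonicalize("N(C)Cc1ccccc1").smiles_canonical
        assert canonicalize(first).smiles_canonical == first

    def test_empty_string_rejected(self):
        with pytest.raises(ValueError):
            canonicalize("")


class TestTokenize:
    @pytest.mark.parametrize("smiles,expected_len", [
        ("CCO", 3),
        ("ClCBr", 3),          # two-letter halogens are atomic tokens
        ("C/C=C\\C", 7),
        ("[nH]1cccc1", 7),
    ])
    def test_token_counts(self, vocab, smiles, expected_len):
        assert len(tokenize(smiles, vocab)) == expected_len

    def test_matches_greedy_reference_on_corpus(self, vocab, small_corpus):
        chem_tokens = [t for t in vocab.tokens if t not in vocab.specials]
        for s in small_corpus[:100]:
            assert tokenize(s, vocab) == greedy_longest_match(s, chem_tokens)

    def test_stereo_bond_tokens_distinct(self, vocab):
        toks = tokenize("C/C=C\\C", vocab)
        assert "/" in toks and "\\" in toks

    def test_concatenation_reproduces_input(self, vocab, small_corpus):
        for s in small_corpus[:50]:
            assert detokenize(tokenize(s, vocab)) == s

    def test_unknown_character_becomes_unk(self, vocab):
        assert UNK in tokenize("C~C", vocab)

    def test_empty_rejected(self, vocab):
        with pytest.raises(ValueError):
            tokenize("", vocab)


class TestVocabulary:
    def test_bijective_with_pad_at_zero(self, vocab):
        assert vocab.tokens[0] == PAD
        assert len(set(vocab.tokens)) == len(vocab.tokens)
        for i, t in enumerate(vocab.tokens):
            assert vocab.index_of[t] == i

    def test_specials_present(self, vocab):
        for t in (PAD, GO, EOS, UNK):
            assert t in vocab.index_of


class TestPadEncode:
    def test_layout(self, vocab):
        enc = pad_encode(["C", "C", "O"], vocab, max_len=5)
        assert len(enc) == 7
        assert enc[0] == vocab.go_idx
        assert enc[4] == vocab.eos_idx
        assert list(enc[5:]) == [vocab.pad_idx, vocab.pad_idx]

    def test_empty_sequence(self, vocab):
        enc = pad_encode([], vocab, max_len=3)
        assert enc[0] == vocab.go_idx and enc[1] == vocab.eos_idx
        assert all(i == vocab.pad_idx for i in enc[2:])

    def test_overlong_rejected(self, vocab):
        with pytest.raises(ValueError):
            pad_encode(["C"] * 10, vocab, max_len=5)

    @settings(deadline=None, derandomize=True)
    @given(st.lists(st.sampled_from(["C", "c", "Cl", "Br", "=", "(", ")", "1",
                                     "@@", "/", "[nH]"]), max_size=20))
    def test_round_trip(self, tokens):
        vocab = TokenVocabulary()
        enc = pad_encode(tokens, vocab, max_len=20)
        assert decode(enc, vocab) == tokens


class TestDescriptorsAndFilter:
    def test_mw_of_ethanol(self):
        rec = compute_descriptors(canonicalize("CCO"))
        assert rec.mw == pytest.approx(46.07, abs=0.01)

    def test_sas_in_range_for_corpus(self, small_corpus):
        for s in small_corpus[:30]:
            assert 1.0 <= sas_score(s) <= 10.0

    def test_complexity_orders_sas(self):
        simple = sas_score("CCO")
        complex_ = sas_score("C1CC2CCC1C(C(C2O)O)O")  # fused polycyclic polyol
        assert simple < complex_

    def test_invalid_molecule_raises(self):
        with pytest.raises(DescriptorError):
            compute_descriptors(canonicalize("C("))

    def test_filter_bands_are_closed_intervals(self):
        recs = [canonicalize(s) for s in
                ["c1ccccc1",                       # MW ~78: below the band
                 "CCCCCCCCCCCCC(=O)NCCc1ccccc1"]]  # mid-band
        for r in recs:
            compute_descriptors(r)
        # exact boundary values are retained
        recs[0].mw, recs[0].logp = 200.0, 6.0
        kept = filter_training_set(recs)
        assert recs[0] in kept and recs[1] in kept

    def test_filter_excludes_low_mw_and_invalid(self):
        benzene = compute_descriptors(canonicalize("c1ccccc1"))
        bad = canonicalize("C(")
        assert filter_training_set([benzene, bad]) == []

    def test_filter_output_subset_of_input(self, small_corpus):
        recs = [compute_descriptors(canonicalize(s)) for s in small_corpus[:50]]
        kept = filter_training_set(recs)
        assert set(id(r) for r in kept) <= set(id(r) for r in recs)
        for r in kept:
            assert 200 <= r.mw <= 600 and -2 <= r.logp <= 6


class TestFingerprints:
    def test_deterministic(self):
        rec = canonicalize("Clc1ccc(CNC(=O)C)cc1")
        a = ecfp(rec, 2, 1024)
        b = ecfp(rec, 2, 1024)
        assert np.array_equal(a.bits, b.bits)

    def test_radius_distinguishes_extended_neighborhoods(self):
        a = canonicalize("CCCCCCCO")
        b = canonicalize("CCCCCCCN")
        t4 = tanimoto(ecfp(a, 2, 2048), ecfp(b, 2, 2048))
        t6 = tanimoto(ecfp(a, 3, 2048), ecfp(b, 3, 2048))
        assert t4 != t6

    def test_popcount_positive(self, small_corpus):
        for s in small_corpus[:10]:
            assert ecfp(canonicalize(s), 2, 2048).bits.sum() >= 1

    def test_invalid_molecule_raises(self):
        with pytest.raises(DescriptorError):
            ecfp(canonicalize("C("), 2, 2048)


class TestTanimoto:
    def _fp(self, on_bits, nbits=16):
        bits = np.zeros(nbits, dtype=np.uint8)
        bits[list(on_bits)] = 1
        return FingerprintVector(bits=bits, radius=2, nbits=nbits)

    def test_identical_is_one(self):
        assert tanimoto(self._fp({1, 5}), self._fp({1, 5})) == 1.0

    def test_disjoint_is_zero(self):
        assert tanimoto(self._fp({1, 2}), self._fp({3, 4})) == 0.0

    def test_partial_overlap(self):
        assert tanimoto(self._fp({1, 2}), self._fp({2, 3})) == pytest.approx(1 / 3)

    def test_symmetric_and_bounded(self, rng):
        for _ in range(20):
            a = self._fp(set(rng.choice(16, size=5)))
            b = self._fp(set(rng.choice(16, size=5)))
            assert tanimoto(a, b) == tanimoto(b, a)
            assert 0.0 <= tanimoto(a, b) <= 1.0

    def test_length_mismatch_raises(self):
        with pytest.raises(ValueError):
            tanimoto(self._fp({1}), self._fp({1}, nbits=32))


class TestIO:
    def test_smi_round_trip(self, tmp_path):
        path = tmp_path / "mols.smi"
        path.write_text("CCO\nc1ccccc1 benzene\r\nCCN\n")
        recs = read_smiles_file(str(path))
        assert len(recs) == 3
        assert all(r.valid for r in recs)
        out = tmp_path / "out.smi"
        write_smiles_file(recs, str(out))
        again = read_smiles_file(str(out))
        assert [r.smiles_canonical for r in again] == \
               [r.smiles_canonical for r in recs]

    def test_tokenize_round_trip_large_corpus(self, vocab):
        corpus = make_corpus(FixtureSpec(n=1000, seed=11))
        for s in corpus:
            assert detokenize(tokenize(s, vocab)) == s
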