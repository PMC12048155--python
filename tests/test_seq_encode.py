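"""Tokenization, node attributes, and perturbation strategies."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from resdenoise.errors import ConfigError, ShapeError
from resdenoise.seq_encode import (
    EmbeddingProvider,
    PerturbationSpec,
    bert_mask,
    embed_recode,
    gaussian_perturb,
    one_hot_encode,
    perturb_multinomial,
    residue_frequencies,
)
from resdenoise.vocab import CANONICAL_AAS, DEFAULT_VOCAB, MASK_CHAR

seq_strategy = st.text(alphabet=CANONICAL_AAS, min_size=1, max_size=80)


def random_seq(n, seed=0):
    return "".join(np.random.default_rng(seed).choice(list(CANONICAL_AAS), size=n))


class TestVocabulary:
    def test_33_distinct_tokens_with_mask(self):
        assert DEFAULT_VOCAB.size == 33
        assert DEFAULT_VOCAB.tokens[DEFAULT_VOCAB.mask_index] == "<mask>"

    def test_mask_char_maps_to_mask_token(self):
        assert DEFAULT_VOCAB.index_of(MASK_CHAR) == DEFAULT_VOCAB.mask_index


class TestOneHot:
    def test_rows_are_unit_one_hot(self):
        m = one_hot_encode("ACD")
        assert m.shape == (3, 33)
        assert np.all(m.sum(axis=1) == 1.0)
        assert np.all((m == 0) | (m == 1))

    def test_non_canonical_absorbs_into_x(self):
        assert np.array_equal(one_hot_encode("B")[0], one_hot_encode("X")[0])


class TestMultinomial:
    def test_p_zero_is_identity(self):
        seq = random_seq(200)
        for seed in (0, 1, 2):
            pair = perturb_multinomial(seq, PerturbationSpec(p=0.0), seed)
            assert pair.v_tilde == seq
            assert not pair.changed.any()

    def test_p_one_point_mass(self):
        theta = np.zeros(20)
        theta[CANONICAL_AAS.index("G")] = 1.0
        pair = perturb_multinomial(random_seq(100), PerturbationSpec(p=1.0, theta=theta), 0)
        assert pair.v_tilde == "G" * 100

    def test_changed_fraction_matches_closed_form(self):
        # fraction = p * (1 - sum_a freq(a) * theta(a)); uniform theta -> p*19/20
        seq = random_seq(100_000, seed=3)
        pair = perturb_multinomial(seq, PerturbationSpec(p=0.3), seed=4)
        assert abs(pair.changed.mean() - 0.3 * 19 / 20) < 0.01

    @given(seed=st.integers(0, 10), seq=seq_strategy)
    @settings(max_examples=30, deadline=None, derandomize=True)
    def test_unperturbed_sites_identical(self, seed, seq):
        pair = perturb_multinomial(seq, PerturbationSpec(p=0.4), seed)
        for i in range(len(seq)):
            if not pair.changed[i]:
                assert pair.v_tilde[i] == seq[i]

    def test_invalid_p_raises(self):
        with pytest.raises(ConfigError):
            PerturbationSpec(p=1.5)


class TestMask:
    def test_selected_fraction(self):
        seq = random_seq(100_000, seed=5)
        pair = bert_mask(seq, PerturbationSpec(strategy="mask"), seed=6)
        assert abs(pair.changed.mean() - 0.15) < 0.01

    def test_mask_split_fractions(self):
        masked = randomized = kept = 0
        for seed in range(5):
            seq = random_seq(50_000, seed=100 + seed)
            pair = bert_mask(seq, PerturbationSpec(strategy="mask"), seed=seed)
            for i in np.flatnonzero(pair.changed):
                if pair.v_tilde[i] == MASK_CHAR:
                    masked += 1
                elif pair.v_tilde[i] != seq[i]:
                    randomized += 1
                else:
                    kept += 1
        total = masked + randomized + kept
        assert abs(masked / total - 0.80) < 0.02
        assert abs(randomized / total - 0.10) < 0.02
        assert abs(kept / total - 0.10) < 0.02

    def test_deterministic(self):
        seq = random_seq(500, seed=7)
        spec = PerturbationSpec(strategy="mask")
        a = bert_mask(seq, spec, seed=8)
        b = bert_mask(seq, spec, seed=8)
        assert a.v_tilde == b.v_tilde
        assert np.array_equal(a.changed, b.changed)


class TestGaussian:
    def test_zero_variance_identity(self):
        W = np.random.default_rng(0).normal(size=(50, 8))
        spec = PerturbationSpec(strategy="gaussian", gaussian_variance=0.0)
        assert np.array_equal(gaussian_perturb(W, spec, 1), W)

    def test_noise_variance(self):
        W = np.zeros((1000, 1000))
        spec = PerturbationSpec(strategy="gaussian")
        out = gaussian_perturb(W, spec, 2)
        assert abs((out - W).var() - 0.5) < 0.01

    def test_negative_variance_rejected(self):
        with pytest.raises(ConfigError):
            PerturbationSpec(strategy="gaussian", gaussian_variance=-0.1)

    def test_deterministic(self):
        W = np.zeros((10, 4))
        spec = PerturbationSpec(strategy="gaussian")
        assert np.array_equal(gaussian_perturb(W, spec, 3), gaussian_perturb(W, spec, 3))


class TestEmbedRecode:
    def test_global_average_identical_rows(self):
        seq = "GAGAG"
        W = one_hot_encode(seq)
        changed = np.array([False, False, True, False, False])
        out = embed_recode(W, seq, changed, "global_average")
        assert np.allclose(out[2], W[0])  # mean of identical G rows

    def test_global_average_no_exemplar_warns_and_keeps(self):
        seq = "GACDE"
        W = np.arange(25.0).reshape(5, 5)
        changed = np.array([False, True, False, False, False])
        with pytest.warns(UserWarning):
            out = embed_recode(W, seq, changed, "global_average")
        assert np.array_equal(out[1], W[1])

    def test_sliding_window_interior(self):
        W = np.arange(20.0).reshape(5, 4)
        changed = np.array([False, False, True, False, False])
        out = embed_recode(W, "AAAAA", changed, "sliding_window", window=3)
        assert np.allclose(out[2], W[1:4].mean(axis=0))

    def test_sliding_window_boundary_truncates(self):
        W = np.arange(20.0).reshape(5, 4)
        changed = np.array([True, False, False, False, False])
        out = embed_recode(W, "AAAAA", changed, "sliding_window", window=3)
        assert np.allclose(out[0], W[0:2].mean(axis=0))

    def test_unchanged_rows_bit_identical(self):
        W = np.random.default_rng(1).normal(size=(9, 6))
        changed = np.zeros(9, dtype=bool)
        changed[4] = True
        out = embed_recode(W, "AAAAGAAAA", changed, "sliding_window")
        untouched = np.ones(9, dtype=bool)
        untouched[4] = False
        assert np.array_equal(out[untouched], W[untouched])


class TestEmbeddingProvider:
    def test_one_hot_mode_dim(self):
        p = EmbeddingProvider(mode="one_hot")
        assert p.encode("ACD").shape == (3, 33)

    def test_table_mode_contract(self):
        table = np.ones((3, 5))
        p = EmbeddingProvider(mode="table", dim=5, lookup={"p1": table})
        assert p.encode("ACD", "p1").shape == (3, 5)
        with pytest.raises(ShapeError):
            p.encode("ACDE", "p1")
        with pytest.raises(KeyError):
            p.encode("ACD", "missing")

    def test_table_directory_round_trip(self, tmp_path):
        table = np.random.default_rng(2).normal(size=(4, 6))
        np.savetxt(tmp_path / "prot.tsv", table, delimiter="\t")
        p = EmbeddingProvider.from_directory(str(tmp_path), dim=6)
        assert np.allclose(p.encode("ACDE", "prot"), table)


def test_residue_frequencies_sum_to_one():
    freqs = residue_frequencies(["ACDEG", "GGGG"])
    assert abs(freqs.sum() - 1.0) < 1e-12
    assert freqs[CANONICAL_AAS.index("G")] > freqs[CANONICAL_AAS.index("W")]
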