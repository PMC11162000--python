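"""Skip-gram with negative sampling: gradients, determinism, OOV policy."""

import copy

import numpy as np
import pytest

from sgcpi.embedding import (
    EmbeddingTable,
    SkipgramConfig,
    build_vocab,
    embed_entity,
    init_table,
    load_word2vec_text,
    negative_sampling_distribution,
    oov_vector,
    pair_objective,
    save_word2vec_text,
    sgns_pair_probability,
    sgns_step,
    train_skipgram,
)
from sgcpi.tokenizer import TokenSequence


def sent(tokens, eid="e"):
    return TokenSequence(entity_id=eid, tokens=tuple(tokens), modality="protein")


def make_random_table(tokens, d, seed=0, scale=0.3):
    vocab = build_vocab([sent(tokens)], 1)
    table = init_table(vocab, SkipgramConfig(d=d, seed=seed))
    rng = np.random.default_rng(seed)
    table.V[:] = rng.normal(size=table.V.shape) * scale
    table.theta[:] = rng.normal(size=table.theta.shape) * scale
    return table


class TestVocab:
    def test_min_count_threshold(self):
        corpus = [sent(["A", "A", "A", "B"])]
        assert set(build_vocab(corpus, 2).index) == {"A"}
        assert set(build_vocab(corpus, 1).index) == {"A", "B"}

    def test_empty_vocab_raises(self):
        with pytest.raises(ValueError, match="empty vocabulary"):
            build_vocab([sent(["A", "B"])], 5)

    def test_index_order_by_count_then_lexicographic(self):
        corpus = [sent(["B", "B", "C", "A", "A"])]
        vocab = build_vocab(corpus, 1)
        assert vocab.tokens == ["A", "B", "C"]  # counts 2,2,1; tie A<B


class TestNegativeSampling:
    def test_symmetric_counts(self):
        v = build_vocab([sent(["A", "B", "A", "B", "A", "B", "A", "B"])], 1)
        assert negative_sampling_distribution(v, 0.75) == pytest.approx([0.5, 0.5])

    def test_power_weighting(self):
        # counts 8 (A) and 1 (B); p ~ [8^0.75, 1] normalized
        v = build_vocab([sent(["A"] * 8 + ["B"])], 1)
        p = negative_sampling_distribution(v, 0.75)
        assert p[v.index["B"]] == pytest.approx(0.17371, abs=1e-4)
        assert p[v.index["A"]] == pytest.approx(0.82629, abs=1e-4)
        assert p.sum() == pytest.approx(1.0, abs=1e-12)


class TestPairProbability:
    def test_zero_logit_is_half_for_both_labels(self):
        v = np.array([1.0, 0.0])
        th = np.array([0.0, 5.0])
        assert sgns_pair_probability(v, th, 1) == pytest.approx(0.5)
        assert sgns_pair_probability(v, th, 0) == pytest.approx(0.5)

    def test_unit_logit(self):
        v = np.array([1.0])
        th = np.array([1.0])
        assert sgns_pair_probability(v, th, 1) == pytest.approx(0.73106, abs=1e-5)

    def test_dimension_mismatch(self):
        with pytest.raises(ValueError):
            sgns_pair_probability(np.ones(2), np.ones(3), 1)


class TestSgnsStep:
    def test_gradient_matches_finite_differences(self):
        """Analytic ascent direction equals central finite differences of
        the pair objective (5 tokens, d=4)."""
        table = make_random_table(list("ABCDE"), d=4, seed=3)
        vocab = table.vocab
        ci, ui = vocab.index["A"], vocab.index["B"]
        neg = np.array([vocab.index[t] for t in "CDE"])
        t2 = copy.deepcopy(table)
        lr = 1e-6
        sgns_step("A", "B", ["C", "D", "E"], t2, lr)
        gV = (t2.V - table.V) / lr
        gT = (t2.theta - table.theta) / lr
        eps = 1e-5
        for arr, g in ((table.V, gV), (table.theta, gT)):
            num = np.zeros_like(arr)
            for i in range(arr.shape[0]):
                for j in range(arr.shape[1]):
                    old = arr[i, j]
                    arr[i, j] = old + eps
                    up = pair_objective(table, ci, ui, neg)
                    arr[i, j] = old - eps
                    dn = pair_objective(table, ci, ui, neg)
                    arr[i, j] = old
                    num[i, j] = (up - dn) / (2 * eps)
            scale = max(np.abs(num).max(), 1e-12)
            assert np.abs(g - num).max() / scale < 1e-4

    def test_zero_lr_is_noop(self):
        table = make_random_table(list("ABC"), d=3, seed=1)
        before_V, before_T = table.V.copy(), table.theta.copy()
        obj = sgns_step("A", "B", ["C"], table, 0.0)
        assert np.isfinite(obj)
        assert np.array_equal(table.V, before_V)
        assert np.array_equal(table.theta, before_T)

    def test_repeated_steps_ascend(self):
        table = make_random_table(list("ABCDE"), d=4, seed=7)
        objs = [sgns_step("A", "B", ["C", "D"], table, 1e-3) for _ in range(50)]
        assert all(b >= a for a, b in zip(objs, objs[1:]))

    def test_unknown_token_raises(self):
        table = make_random_table(list("AB"), d=2)
        with pytest.raises(KeyError):
            sgns_step("A", "Z", ["B"], table, 0.1)


class TestTraining:
    def test_deterministic_for_fixed_seed(self):
        corpus = [sent(list("ABCAB"), "x"), sent(list("BCA"), "y")]
        vocab = build_vocab(corpus, 1)
        cfg = SkipgramConfig(d=8, epochs=3, seed=42)
        t1, o1 = train_skipgram(corpus, vocab, cfg)
        t2, o2 = train_skipgram(corpus, vocab, cfg)
        assert np.array_equal(t1.V, t2.V)
        assert np.array_equal(t1.theta, t2.theta)
        assert o1 == o2

    def test_zero_epochs_returns_initialization(self):
        corpus = [sent(list("ABC"))]
        vocab = build_vocab(corpus, 1)
        cfg = SkipgramConfig(d=6, epochs=0, seed=5)
        table, objs = train_skipgram(corpus, vocab, cfg)
        ref = init_table(vocab, cfg)
        assert np.array_equal(table.V, ref.V)
        assert np.array_equal(table.theta, ref.theta)
        assert objs == []

    def test_cooccurring_pair_probability_rises(self):
        """Single repeated sentence "A B": the model probability of the
        observed context exceeds 0.9 after sustained training."""
        corpus = [sent(["A", "B"], "s")]
        vocab = build_vocab(corpus, 1)
        cfg = SkipgramConfig(d=8, epochs=200, seed=1, lr=0.1)
        table, _ = train_skipgram(corpus, vocab, cfg)
        p = sgns_pair_probability(
            table.V[vocab.index["A"]], table.theta[vocab.index["B"]], 1
        )
        assert p > 0.9

    def test_epoch_objective_nondecreasing_on_average(self):
        """Mean epoch log-likelihood over 5 seeds is non-decreasing across
        the first 5 epochs at a small learning rate."""
        corpus = [
            sent(list("ABCAB"), "x"),
            sent(list("BCACA"), "y"),
            sent(list("CABBC"), "z"),
        ]
        vocab = build_vocab(corpus, 1)
        trajs = []
        for seed in range(5):
            cfg = SkipgramConfig(d=8, epochs=5, seed=seed, lr=1e-2, lr_min=1e-4)
            _, objs = train_skipgram(corpus, vocab, cfg)
            trajs.append(objs)
        mean = np.mean(trajs, axis=0)
        assert all(b >= a for a, b in zip(mean, mean[1:]))

    def test_invalid_config_rejected(self):
        with pytest.raises(ValueError):
            SkipgramConfig(d=0)
        with pytest.raises(ValueError):
            SkipgramConfig(window=0)


class TestEntityEmbedding:
    def test_oov_vector_is_vocab_mean(self):
        table = make_random_table(list("AB"), d=2)
        table.V[:] = np.array([[1.0, 0.0], [0.0, 1.0]])
        assert oov_vector(table) == pytest.approx([0.5, 0.5])

    def test_oov_vector_of_centered_table_is_zero(self):
        table = make_random_table(list("ABCD"), d=3, seed=2)
        table.V -= table.V.mean(axis=0)
        assert np.abs(oov_vector(table)).max() < 1e-12

    def test_mean_of_token_vectors(self):
        table = make_random_table(list("AB"), d=2)
        table.V[table.vocab.index["A"]] = [2.0, 0.0]
        table.V[table.vocab.index["B"]] = [0.0, 2.0]
        emb = embed_entity(sent(["A", "B"]), table)
        assert emb.vector == pytest.approx([1.0, 1.0])
        assert emb.oov_fraction == 0.0

    def test_all_oov_under_averaged_policy(self):
        table = make_random_table(list("AB"), d=2)
        emb = embed_entity(sent(["Z", "Q"]), table, oov_policy="averaged")
        assert emb.vector == pytest.approx(oov_vector(table))
        assert emb.oov_fraction == 1.0

    def test_oov_error_policy_names_token(self):
        table = make_random_table(list("AB"), d=2)
        with pytest.raises(KeyError, match="Z"):
            embed_entity(sent(["A", "Z"]), table, oov_policy="error")

    def test_permutation_invariance(self):
        table = make_random_table(list("ABC"), d=4, seed=9)
        e1 = embed_entity(sent(["A", "B", "C", "A"]), table)
        e2 = embed_entity(sent(["C", "A", "A", "B"]), table)
        assert e1.vector == pytest.approx(e2.vector, abs=1e-15)

    def test_empty_tokens_rejected(self):
        table = make_random_table(list("AB"), d=2)
        with pytest.raises(ValueError):
            embed_entity(sent([]), table)


def test_word2vec_text_roundtrip(tmp_path):
    table = make_random_table(list("ABC"), d=5, seed=4)
    path = tmp_path / "vec.txt"
    save_word2vec_text(table, path)
    toks, M = load_word2vec_text(path)
    assert toks == table.vocab.tokens
    assert np.array_equal(M, table.V)
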