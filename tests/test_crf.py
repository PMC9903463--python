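"""Linear-chain CRF against brute-force enumeration oracles."""

import itertools

import numpy as np
import pytest

from coloner.crf import (
    CrfParameters, gold_score, log_partition, negative_log_likelihood,
    viterbi_decode,
)
from coloner.errors import InfeasibleDecodeError, ValidationError
from coloner.schema import TagVocabulary, transition_mask


def enumerate_scores(em, params):
    """Score of every tag path of a single sentence, by direct summation."""
    T, K = em.shape
    out = {}
    for path in itertools.product(range(K), repeat=T):
        s = params.start[path[0]] + params.stop[path[-1]]
        s += sum(em[t, path[t]] for t in range(T))
        s += sum(params.transitions[a, b] for a, b in zip(path, path[1:]))
        out[path] = s
    return out


def random_instance(rng, max_t=5, max_k=5, scale=3.0):
    T = int(rng.integers(1, max_t + 1))
    K = int(rng.integers(2, max_k + 1))
    em = rng.normal(0, scale, (1, T, K))
    params = CrfParameters(rng.normal(0, scale, (K, K)),
                           rng.normal(0, scale, K), rng.normal(0, scale, K))
    return T, K, em, params


class TestLogPartition:
    def test_uniform_scores_closed_form(self):
        for T, K in [(1, 3), (4, 5), (7, 2)]:
            em = np.zeros((1, T, K))
            lz = log_partition(em, np.array([T]), CrfParameters.zeros(K))
            assert lz[0] == pytest.approx(T * np.log(K), abs=1e-12)

    def test_small_integer_instance_matches_enumeration(self):
        em = np.array([[[1.0, 2.0, -1.0], [0.0, 1.0, 3.0], [2.0, -2.0, 1.0]]])
        params = CrfParameters(
            transitions=np.array([[1.0, -1.0, 0.0], [0.0, 2.0, -1.0], [1.0, 0.0, 1.0]]),
            start=np.array([0.5, -0.5, 1.0]),
            stop=np.array([1.0, 0.0, -1.0]),
        )
        brute = np.logaddexp.reduce(list(enumerate_scores(em[0], params).values()))
        lz = log_partition(em, np.array([3]), params)
        assert lz[0] == pytest.approx(brute, abs=1e-6)

    def test_single_token_closed_form(self, rng):
        em = rng.normal(0, 2, (1, 1, 4))
        params = CrfParameters(rng.normal(0, 2, (4, 4)),
                               rng.normal(0, 2, 4), rng.normal(0, 2, 4))
        expected = np.logaddexp.reduce(params.start + em[0, 0] + params.stop)
        assert log_partition(em, np.array([1]), params)[0] == pytest.approx(expected, abs=1e-12)

    def test_stable_for_large_scores(self):
        em = np.full((1, 4, 3), 50.0)
        params = CrfParameters(np.full((3, 3), -50.0), np.full(3, 50.0), np.full(3, 50.0))
        lz = log_partition(em, np.array([4]), params)
        assert np.isfinite(lz[0])

    def test_zero_length_rejected(self):
        with pytest.raises(ValidationError):
            log_partition(np.zeros((1, 3, 2)), np.array([0]), CrfParameters.zeros(2))


class TestNegativeLogLikelihood:
    def test_gold_path_score_matches_direct_summation(self, rng):
        for _ in range(50):
            T, K, em, params = random_instance(rng)
            tags = rng.integers(0, K, (1, T))
            scores = enumerate_scores(em[0], params)
            assert gold_score(em, tags, np.array([T]), params)[0] == \
                pytest.approx(scores[tuple(tags[0])], abs=1e-9)

    def test_loss_nonnegative_and_matches_enumeration(self, rng):
        for _ in range(300):
            T, K, em, params = random_instance(rng)
            tags = rng.integers(0, K, (1, T))
            loss = negative_log_likelihood(em, tags, np.array([T]), params)
            assert loss >= -1e-10
            scores = enumerate_scores(em[0], params)
            brute = np.logaddexp.reduce(list(scores.values())) - scores[tuple(tags[0])]
            assert loss == pytest.approx(brute, abs=1e-6)

    def test_uniform_scores_loss_is_t_log_k(self):
        T, K = 5, 4
        em = np.zeros((1, T, K))
        tags = np.array([[0, 1, 2, 3, 0]])
        loss = negative_log_likelihood(em, tags, np.array([T]), CrfParameters.zeros(K))
        assert loss == pytest.approx(T * np.log(K), abs=1e-12)

    def test_path_probabilities_normalize(self, rng):
        """exp(score - log Z) sums to one over all paths."""
        for _ in range(20):
            T, K, em, params = random_instance(rng, max_t=4, max_k=4)
            lz = log_partition(em, np.array([T]), params)[0]
            total = sum(np.exp(s - lz) for s in enumerate_scores(em[0], params).values())
            assert total == pytest.approx(1.0, abs=1e-9)

    def test_misaligned_tags_rejected(self):
        with pytest.raises(ValidationError):
            negative_log_likelihood(np.zeros((1, 3, 2)), np.zeros((2, 3), dtype=int),
                                    np.array([3]), CrfParameters.zeros(2))

    def test_batched_loss_equals_mean_of_singles(self, rng):
        K = 4
        lengths = np.array([3, 1, 2])
        em = rng.normal(0, 2, (3, 3, K))
        params = CrfParameters(rng.normal(0, 1, (K, K)), rng.normal(0, 1, K),
                               rng.normal(0, 1, K))
        tags = rng.integers(0, K, (3, 3))
        batched = negative_log_likelihood(em, tags, lengths, params)
        singles = [
            negative_log_likelihood(em[b:b+1, :lengths[b]], tags[b:b+1, :lengths[b]],
                                    lengths[b:b+1], params)
            for b in range(3)
        ]
        assert batched == pytest.approx(np.mean(singles), abs=1e-10)


class TestViterbi:
    def test_all_zero_scores_decode_to_lowest_index(self):
        em = np.zeros((1, 4, 5))
        paths, score = viterbi_decode(em, np.array([4]), CrfParameters.zeros(5))
        assert paths[0] == [0, 0, 0, 0]
        assert score[0] == 0.0

    def test_matches_exhaustive_argmax(self, rng):
        for _ in range(200):
            T, K, em, params = random_instance(rng, max_t=4, max_k=4)
            scores = enumerate_scores(em[0], params)
            paths, best = viterbi_decode(em, np.array([T]), params)
            assert best[0] == pytest.approx(max(scores.values()), abs=1e-9)
            assert scores[tuple(paths[0])] == pytest.approx(best[0], abs=1e-9)

    def test_constrained_decode_satisfies_iob2(self, rng, tag_vocab):
        from coloner.schema import is_valid_iob2
        allowed, start, _ = transition_mask(tag_vocab).nopad()
        K = len(tag_vocab) - 1
        params = CrfParameters(rng.normal(0, 2, (K, K)), rng.normal(0, 2, K),
                               rng.normal(0, 2, K))
        for _ in range(100):
            T = int(rng.integers(1, 8))
            em = rng.normal(0, 4, (1, T, K))
            paths, _ = viterbi_decode(em, np.array([T]), params,
                                      allowed_transitions=allowed, allowed_start=start)
            tags = [tag_vocab.tag(i + 1) for i in paths[0]]
            assert is_valid_iob2(tags, tag_vocab)

    def test_infeasible_decode_raises(self):
        em = np.zeros((1, 2, 3))
        never = np.zeros(3, dtype=bool)
        with pytest.raises(InfeasibleDecodeError):
            viterbi_decode(em, np.array([2]), CrfParameters.zeros(3),
                           allowed_start=never)
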