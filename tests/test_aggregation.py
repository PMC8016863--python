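"""Majority vote, triplet recovery, EM label model, posteriors, sweep."""

import itertools
from collections import Counter

import numpy as np
import pytest

from ontoweave.aggregation import (
    LabelModel,
    LabelModelParams,
    estimate_accuracies_triplet,
    fit_label_model,
    majority_vote,
    mv_default_class,
    posterior,
)
from ontoweave.synthesis import SourceSpec, sample_label_matrix


def _mv_oracle_row(row, K, default):
    counts = Counter(v for v in row if v >= 0)
    if not counts:
        return default
    top = max(counts.values())
    modes = [c for c, n in counts.items() if n == top]
    return modes[0] if len(modes) == 1 else default


def _posterior_oracle(row, acc, prior, k):
    """Independent enumeration of the accuracy-factor model including
    coverage factors (which cancel on normalization)."""
    K = k + 1
    joint = np.zeros(K)
    for y in range(K):
        p = prior[y]
        for j, v in enumerate(row):
            if v == -1:
                p *= 0.5  # arbitrary abstain probability; independent of y
            else:
                p *= 0.9 * (acc[j] if v == y else (1 - acc[j]) / k)
        joint[y] = p
    return joint / joint.sum()


class TestMajorityVote:
    def test_modal_vote(self):
        L = np.array([[1, 1, 0]])
        assert majority_vote(L, default_class=0, k=1).hard.tolist() == [1]

    def test_all_abstain_defaults(self):
        L = np.array([[-1, -1, -1]])
        assert majority_vote(L, default_class=0, k=1).hard.tolist() == [0]
        assert majority_vote(L, default_class=0, k=1).abstain.tolist() == [True]

    def test_tie_defaults(self):
        L = np.array([[1, 0, -1]])
        assert majority_vote(L, default_class=0, k=1).hard.tolist() == [0]

    def test_probs_one_hot(self):
        L = np.array([[2, 2, 1]])
        mv = majority_vote(L, default_class=0, k=2)
        assert mv.probs.tolist() == [[0.0, 0.0, 1.0]]

    def test_default_class_validated(self):
        with pytest.raises(ValueError, match="default_class"):
            majority_vote(np.array([[0]]), default_class=5, k=1)

    def test_matches_exhaustive_oracle(self, rng):
        for _ in range(50):
            n, m, k = int(rng.integers(1, 50)), int(rng.integers(1, 6)), int(rng.integers(1, 4))
            L = rng.integers(-1, k + 1, size=(n, m))
            default = int(rng.integers(0, k + 1))
            got = majority_vote(L, default_class=default, k=k).hard
            expect = [_mv_oracle_row(row, k + 1, default) for row in L]
            assert got.tolist() == expect


class TestTriplet:
    TRUTHS = np.array([0.6, 0.7, 0.8, 0.9, 0.95])

    def _matrix(self, coverage, n, seed):
        rng = np.random.default_rng(seed)
        y = (rng.random(n) < 0.5).astype(int)
        specs = [SourceSpec(p, coverage) for p in self.TRUTHS]
        return sample_label_matrix(y, specs, seed=seed + 1), y

    def test_recovery_full_coverage(self):
        L, _ = self._matrix(1.0, 10_000, 7)
        est = estimate_accuracies_triplet(L)
        assert np.abs(est - self.TRUTHS).max() < 0.03

    def test_recovery_partial_coverage(self):
        L, _ = self._matrix(0.5, 20_000, 8)
        est = estimate_accuracies_triplet(L)
        assert np.abs(est - self.TRUTHS).max() < 0.05

    def test_perfect_sources_hit_upper_clamp(self):
        y = np.tile([0, 1], 500)
        L = np.stack([y, y, y], axis=1)
        est = estimate_accuracies_triplet(type("L", (), {"values": L, "k": 1})())
        assert np.allclose(est, 0.99)

    def test_requires_binary_and_three_sources(self):
        with pytest.raises(ValueError, match="binary"):
            estimate_accuracies_triplet(type("L", (), {"values": np.zeros((5, 3), int), "k": 2})())
        with pytest.raises(ValueError, match="3 sources"):
            estimate_accuracies_triplet(type("L", (), {"values": np.zeros((5, 2), int), "k": 1})())


class TestLabelModelFit:
    def test_parameter_recovery(self):
        rng = np.random.default_rng(3)
        y = (rng.random(10_000) < 0.3).astype(int)
        truths = [0.6, 0.7, 0.8, 0.9, 0.95]
        L = sample_label_matrix(y, [SourceSpec(p, 0.8) for p in truths], seed=4)
        res = LabelModel(L).fit()
        assert np.abs(res.params.accuracies - truths).max() < 0.05
        assert abs(res.params.prior[1] - 0.3) < 0.05

    def test_unanimous_perfect_sources_one_hot_posterior(self):
        y = np.tile([0, 1], 100)
        L = np.stack([y, y, y], axis=1)
        res = LabelModel(L, k=1).fit()
        post = res.predict_proba(default_class=0)
        assert (post.hard == y).all()
        assert post.probs.max(axis=1).min() > 0.99

    def test_em_agrees_with_triplet(self):
        rng = np.random.default_rng(5)
        y = (rng.random(20_000) < 0.5).astype(int)
        L = sample_label_matrix(y, [SourceSpec(p, 0.8) for p in (0.6, 0.7, 0.8, 0.9, 0.95)], seed=6)
        em = LabelModel(L).fit().params.accuracies
        trip = estimate_accuracies_triplet(L)
        assert np.abs(em - trip).max() < 0.03

    def test_m_below_three_raises(self):
        with pytest.raises(ValueError, match="3 sources"):
            LabelModel(np.zeros((10, 2), int), k=1).fit()

    def test_all_abstain_matrix_raises(self):
        with pytest.raises(ValueError, match="abstain"):
            LabelModel(np.full((10, 3), -1), k=1).fit()

    def test_column_permutation_symmetry(self):
        rng = np.random.default_rng(9)
        y = (rng.random(5_000) < 0.5).astype(int)
        L = sample_label_matrix(y, [SourceSpec(p) for p in (0.9, 0.7, 0.6)], seed=10)
        perm = [2, 0, 1]
        res1 = LabelModel(L.values, k=1).fit()
        res2 = LabelModel(L.values[:, perm], k=1).fit()
        assert np.allclose(res1.params.accuracies[perm], res2.params.accuracies, atol=1e-8)
        p1 = posterior(L.values, res1.params, 0).probs
        p2 = posterior(L.values[:, perm], res2.params, 0).probs
        assert np.allclose(p1, p2, atol=1e-8)

    def test_accuracy_estimate_monotone_in_truth(self):
        # raising one source's true accuracy (paired seeds) should not lower
        # its estimate, in the median over replicates
        diffs = []
        for rep in range(20):
            rng = np.random.default_rng(1000 + rep)
            y = (rng.random(3_000) < 0.5).astype(int)
            lo = sample_label_matrix(y, [SourceSpec(0.65), SourceSpec(0.8), SourceSpec(0.7)],
                                     seed=2000 + rep)
            hi = sample_label_matrix(y, [SourceSpec(0.85), SourceSpec(0.8), SourceSpec(0.7)],
                                     seed=2000 + rep)
            a_lo = LabelModel(lo).fit().params.accuracies[0]
            a_hi = LabelModel(hi).fit().params.accuracies[0]
            diffs.append(a_hi - a_lo)
        assert np.median(diffs) > 0

    def test_abstain_dominance(self):
        # an all-abstain source changes no MV or label-model prediction
        rng = np.random.default_rng(11)
        y = (rng.random(2_000) < 0.5).astype(int)
        L = sample_label_matrix(y, [SourceSpec(p) for p in (0.9, 0.7, 0.6)], seed=12)
        La = np.hstack([L.values, np.full((L.n, 1), -1, dtype=np.int16)])
        assert (majority_vote(L.values, 0, k=1).hard == majority_vote(La, 0, k=1).hard).all()
        h1 = LabelModel(L.values, k=1).fit(use_triplet_init=False).predict_proba(default_class=0).hard
        h2 = LabelModel(La, k=1).fit(use_triplet_init=False).predict_proba(default_class=0).hard
        assert (h1 == h2).all()


class TestPosterior:
    def test_single_source_posterior_equals_accuracy(self):
        params = LabelModelParams([0.8], [1.0], [0.5, 0.5], k=1)
        post = posterior(np.array([[1]]), params, 0)
        assert np.isclose(post.probs[0, 1], 0.8)

    def test_two_agreeing_sources_closed_form(self):
        params = LabelModelParams([0.8, 0.8], [1.0, 1.0], [0.5, 0.5], k=1)
        post = posterior(np.array([[1, 1]]), params, 0)
        assert np.isclose(post.probs[0, 1], 0.8**2 / (0.8**2 + 0.2**2))

    def test_all_abstain_returns_prior_flagged(self):
        params = LabelModelParams([0.8, 0.7, 0.6], [1.0] * 3, [0.3, 0.7], k=1)
        post = posterior(np.array([[-1, -1, -1]]), params, 0)
        assert post.abstain.tolist() == [True]
        assert np.allclose(post.probs[0], [0.3, 0.7])

    def test_rows_normalize(self, rng):
        params = LabelModelParams([0.8, 0.6, 0.7], [1.0] * 3, [0.2, 0.5, 0.3], k=2)
        L = rng.integers(-1, 3, size=(200, 3))
        post = posterior(L, params, 0)
        assert np.allclose(post.probs.sum(axis=1), 1.0, atol=1e-12)

    def test_matches_enumeration_oracle_exhaustively(self, rng):
        for m, k in itertools.product(range(1, 5), (1, 2)):
            acc = rng.uniform(0.55, 0.95, size=m)
            prior = rng.dirichlet(np.ones(k + 1))
            params = LabelModelParams(acc, np.ones(m), prior, k=k)
            rows = np.array(list(itertools.product(range(-1, k + 1), repeat=m)))
            post = posterior(rows, params, 0)
            for row, got in zip(rows, post.probs):
                assert np.allclose(got, _posterior_oracle(row, acc, prior, k), atol=1e-9)


class TestHelpers:
    def test_mv_default_class_is_corpus_mode(self):
        L = np.array([[1, 1, -1], [1, -1, 1], [0, 0, 1], [0, 1, -1]])
        assert mv_default_class(L, k=1) == 1

    def test_fit_label_model_wrapper_returns_params(self):
        rng = np.random.default_rng(13)
        y = (rng.random(1000) < 0.5).astype(int)
        L = sample_label_matrix(y, [SourceSpec(p) for p in (0.9, 0.7, 0.6)], seed=14)
        params = fit_label_model(L)
        assert params.m == 3
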