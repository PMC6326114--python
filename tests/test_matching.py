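"""Core Bayesian matcher: weights, similarity, posteriors, decisions."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from diaglink import (
    BinaryRecordDataset,
    CodeWeightTable,
    HyperParameters,
    SimilarityMatrix,
    align_codes,
    average_posteriors,
    compute_code_weights,
    compute_directed_posterior,
    compute_similarity,
    threshold_matches,
)
from conftest import random_dataset


def brute_force_similarity(MA, MB, w):
    """Independent oracle: per-pair, per-code pattern lookup."""
    nA, nB = MA.shape[0], MB.shape[0]
    out = np.zeros((nA, nB))
    for i in range(nA):
        for j in range(nB):
            s = 0.0
            for k in range(MA.shape[1]):
                a, b = MA[i, k], MB[j, k]
                if a and b:
                    s += w.w11[k]
                elif a and not b:
                    s += w.w10[k]
                elif not a and b:
                    s += w.w01[k]
                else:
                    s += w.w00[k]
            out[i, j] = s
    return out


class TestCodeWeights:
    def test_closed_form_values(self):
        h = HyperParameters(pi_B=[0.1], eps_minus=0.01, eps_plus=0.01, pi_0=0.5)
        w = compute_code_weights(h)
        assert w.w11[0] == pytest.approx(np.log(0.99 / 0.1), abs=1e-12)
        assert w.w00[0] == pytest.approx(np.log(0.99 / 0.9), abs=1e-12)
        assert w.w10[0] == pytest.approx(np.log(0.01 / 0.9), abs=1e-12)
        assert w.w01[0] == pytest.approx(np.log(0.01 / 0.1), abs=1e-12)

    @pytest.mark.parametrize("eps", [0.01, 0.2])
    def test_prevalence_half_symmetry(self, eps):
        w = compute_code_weights(
            HyperParameters(pi_B=[0.5], eps_minus=eps, eps_plus=eps, pi_0=0.5)
        )
        assert w.w11[0] == pytest.approx(np.log(2 * (1 - eps)))
        assert w.w00[0] == pytest.approx(np.log(2 * (1 - eps)))
        assert w.w10[0] == pytest.approx(np.log(2 * eps))
        assert w.w01[0] == pytest.approx(np.log(2 * eps))

    def test_zero_information(self):
        w = compute_code_weights(
            HyperParameters(pi_B=[0.5], eps_minus=0.5, eps_plus=0.5, pi_0=0.5)
        )
        for name in ("w11", "w00", "w10", "w01"):
            assert getattr(w, name)[0] == pytest.approx(0.0, abs=1e-14)

    def test_boundary_rejected_without_clipping(self):
        with pytest.raises(ValueError, match=r"eps_minus\[0\]"):
            HyperParameters(
                pi_B=[0.1], eps_minus=0.0, eps_plus=0.01, pi_0=0.5, clip=False
            )

    def test_boundary_clipped_by_default(self):
        h = HyperParameters(pi_B=[0.0, 1.0], eps_minus=0.01, eps_plus=0.01,
                            pi_0=0.5, n_B=10)
        assert h.pi_B[0] == pytest.approx(0.05)
        assert h.pi_B[1] == pytest.approx(0.95)
        w = compute_code_weights(h)
        assert np.all(np.isfinite(w.w11))

    def test_weight_ordering_for_rare_codes(self):
        # w11 > w00 whenever pi_B < 1 - pi_B and eps_minus == eps_plus
        for p in (0.01, 0.2, 0.49):
            w = compute_code_weights(
                HyperParameters(pi_B=[p], eps_minus=0.05, eps_plus=0.05, pi_0=0.5)
            )
            assert w.w11[0] > w.w00[0]


class TestSimilarity:
    def test_single_code_reduces_to_w11(self):
        h = HyperParameters(pi_B=[0.1], eps_minus=0.01, eps_plus=0.01, pi_0=0.5)
        w = compute_code_weights(h)
        A = BinaryRecordDataset(["a"], ["c"], [[1]])
        B = BinaryRecordDataset(["b"], ["c"], [[1]])
        sim = compute_similarity(A, B, align_codes(A, B), w)
        assert sim.scores[0, 0] == pytest.approx(np.log(0.99 / 0.1), abs=1e-12)

    def test_all_zero_profiles_sum_w00(self, rng):
        K = 7
        h = HyperParameters(
            pi_B=rng.uniform(0.05, 0.6, K), eps_minus=0.02, eps_plus=0.03, pi_0=0.5
        )
        w = compute_code_weights(h)
        codes = [f"C{k}" for k in range(K)]
        A = BinaryRecordDataset(["a"], codes, np.zeros((1, K)))
        B = BinaryRecordDataset(["b"], codes, np.zeros((1, K)))
        sim = compute_similarity(A, B, align_codes(A, B), w)
        assert sim.scores[0, 0] == pytest.approx(w.w00.sum(), abs=1e-12)

    def test_decomposition_equals_brute_force(self, rng):
        codes = [f"C{k}" for k in range(50)]
        for _ in range(10):
            A = random_dataset(rng, 20, codes, p=0.2, prefix="A")
            B = random_dataset(rng, 15, codes, p=0.2, prefix="B")
            h = HyperParameters(
                pi_B=rng.uniform(0.02, 0.7, 50),
                eps_minus=rng.uniform(0.005, 0.2, 50),
                eps_plus=rng.uniform(0.005, 0.2, 50),
                pi_0=0.1,
            )
            w = compute_code_weights(h)
            align = align_codes(A, B)
            sim = compute_similarity(A, B, align, w)
            oracle = brute_force_similarity(
                A.reindexed(align.shared_code_ids),
                B.reindexed(align.shared_code_ids),
                w,
            )
            np.testing.assert_allclose(sim.scores, oracle, atol=1e-10)

    def test_dimension_mismatch_rejected(self, small_pair, simple_hyper):
        A, B = small_pair
        w = compute_code_weights(simple_hyper)
        bad = CodeWeightTable(w.w11[:10], w.w00[:10], w.w10[:10], w.w01[:10])
        with pytest.raises(ValueError, match="codes"):
            compute_similarity(A, B, align_codes(A, B), bad)


class TestDirectedPosterior:
    def test_single_candidate_identity(self):
        sim = SimilarityMatrix(np.array([[0.0]]), ["a"], ["b"])
        p = compute_directed_posterior(sim, 0.5, "A_to_B")
        assert p.probs[0, 0] == pytest.approx(0.5, abs=1e-14)

    def test_two_candidate_hand_values(self):
        # independent evaluation of the closed form
        sim = SimilarityMatrix(np.array([[1.0, 2.0]]), ["a"], ["b1", "b2"])
        p = compute_directed_posterior(sim, 0.1, "A_to_B")
        l0 = np.log(0.1 / 0.9)
        e = np.exp(np.array([1.0, 2.0]) + l0)
        expected = e / (1 + e.sum())
        np.testing.assert_allclose(p.probs[0], expected, atol=1e-12)
        assert p.probs[0, 0] == pytest.approx(0.1423, abs=1e-4)
        assert p.probs[0, 1] == pytest.approx(0.3867, abs=1e-4)
        assert p.no_match_probability()[0] == pytest.approx(0.4710, abs=1e-4)

    @given(st.integers(0, 2**31 - 1))
    @settings(max_examples=25, deadline=None)
    def test_normalization_with_no_match_mass(self, seed):
        r = np.random.default_rng(seed)
        scores = r.normal(0, 50, size=(8, 11))
        sim = SimilarityMatrix(
            scores, [f"a{i}" for i in range(8)], [f"b{j}" for j in range(11)]
        )
        pi0 = float(r.uniform(0.001, 0.999))
        pab = compute_directed_posterior(sim, pi0, "A_to_B")
        total = pab.probs.sum(axis=1) + pab.no_match_probability()
        np.testing.assert_allclose(total, 1.0, atol=1e-12)
        pba = compute_directed_posterior(sim, pi0, "B_to_A")
        total = pba.probs.sum(axis=0) + pba.no_match_probability()
        np.testing.assert_allclose(total, 1.0, atol=1e-12)

    def test_overflow_safe_for_huge_scores(self):
        sim = SimilarityMatrix(np.array([[900.0, 850.0]]), ["a"], ["b1", "b2"])
        p = compute_directed_posterior(sim, 0.01, "A_to_B")
        assert np.all(np.isfinite(p.probs))
        assert p.probs[0, 0] == pytest.approx(1.0, abs=1e-12)

    def test_monotone_in_similarity(self):
        base = np.array([[1.0, 2.0], [0.5, -1.0]])
        for direction in ("A_to_B", "B_to_A"):
            lo = compute_directed_posterior(
                SimilarityMatrix(base, ["a1", "a2"], ["b1", "b2"]), 0.2, direction
            ).probs[0, 0]
            bumped = base.copy()
            bumped[0, 0] += 0.5
            hi = compute_directed_posterior(
                SimilarityMatrix(bumped, ["a1", "a2"], ["b1", "b2"]), 0.2, direction
            ).probs[0, 0]
            assert hi > lo

    def test_nonfinite_scores_rejected(self):
        with pytest.raises(ValueError):
            SimilarityMatrix(np.array([[np.inf]]), ["a"], ["b"])


class TestAveragingAndThreshold:
    def _directed(self, probs, direction):
        from diaglink import PosteriorMatrix

        nA, nB = np.asarray(probs).shape
        return PosteriorMatrix(
            np.asarray(probs, dtype=float),
            direction,
            [f"a{i+1}" for i in range(nA)],
            [f"b{j+1}" for j in range(nB)],
        )

    def test_elementwise_mean(self):
        p = average_posteriors(
            self._directed([[0.9]], "A_to_B"), self._directed([[0.7]], "B_to_A")
        )
        assert p.probs[0, 0] == pytest.approx(0.8)
        assert p.direction == "averaged"

    def test_idempotent_on_identical_inputs(self, rng):
        x = rng.uniform(0, 0.4, (3, 4))
        p = average_posteriors(
            self._directed(x, "A_to_B"), self._directed(x, "B_to_A")
        )
        np.testing.assert_allclose(p.probs, x)

    def test_direction_mismatch_rejected(self):
        with pytest.raises(ValueError):
            average_posteriors(
                self._directed([[0.5]], "A_to_B"), self._directed([[0.5]], "A_to_B")
            )

    @pytest.mark.parametrize(
        "alpha,expected",
        [(0.5, {("a1", "b1")}), (0.9, {("a1", "b1")}),
         (0.3, {("a1", "b1"), ("a2", "b2")})],
    )
    def test_threshold_filter(self, alpha, expected):
        post = self._directed([[0.95, 0.02], [0.01, 0.40]], "A_to_B")
        post.direction = "averaged"
        ms = threshold_matches(post, alpha)
        assert ms.id_pairs() == expected

    def test_exact_tie_counts_as_match(self):
        post = self._directed([[0.5]], "A_to_B")
        post.direction = "averaged"
        assert threshold_matches(post, 0.5).id_pairs() == {("a1", "b1")}

    def test_requires_averaged_direction(self):
        with pytest.raises(ValueError):
            threshold_matches(self._directed([[0.9]], "A_to_B"), 0.5)


class TestSymmetry:
    def test_swap_and_transpose(self, rng):
        """With fully symmetric hyper-parameters (eps_minus = eps_plus and
        prevalence 1/2, so that w10 = w01) the averaged posterior of (B, A)
        is the transpose of that of (A, B)."""
        codes = [f"C{k}" for k in range(30)]
        A = random_dataset(rng, 10, codes, p=0.5, prefix="A")
        B = random_dataset(rng, 12, codes, p=0.5, prefix="B")
        pi = np.full(30, 0.5)
        h = HyperParameters(pi_B=pi, eps_minus=0.02, eps_plus=0.02, pi_0=0.05,
                            pi_A=pi)
        w = compute_code_weights(h)
        sim_ab = compute_similarity(A, B, align_codes(A, B), w)
        sim_ba = compute_similarity(B, A, align_codes(B, A), w)
        np.testing.assert_allclose(sim_ab.scores, sim_ba.scores.T, atol=1e-10)
        avg_ab = average_posteriors(
            compute_directed_posterior(sim_ab, 0.05, "A_to_B"),
            compute_directed_posterior(sim_ab, 0.05, "B_to_A"),
        )
        avg_ba = average_posteriors(
            compute_directed_posterior(sim_ba, 0.05, "A_to_B"),
            compute_directed_posterior(sim_ba, 0.05, "B_to_A"),
        )
        np.testing.assert_allclose(avg_ab.probs, avg_ba.probs.T, atol=1e-12)
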