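"""Intersection-line heuristic: geometry, scoring, and row inference."""

import numpy as np
import pytest

import steadynet as sn
from steadynet.heuristic import (
    DifferenceMatrix,
    build_difference_matrix,
    sample_intersection_line,
    score_line,
)


class TestDifferenceMatrix:
    def test_pair_count(self):
        rng = np.random.default_rng(1)
        # 4 samples all containing taxon 0 -> C(4,2) = 6 difference columns
        ss = sn.SampleSet(rng.uniform(0.5, 2.0, size=(4, 3)))
        M = build_difference_matrix(ss, 0)
        assert M.n_pairs == 6

    def test_direct_subtraction(self):
        ss = sn.SampleSet(np.array([[1.0, 0.0], [2.0, 1.0]]))
        M = build_difference_matrix(ss, 0)
        assert M.n_pairs == 1
        assert np.allclose(np.abs(M.diffs[0]), [1.0, 1.0])

    def test_too_few_samples(self):
        ss = sn.SampleSet(np.array([[1.0, 0.0], [0.0, 2.0]]))
        with pytest.raises(ValueError, match="at least 2"):
            build_difference_matrix(ss, 0)

    def test_identical_replicates_rejected(self):
        ss = sn.SampleSet(np.array([[1.0, 2.0], [1.0, 2.0]]))
        with pytest.raises(ValueError, match="average"):
            build_difference_matrix(ss, 0)


class TestIntersectionLine:
    def test_kernel_in_2d(self):
        M = DifferenceMatrix(
            diffs=np.array([[1.0, 1.0]]), taxon=0, pair_index=[(0, 1)]
        )
        line = sample_intersection_line(M, np.random.default_rng(0))
        assert line is not None
        d = line.direction / np.linalg.norm(line.direction)
        assert np.allclose(np.abs(d), [np.sqrt(0.5), np.sqrt(0.5)])
        assert tuple(line.pattern) in {(1, -1), (-1, 1)}

    def test_kernel_in_3d(self):
        M = DifferenceMatrix(
            diffs=np.array([[1.0, 0.0, 0.0], [0.0, 1.0, 0.0]]),
            taxon=0,
            pair_index=[(0, 1), (0, 2)],
        )
        line = sample_intersection_line(M, np.random.default_rng(0))
        assert np.allclose(np.abs(line.direction), [0, 0, 1])

    def test_zero_column_with_reduced_kernel_marks_unidentified(self):
        """A taxon never varying alongside the focal one is unidentifiable:
        the line lives in the co-occurring subspace and flags the dead
        coordinate instead of failing."""
        M = DifferenceMatrix(
            diffs=np.array([[1.0, 1.0, 0.0], [2.0, 2.0, 0.0]]),
            taxon=0,
            pair_index=[(0, 1), (0, 2)],
        )
        line = sample_intersection_line(M, np.random.default_rng(0))
        assert line is not None
        assert line.unidentified == frozenset({2})
        assert tuple(line.pattern) in {(1, -1, 0), (-1, 1, 0)}

    def test_rank_deficient_subset_signals_retry(self):
        M = DifferenceMatrix(
            diffs=np.array([[1.0, 0.0, 0.0], [2.0, 0.0, 0.0]]),
            taxon=0,
            pair_index=[(0, 1), (0, 2)],
        )
        assert sample_intersection_line(M, np.random.default_rng(0)) is None


class TestScoreLine:
    def test_zero_pattern_scores_one(self):
        rng = np.random.default_rng(2)
        M = DifferenceMatrix(
            diffs=rng.normal(size=(6, 4)), taxon=0, pair_index=[]
        )
        line = sample_intersection_line(M, rng)
        line.pattern = np.zeros(4, dtype=np.int8)
        assert score_line(line, M) == 1.0

    def test_phi_is_a_fraction_of_satisfied_pairs(self):
        # pattern (+,+) satisfies (1,-1)-type rows, not (1,1)-type rows
        M = DifferenceMatrix(
            diffs=np.array(
                [[1.0, -1.0], [2.0, -0.5], [1.0, 1.0], [0.5, 0.5]]
            ),
            taxon=0,
            pair_index=[],
        )
        from steadynet.heuristic import ScoredLine

        line = ScoredLine(
            direction=np.array([1.0, 1.0]),
            pattern=np.array([1, 1], dtype=np.int8),
            phi=np.nan,
        )
        assert score_line(line, M) == 0.5


class TestHeuristicRow:
    def test_two_taxon_row(self):
        ss = sn.SampleSet(np.array([[1.0, 0.0], [2.0, 1.0]]))
        cand, phi, lines = sn.heuristic_infer_row(
            ss, 0, psi=5, rng=np.random.default_rng(0)
        )
        assert phi == 1.0
        assert cand.patterns == {(0, 0), (1, -1), (-1, 1)}

    def test_seed_determinism(self, glv8):
        _, samples = glv8
        out1 = sn.infer_sign_matrix(samples, psi=40, seed=123)
        out2 = sn.infer_sign_matrix(samples, psi=40, seed=123)
        assert np.array_equal(out1[0].values, out2[0].values)
        assert np.array_equal(out1[0].determined, out2[0].determined)

    def test_matches_bruteforce_on_noiseless_glv(self, glv8):
        """Heuristic pins every sign; brute-force enumeration never contradicts.

        At moderate sample sizes the brute force may leave rows undetermined
        (its candidate sets need many more samples to shrink to 3 patterns),
        but every sign it does determine must be correct.
        """
        model, samples = glv8
        truth = sn.jacobian_sign_truth(model)
        heur, _ = sn.infer_sign_matrix(samples, method="heuristic", psi=80, seed=0)
        assert sn.sign_accuracy(heur, truth).accuracy_overall == 100.0
        brute, _ = sn.infer_sign_matrix(samples, method="bruteforce")
        res = sn.sign_accuracy(brute, truth)
        assert res.accuracy == 100.0  # determined entries all correct


class TestRelativeAbundanceDegeneracy:
    def test_all_lines_are_the_ones_vector(self):
        """Compositional samples force every intersection line onto (1,...,1)."""
        rng = np.random.default_rng(3)
        raw = rng.uniform(0.5, 2.0, size=(8, 4))
        rel = raw / raw.sum(axis=1, keepdims=True)
        ss = sn.SampleSet(rel)
        M = build_difference_matrix(ss, 0)
        for _ in range(20):
            line = sample_intersection_line(M, rng)
            if line is None:
                continue
            d = line.direction / np.linalg.norm(line.direction)
            assert np.allclose(np.abs(d), 0.5, atol=1e-6)  # (1,1,1,1)/2
            assert tuple(line.pattern) == (1, 1, 1, 1)

    def test_guard_aborts_inference(self):
        rng = np.random.default_rng(4)
        raw = rng.uniform(0.5, 2.0, size=(8, 4))
        rel = raw / raw.sum(axis=1, keepdims=True)
        with pytest.raises(ValueError, match="compositional"):
            sn.infer_sign_matrix(sn.SampleSet(rel), psi=10, seed=0)

    def test_multistability_refusal(self):
        ss = sn.SampleSet(np.array([[1.0, 2.0, 0.0], [2.0, 1.0, 0.0],
                                    [1.0, 0.0, 1.0]]))
        with pytest.raises(ValueError, match="multi-stability"):
            sn.infer_sign_matrix(ss, psi=10, seed=0)


def test_small_sample_size_degrades_accuracy():
    """Below ~3N samples the heuristic cannot pin down the rows."""
    rng = np.random.default_rng(6)
    accs = {"small": [], "large": []}
    for seed in range(3):
        model = sn.random_glv_model(8, 0.4, rng=rng)
        truth = sn.jacobian_sign_truth(model)
        for label, omega in (("small", 10), ("large", 48)):
            samples, _ = sn.generate_sample_set(model, omega, rng=rng)
            signs, _ = sn.infer_sign_matrix(samples, psi=80, seed=seed)
            accs[label].append(sn.sign_accuracy(signs, truth).accuracy_overall)
    assert np.mean(accs["small"]) < np.mean(accs["large"])
    assert np.mean(accs["large"]) >= 95.0
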