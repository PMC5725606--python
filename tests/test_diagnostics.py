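"""Assumption guards, evaluation metrics, and the scaling experiments."""

import numpy as np
import pytest

import steadynet as sn
from steadynet.signs import SignMatrix


class TestMultistability:
    def test_same_support_different_states_flagged(self):
        ss = sn.SampleSet(np.array([[1.0, 2.0, 0.0], [2.0, 1.0, 0.0]]))
        flag, groups = sn.detect_true_multistability(ss)
        assert flag
        assert groups == [frozenset({0, 1})]

    def test_distinct_supports_pass(self):
        ss = sn.SampleSet(np.array([[1.0, 0.0], [1.0, 2.0]]))
        assert not sn.detect_true_multistability(ss)[0]

    def test_within_tolerance_not_flagged(self):
        ss = sn.SampleSet(np.array([[1.0, 2.0, 0.0], [1.0000001, 2.0, 0.0]]))
        flag, _ = sn.detect_true_multistability(ss, tol=1e-3)
        assert not flag


class TestCompositionalityGuard:
    def test_unit_sums_flagged(self):
        rng = np.random.default_rng(0)
        raw = rng.uniform(0.5, 2.0, size=(6, 4))
        rel = raw / raw.sum(axis=1, keepdims=True)
        assert sn.compositionality_guard(sn.SampleSet(rel))[0]

    def test_absolute_abundances_pass(self):
        rng = np.random.default_rng(1)
        ss = sn.SampleSet(rng.uniform(0.5, 2.0, size=(6, 4)))
        assert not sn.compositionality_guard(ss)[0]

    def test_single_sample_undecidable(self):
        ss = sn.SampleSet(np.array([[0.3, 0.7]]))
        flag, note = sn.compositionality_guard(ss)
        assert not flag
        assert "undecidable" in note


class TestRelativeYield:
    def test_values(self):
        mono = sn.SampleSet(np.array([[1.0, 0.0], [0.0, 1.0]]))
        duo_up = sn.SampleSet(np.array([[3.0, 1.0]]))
        duo_dn = sn.SampleSet(np.array([[1.0 / 3.0, 1.0]]))
        assert sn.relative_yield(mono, duo_up, 0, 1) == pytest.approx(0.5)
        assert sn.relative_yield(mono, duo_dn, 0, 1) == pytest.approx(-0.5)

    def test_equal_abundance_is_zero(self):
        mono = sn.SampleSet(np.array([[2.0, 0.0]]))
        duo = sn.SampleSet(np.array([[2.0, 1.0]]))
        assert sn.relative_yield(mono, duo, 0, 1) == 0.0

    def test_antisymmetric_in_arguments(self):
        mono = sn.SampleSet(np.array([[1.0, 0.0]]))
        duo = sn.SampleSet(np.array([[4.0, 1.0]]))
        swapped_mono = sn.SampleSet(np.array([[4.0, 0.0]]))
        swapped_duo = sn.SampleSet(np.array([[1.0, 1.0]]))
        a = sn.relative_yield(mono, duo, 0, 1)
        b = sn.relative_yield(swapped_mono, swapped_duo, 0, 1)
        assert a == pytest.approx(-b)

    def test_missing_sample_errors(self):
        mono = sn.SampleSet(np.array([[1.0, 0.0]]))
        with pytest.raises(ValueError, match="no sample"):
            sn.relative_yield(mono, mono, 0, 1)


class TestInvasionPrediction:
    def test_direction_follows_sign(self):
        values = np.array([[-1, 1, 0], [-1, -1, -1], [0, 1, -1]], dtype=np.int8)
        signs = SignMatrix.from_values(values)
        pred = sn.predict_invasion_response(signs, invader=1)
        assert pred == {0: 1, 2: 1}

    def test_undetermined_is_unpredictable(self):
        values = np.array([[-1, 1], [0, -1]], dtype=np.int8)
        det = np.array([[True, False], [True, True]])
        signs = SignMatrix(values=values, determined=det)
        pred = sn.predict_invasion_response(signs, invader=1)
        assert pred == {0: None}


class TestSignAccuracy:
    def test_identical_matrices(self):
        m = SignMatrix.from_values(np.array([[-1, 1], [0, -1]], dtype=np.int8))
        res = sn.sign_accuracy(m, m)
        assert res.accuracy == 100.0 and res.accuracy_overall == 100.0

    def test_partial_accuracy_arithmetic(self):
        """50 correct of 64 determined signs -> 78.13%."""
        rng = np.random.default_rng(2)
        truth_vals = rng.integers(-1, 2, size=(8, 8)).astype(np.int8)
        inferred_vals = truth_vals.copy()
        # flip 14 entries to a different sign
        flat = rng.choice(64, size=14, replace=False)
        for k in flat:
            i, j = divmod(int(k), 8)
            inferred_vals[i, j] = ((truth_vals[i, j] + 2) % 3) - 1
        res = sn.sign_accuracy(
            SignMatrix.from_values(inferred_vals),
            SignMatrix.from_values(truth_vals),
        )
        assert res.accuracy == pytest.approx(100 * 50 / 64, abs=0.01)

    def test_all_undetermined(self):
        vals = np.zeros((3, 3), dtype=np.int8)
        inferred = SignMatrix(values=vals, determined=np.zeros((3, 3), bool))
        truth = SignMatrix.from_values(vals)
        res = sn.sign_accuracy(inferred, truth)
        assert res.n_determined == 0 and res.accuracy == 0.0

    def test_shape_mismatch(self):
        a = SignMatrix.from_values(np.zeros((2, 2), dtype=np.int8))
        b = SignMatrix.from_values(np.zeros((3, 3), dtype=np.int8))
        with pytest.raises(ValueError):
            sn.sign_accuracy(a, b)


class TestNrmse:
    def test_zero_for_perfect_estimates(self):
        A = np.array([[-1.0, 0.2], [0.0, -1.0]])
        r = np.array([0.5, 1.0])
        out = sn.nrmse(A, A, r, r)
        assert out["A"] == 0.0 and out["r"] == 0.0

    def test_known_value(self):
        A = np.array([[-1.0, 1.0], [0.0, -1.0]])
        A_hat = A + 0.1
        # RMSE = 0.1, spread = 2 -> 0.05
        assert sn.nrmse(A_hat, A)["A"] == pytest.approx(0.05)


class TestRobustness:
    def test_eta_zero_keeps_everything(self, glv8):
        _, samples = glv8

        def infer_fn(ss):
            return sn.infer_sign_matrix(ss, psi=40, seed=5,
                                        check_assumptions=False)[0]

        out = sn.robustness_analysis(
            samples, [0.0], reps=2, infer_fn=infer_fn,
            rng=np.random.default_rng(0),
        )
        assert np.all(out[0.0] == 100.0)

    def test_percentages_bounded(self, glv8):
        _, samples = glv8
        rng = np.random.default_rng(1)

        def infer_fn(ss):
            return sn.infer_sign_matrix(
                ss, psi=40, seed=int(rng.integers(2**31 - 1)),
                check_assumptions=False,
            )[0]

        out = sn.robustness_analysis(
            samples, [0.1], reps=3, infer_fn=infer_fn, rng=rng
        )
        assert np.all((out[0.1] >= 0) & (out[0.1] <= 100))

    def test_reps_validation(self, glv8):
        _, samples = glv8
        with pytest.raises(ValueError):
            sn.robustness_analysis(samples, [0.1], reps=1, infer_fn=lambda s: None)


def test_min_sample_size_trivial_target():
    """A 0+% accuracy target is met at the smallest omega tried."""
    res = sn.min_sample_size_experiment(
        "glv", [5], accuracy_target=1.0, n_draws=2, omega_step=4,
        rng=np.random.default_rng(3),
    )
    assert res["omega_star"][5] == 4
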