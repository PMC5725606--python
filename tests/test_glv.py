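"""GLV quantitative inference: hyperplane fits, growth rates, Lasso, knockoffs."""

import numpy as np
import pytest

import steadynet as sn
from steadynet.diagnostics import fdr_offdiagonal


class TestConsistencyCheck:
    def test_noiseless_glv_r2_is_one(self, glv8):
        _, samples = glv8
        for taxon in range(samples.n_taxa):
            d = sn.glv_consistency_check(samples, taxon)
            if not d.underdetermined:
                assert d.r_squared > 1 - 1e-9

    def test_non_glv_row_has_low_r2(self):
        """Strongly saturating dynamics push steady states well off any
        hyperplane, giving R^2 clearly below 1 (the model-inconsistency
        signal, comparable to the illustrative 0.77 regime)."""
        import itertools

        rng = np.random.default_rng(9)
        A = np.array([[-6.0, 1.2, -0.8],
                      [0.9, -6.0, 1.0],
                      [-1.1, 0.7, -6.0]])
        model = sn.DynamicsModel(
            "holling2", sn.EcologicalNetwork(A, 1.0),
            growth_rates=np.array([4.0, 3.5, 4.5]), c=1.0,
        )
        rows = [
            x
            for size in (1, 2, 3)
            for supp in itertools.combinations(range(3), size)
            if (x := sn.integrate_to_steady_state(model, set(supp), rng=rng))
            is not None
        ]
        samples = sn.SampleSet(np.array(rows))
        r2 = [sn.glv_consistency_check(samples, i).r_squared for i in range(3)]
        assert min(r2) < 0.9

    def test_single_sample_underdetermined(self):
        ss = sn.SampleSet(np.array([[1.0, 2.0]]))
        d = sn.glv_consistency_check(ss, 0)
        assert d.underdetermined


class TestExactFit:
    def test_toy_recovery(self, toy_samples):
        row, deficient = sn.fit_row_exact(toy_samples, 0, a_ii=-1.0)
        assert not deficient or toy_samples.n_samples < 3
        assert np.allclose(row, [-1.0, 0.5])
        assert sn.estimate_growth_rate(row, toy_samples, 0) == pytest.approx(1.0)

    def test_diagonal_network_gives_zero_offdiagonals(self):
        rng = np.random.default_rng(10)
        net = sn.EcologicalNetwork(np.diag([-1.0, -1.0, -1.0]), 0.0)
        model = sn.DynamicsModel("glv", net, np.array([1.0, 0.5, 0.8]))
        samples, _ = sn.generate_sample_set(model, 7, rng=rng)
        for i in range(3):
            row, _ = sn.fit_row_exact(samples, i, a_ii=-1.0)
            off = [row[j] for j in range(3) if j != i]
            assert np.allclose(off, 0.0, atol=1e-9)

    def test_zero_aii_rejected(self, toy_samples):
        with pytest.raises(ValueError):
            sn.fit_row_exact(toy_samples, 0, a_ii=0.0)

    def test_exact_recovery_noiseless(self):
        """Known a_ii on noiseless data recovers A and r to machine precision."""
        rng = np.random.default_rng(21)
        model = sn.random_glv_model(12, 0.4, rng=rng)
        samples, _ = sn.generate_sample_set(model, 60, rng=rng)
        params = sn.infer_glv(samples, a_ii_known=-1.0, method="exact")
        assert np.abs(params.A - model.network.adjacency).max() < 1e-10
        assert np.abs(params.r - model.growth_rates).max() < 1e-10

    def test_hyperplane_identity(self):
        """Every noiseless steady state satisfies a_i . x + r_i = 0 on-support."""
        rng = np.random.default_rng(22)
        model = sn.random_glv_model(10, 0.4, rng=rng)
        samples, _ = sn.generate_sample_set(model, 30, rng=rng)
        A, r = model.network.adjacency, model.growth_rates
        for x, supp in zip(samples.abundances, samples.supports):
            for i in supp:
                assert abs(A[i] @ x + r[i]) < 1e-8


class TestGrowthRate:
    def test_zero_row_gives_zero_rate(self, toy_samples):
        assert sn.estimate_growth_rate(np.zeros(2), toy_samples, 0) == 0.0

    def test_mean_over_samples(self):
        ss = sn.SampleSet(np.array([[1.0, 1.0], [2.0, 0.0]]))
        # -a.x per sample: -( -1*1 + 0*1 ) = 1 and 2 -> mean 1.5
        assert sn.estimate_growth_rate(np.array([-1.0, 0.0]), ss, 0) == 1.5


class TestHalfNormalPrior:
    def test_draws_are_negative_and_near_minus_one(self):
        rng = np.random.default_rng(0)
        draws = [sn.half_normal_aii(rng) for _ in range(2000)]
        assert all(d < 0 for d in draws)
        assert abs(np.mean(draws) + 1.0) < 0.02  # sd 0.1 around -1


class TestLassoRow:
    def test_near_exact_on_noiseless_data(self):
        rng = np.random.default_rng(30)
        model = sn.random_glv_model(10, 0.4, rng=rng)
        samples, _ = sn.generate_sample_set(model, 60, rng=rng)
        row, r0 = sn.lasso_infer_row(samples, 0, a_ii=-1.0, seed=0)
        true_row = model.network.adjacency[0]
        # CV-chosen penalty leaves a little shrinkage; recovery is close
        assert np.abs(row - true_row).max() < 0.01
        assert abs(r0 - model.growth_rates[0]) < 0.02


class TestKnockoffRow:
    def test_invalid_q(self, toy_samples):
        with pytest.raises(ValueError):
            sn.knockoff_filter_row(toy_samples, 0, q=1.0)

    def test_null_row_selects_nothing(self):
        """Taxon 0 interacts with nobody: selection should stay empty."""
        rng = np.random.default_rng(31)
        A = sn.random_network(10, 0.4, rng=rng).adjacency
        A[0, 1:] = 0.0
        net = sn.EcologicalNetwork(A, 0.4)
        model = sn.DynamicsModel("glv", net, sn.simulate.random_growth_rates(10, rng))
        samples, _ = sn.generate_sample_set(model, 60, rng=rng)
        noisy = sn.add_noise(samples, 0.05, rng)
        _, _, selected, ok = sn.knockoff_filter_row(noisy, 0, q=0.2, rng=rng)
        assert ok
        assert len(selected) <= 2  # null row: false selections are rare

    def test_fdr_controlled_on_noisy_community(self):
        """Matrix-wide FDR of the knockoff path stays near/below q."""
        rng = np.random.default_rng(32)
        fdrs = []
        for seed in range(2):
            model = sn.random_glv_model(30, 0.4, rng=rng)
            samples, _ = sn.generate_sample_set(model, 150, rng=rng)
            noisy = sn.add_noise(samples, 0.1, rng)
            params = sn.infer_glv(noisy, q=0.2, seed=seed)
            fdrs.append(fdr_offdiagonal(params.A, model.network.adjacency))
        assert np.mean(fdrs) <= 0.2 + 0.1  # small-sample Monte-Carlo slack


def test_infer_glv_flags_inconsistent_rows():
    rng = np.random.default_rng(33)
    model = sn.random_model("holling2", 6, 0.6, rng=rng, scale=0.5)
    samples = None
    for _ in range(10):
        try:
            samples, _ = sn.generate_sample_set(model, 25, rng=rng)
            break
        except RuntimeError:
            continue
    assert samples is not None
    params = sn.infer_glv(samples, a_ii_known=-1.0, seed=0)
    r2 = [d.r_squared for d in params.diagnostics if d.r_squared is not None]
    assert min(r2) < 1 - 1e-6
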