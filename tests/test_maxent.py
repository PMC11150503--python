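import numpy as np
import pytest

from antforage.features import OccupancyMatrix
from antforage.maxent import (PairwiseModel, calibrate_beta, exact_distribution,
                              fit_independent, fit_pairwise, goodness_of_fit,
                              occupancy_vs_beta, pairwise_fraction,
                              polish_fields, sample_equilibrium, score)


def _occ(X, fr=2.0):
    X = np.asarray(X, dtype=np.uint8)
    return OccupancyMatrix(X, fr, list(range(X.shape[1])))


@pytest.fixture(scope="module")
def two_spin_model():
    # h = (1, -1), J12 = 0.5, beta = 1
    return PairwiseModel(np.array([1.0, -1.0]),
                         np.array([[0.0, 0.5], [0.5, 0.0]]))


class TestScoreAndEnumeration:
    def test_zero_parameters_zero_score(self):
        m = PairwiseModel(np.zeros(3), np.zeros((3, 3)))
        assert score(m, np.array([1, 0, 1])) == 0.0

    def test_two_spin_example(self, two_spin_model):
        assert score(two_spin_model, np.array([1, 1])) == pytest.approx(0.5)

    def test_global_flip_symmetry_at_zero_field(self):
        rng = np.random.default_rng(0)
        J = rng.normal(0, 0.4, (4, 4))
        J = np.triu(J, 1)
        J = J + J.T
        m = PairwiseModel(np.zeros(4), J)
        s = np.array([1, -1, 1, 1])
        assert score(m, s) == pytest.approx(score(m, -s))

    def test_exact_two_spin_probability(self, two_spin_model):
        ed = exact_distribution(two_spin_model)
        # Z = 2 e^0.5 + e^1.5 + e^-2.5
        assert ed.Z == pytest.approx(2 * np.e**0.5 + np.e**1.5 + np.e**-2.5)
        idx = next(k for k, s in enumerate(ed.states) if tuple(s) == (1, -1))
        assert ed.probs[idx] == pytest.approx(np.e**1.5 / ed.Z, abs=1e-12)
        assert ed.probs[idx] == pytest.approx(0.570, abs=5e-4)
        assert ed.probs.sum() == pytest.approx(1.0, abs=1e-10)

    def test_single_free_spin_uniform(self):
        ed = exact_distribution(PairwiseModel(np.zeros(1), np.zeros((1, 1))))
        assert np.allclose(ed.probs, 0.5)

    def test_enumeration_guard(self):
        m = PairwiseModel(np.zeros(21), np.zeros((21, 21)))
        with pytest.raises(ValueError, match="N <= 20"):
            exact_distribution(m)

    def test_temperature_rescaling_degeneracy(self):
        """Scaling (h, J) by c and beta by 1/c leaves the distribution
        invariant; training may therefore fix beta = 1."""
        rng = np.random.default_rng(1)
        J = np.triu(rng.normal(0, 0.3, (5, 5)), 1)
        J = J + J.T
        h = rng.normal(0, 0.5, 5)
        a = exact_distribution(PairwiseModel(h, J, beta=1.0))
        b = exact_distribution(PairwiseModel(3.0 * h, 3.0 * J, beta=1.0 / 3.0))
        assert np.allclose(a.probs, b.probs, atol=1e-12)


class TestSampler:
    def test_free_spins_half_occupancy(self):
        m = PairwiseModel(np.zeros(5), np.zeros((5, 5)))
        X = sample_equilibrium(m, 4000, thin_sweeps=2, seed=0)
        se = np.sqrt(0.25 / 4000)
        assert np.abs(X.mean(axis=0) - 0.5).max() < 4 * se

    def test_two_spin_matches_enumeration(self, two_spin_model):
        ed = exact_distribution(two_spin_model)
        idx = next(k for k, s in enumerate(ed.states) if tuple(s) == (1, -1))
        X = sample_equilibrium(two_spin_model, 8000, thin_sweeps=5, seed=2)
        S = 2 * X.astype(int) - 1
        emp = np.mean((S[:, 0] == 1) & (S[:, 1] == -1))
        se = np.sqrt(ed.probs[idx] * (1 - ed.probs[idx]) / 8000)
        assert abs(emp - ed.probs[idx]) < 4 * se

    def test_reproducible(self, two_spin_model):
        a = sample_equilibrium(two_spin_model, 100, seed=9)
        b = sample_equilibrium(two_spin_model, 100, seed=9)
        assert (a == b).all()

    def test_total_variation_shrinks_with_samples(self):
        """Ergodicity: empirical state distribution approaches enumeration."""
        rng = np.random.default_rng(3)
        J = np.triu(rng.normal(0, 0.3, (6, 6)), 1)
        J = J + J.T
        m = PairwiseModel(rng.normal(0, 0.3, 6), J)
        ed = exact_distribution(m)
        pows = 1 << np.arange(6)

        def tv(n):
            X = sample_equilibrium(m, n, thin_sweeps=3, seed=4)
            idx = X.astype(int) @ pows
            emp = np.bincount(idx, minlength=64) / n
            return 0.5 * np.abs(emp - ed.probs).sum()

        assert tv(100_000) < tv(1000)


class TestFits:
    def test_independent_closed_form(self):
        occ = _occ(np.ones((98, 1)))
        m = fit_independent(occ)
        assert m.is_null and m.J.max() == 0.0
        assert m.h[0] == pytest.approx(np.arctanh(0.98))
        half = _occ(np.r_[np.ones((50, 1)), np.zeros((50, 1))])
        assert fit_independent(half).h[0] == pytest.approx(0.0, abs=1e-12)
        p8 = _occ(np.r_[np.ones((8, 1)), np.zeros((2, 1))])  # p=0.75 smoothed
        assert fit_independent(p8, pseudocount=0.0).h[0] == pytest.approx(
            0.5 * np.log(4), abs=1e-12)

    def test_independent_round_trip_recovers_p(self):
        rng = np.random.default_rng(5)
        p_true = np.array([0.1, 0.3, 0.6, 0.9])
        X = (rng.random((5000, 4)) < p_true).astype(np.uint8)
        m = fit_independent(_occ(X))
        Y = sample_equilibrium(m, 5000, thin_sweeps=1, seed=6)
        se = np.sqrt(p_true * (1 - p_true) / 5000)
        assert (np.abs(Y.mean(axis=0) - X.mean(axis=0)) < 4 * se + 1e-3).all()

    def test_pairwise_on_fair_coins_recovers_nothing(self):
        X = (np.random.default_rng(7).random((20_000, 10)) < 0.5).astype(np.uint8)
        m = fit_pairwise(_occ(X))
        iu = np.triu_indices(10, 1)
        assert np.abs(m.J[iu]).mean() < 0.05
        assert np.abs(m.h).max() < 0.05
        assert m.fit_meta["converged"]

    def test_parameter_recovery_sparse_model(self):
        """Pseudolikelihood recovers a known sparse (h, J) from Glauber
        samples: r(h) >= 0.9, r(J) >= 0.8 at 25 nodes, 2e4 samples."""
        rng = np.random.default_rng(42)
        N = 25
        h = rng.normal(0, 0.3, N)
        iu = np.triu_indices(N, 1)
        J = np.zeros((N, N))
        J[iu] = rng.normal(0, 0.35, len(iu[0])) * (rng.random(len(iu[0])) < 0.12)
        J = J + J.T
        X = sample_equilibrium(PairwiseModel(h, J), 20_000,
                               burn_in_sweeps=500, thin_sweeps=5, seed=1)
        fit = fit_pairwise(_occ(X))
        assert np.corrcoef(fit.h, h)[0, 1] >= 0.9
        assert np.corrcoef(fit.J[iu], J[iu])[0, 1] >= 0.8

    def test_symmetrization_does_not_move_objective(self):
        """The PL objective of the symmetrized J stays within tolerance of the
        directed optimum's on recovery-type data."""
        from antforage.maxent import _pseudolikelihood

        rng = np.random.default_rng(8)
        J = np.zeros((8, 8))
        iu = np.triu_indices(8, 1)
        J[iu] = rng.normal(0, 0.3, len(iu[0]))
        J = J + J.T
        m = PairwiseModel(rng.normal(0, 0.2, 8), J)
        X = sample_equilibrium(m, 8000, thin_sweeps=3, seed=9)
        S = 2 * X.astype(float) - 1
        fit = fit_pairwise(_occ(X))
        pl_sym = _pseudolikelihood(S, fit.h, fit.J) / len(S)
        pl_true = _pseudolikelihood(S, m.h, m.J) / len(S)
        assert pl_sym >= pl_true - 0.01

    def test_polish_pins_occupancies(self):
        rng = np.random.default_rng(10)
        X = (rng.random((4000, 12)) < np.linspace(0.05, 0.5, 12)).astype(np.uint8)
        occ = _occ(X)
        m = polish_fields(fit_pairwise(occ), occ, seed=3)
        Y = sample_equilibrium(m, 3000, seed=4)
        assert np.abs(Y.mean(0) - X.mean(0)).max() < 0.05


class TestGoodnessAndBeta:
    def test_self_consistency(self):
        rng = np.random.default_rng(11)
        J = np.zeros((10, 10))
        iu = np.triu_indices(10, 1)
        J[iu] = rng.normal(0, 0.25, len(iu[0])) * (rng.random(len(iu[0])) < 0.3)
        J = J + J.T
        m = PairwiseModel(rng.normal(-0.3, 0.3, 10), J)
        X = sample_equilibrium(m, 6000, thin_sweeps=3, seed=12)
        rep = goodness_of_fit(m, _occ(X), n_samples=6000, seed=13)
        assert rep["occupancy_rmse"] < 0.05
        assert rep["pair_corr_r"] > 0.7

    def test_null_matches_means_not_correlations(self):
        rng = np.random.default_rng(14)
        z = (rng.random(4000) < 0.4).astype(np.uint8)
        noise = (rng.random((4000, 6)) < 0.15).astype(np.uint8)
        X = np.clip(z[:, None] | noise, 0, 1)  # strongly correlated columns
        occ = _occ(X)
        rep = goodness_of_fit(fit_independent(occ), occ, n_samples=4000, seed=15)
        assert rep["occupancy_rmse"] < 0.05
        assert abs(rep["pair_corr_r"]) < 0.5 or rep["pair_corr_rmse"] > 0.05

    def test_infinite_temperature_limit(self):
        m = PairwiseModel(np.full(6, -2.0), np.zeros((6, 6)))
        curve = occupancy_vs_beta(m, [1e-3], n_samples=2000, seed=16)
        assert curve[0][1] == pytest.approx(0.5, abs=0.03)

    def test_strong_negative_field_empties(self):
        m = PairwiseModel(np.full(6, -2.0), np.zeros((6, 6)))
        curve = occupancy_vs_beta(m, [5.0], n_samples=2000, seed=17)
        assert curve[0][1] < 0.01

    def test_calibration_fixed_point_and_tolerance(self):
        m = PairwiseModel(np.full(8, -1.0), np.zeros((8, 8)))
        X = sample_equilibrium(m, 4000, seed=18)
        target = float(X.mean())
        b = calibrate_beta(m, target, tol=0.01, seed=19)
        assert 0.8 <= b <= 1.25
        achieved = float(sample_equilibrium(m.with_beta(b), 4000, seed=20).mean())
        assert abs(achieved - target) <= 0.02

    def test_unreachable_target_raises(self):
        m = PairwiseModel(np.full(4, -3.0), np.zeros((4, 4)))
        with pytest.raises(ValueError, match="outside achievable"):
            calibrate_beta(m, 0.95, seed=21)


class TestPairwiseFraction:
    def test_two_nodes_always_one(self):
        rng = np.random.default_rng(22)
        X = (rng.random((3000, 2)) < [0.3, 0.6]).astype(np.uint8)
        X[:, 1] |= X[:, 0]  # correlated pair
        assert pairwise_fraction(_occ(X), [0, 1]) == pytest.approx(1.0, abs=1e-6)

    def test_parity_distribution_zero(self):
        rng = np.random.default_rng(23)
        a = rng.integers(0, 2, 8000)
        b = rng.integers(0, 2, 8000)
        X = np.stack([a, b, (a + b) % 2], axis=1).astype(np.uint8)
        assert pairwise_fraction(_occ(X), [0, 1, 2]) < 0.01

    def test_subset_guard(self):
        X = np.zeros((10, 12), dtype=np.uint8)
        with pytest.raises(ValueError, match="max 10"):
            pairwise_fraction(_occ(X), list(range(11)))
        with pytest.raises(ValueError, match="at least 2"):
            pairwise_fraction(_occ(X), [0])


def test_model_json_round_trip(tmp_path, two_spin_model):
    rng = np.random.default_rng(24)
    J = np.triu(rng.normal(0, 0.3, (7, 7)), 1)
    J = J + J.T
    m = PairwiseModel(rng.normal(0, 1, 7), J, beta=0.9,
                      fit_meta={"method": "test", "lambda": 0.01})
    m.to_json(tmp_path / "m.json")
    back = PairwiseModel.from_json(tmp_path / "m.json")
    assert np.array_equal(back.h, m.h)          # exact round trip
    assert np.array_equal(back.J, m.J)
    assert back.beta == m.beta and back.fit_meta["lambda"] == 0.01
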