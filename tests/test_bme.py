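import itertools

import numpy as np
import pytest
from scipy.optimize import minimize

from ensaxs.bme import (
    MaxEntReweighting,
    bme_weights,
    effective_fraction,
    relative_entropy,
    theta_scan,
)
from ensaxs.core import Ensemble, ScatteringProfile
from ensaxs.debye import ensemble_profiles
from ensaxs.synthetic import default_q_grid, make_mixture_ensemble, make_target_profile
from ensaxs.synthetic import MixtureSpec, Subpopulation


def _target(I_exp, sigma):
    m = len(I_exp)
    q = 0.01 * np.arange(1, m + 1)
    return ScatteringProfile(q=q, I=np.asarray(I_exp, float),
                             sigma=np.asarray(sigma, float))


def objective(w, I, y, sig, w0, theta):
    chi2 = (((w @ I - y) / sig) ** 2).sum()
    return 0.5 * chi2 - theta * relative_entropy(w, w0)


def softmax_minimize(I, y, sig, w0, theta):
    """Independent direct minimization under a softmax parametrization."""
    n = I.shape[0]

    def f(z):
        z = z - z.max()
        w = np.exp(z)
        w /= w.sum()
        return objective(w, I, y, sig, w0, theta)

    best = np.inf
    for start in range(3):
        rng = np.random.default_rng(start)
        res = minimize(f, rng.normal(scale=0.5, size=n), method="Nelder-Mead",
                       options={"xatol": 1e-10, "fatol": 1e-12, "maxiter": 20000})
        best = min(best, res.fun)
    return best


class TestBmeWeights:
    def test_single_snapshot_forced(self):
        target = _target([2.0, 3.0], [0.5, 0.5])
        res = bme_weights(np.array([[1.0, 1.0]]), target, theta=5.0)
        assert np.array_equal(res.weights, [1.0])
        assert res.entropy == 0.0
        assert res.phi_eff == 1.0

    def test_huge_theta_returns_prior(self, rng):
        I = rng.uniform(1, 5, size=(6, 4))
        target = _target(rng.uniform(1, 5, 4), rng.uniform(0.2, 1, 4))
        res = bme_weights(I, target, theta=1e9)
        assert np.abs(res.weights - 1 / 6).max() < 1e-4

    def test_toy_instance_matches_grid_oracle(self):
        # printed integer intensities, N=3 snapshots, M=2 points
        I = np.array([[1.0, 4.0], [3.0, 2.0], [5.0, 1.0]])
        target = _target([3.0, 2.0], [1.0, 1.0])
        theta = 2.0
        res = bme_weights(I, target, theta=theta)
        w0 = np.full(3, 1 / 3)
        best = np.inf
        m = 1000
        for a in range(m + 1):
            for b in range(m + 1 - a):
                w = np.array([a, b, m - a - b]) / m
                best = min(best, objective(w, I, target.I, target.sigma, w0, theta))
        assert res.objective <= best + 1e-6
        assert abs(res.objective - best) < 1e-4  # grid resolution limit

    def test_never_worse_than_prior(self, rng):
        for k in range(10):
            r = np.random.default_rng(k)
            I = r.uniform(1, 10, size=(8, 5))
            target = _target(r.uniform(1, 10, 5), r.uniform(0.3, 2, 5))
            res = bme_weights(I, target, theta=float(r.uniform(0.5, 50)))
            w0 = np.full(8, 1 / 8)
            L0 = objective(w0, I, target.I, target.sigma, w0, res.theta)
            assert res.objective <= L0 + 1e-10
            assert res.weights.min() >= -1e-9
            assert res.weights.sum() == pytest.approx(1.0, abs=1e-9)

    def test_matches_softmax_minimizer(self, rng):
        I = rng.uniform(1, 6, size=(3, 2))
        target = _target(rng.uniform(1, 6, 2), rng.uniform(0.5, 1.5, 2))
        res = bme_weights(I, target, theta=3.0)
        ref = softmax_minimize(I, target.I, target.sigma, np.full(3, 1 / 3), 3.0)
        assert res.objective <= ref + 1e-6

    def test_invalid_inputs(self, rng):
        I = rng.uniform(1, 5, size=(4, 3))
        target = _target(rng.uniform(1, 5, 3), rng.uniform(0.2, 1, 3))
        with pytest.raises(ValueError):
            bme_weights(I, target, theta=0.0)
        with pytest.raises(ValueError):
            bme_weights(I, target, w0=np.array([0.5, 0.5, 0.5, 0.5]), theta=1.0)
        bad = ScatteringProfile(q=target.q, I=target.I)
        with pytest.raises(ValueError, match="sigma"):
            bme_weights(I, bad, theta=1.0)


class TestEffectiveFraction:
    def test_uniform_is_one(self):
        assert effective_fraction(np.full(5, 0.2)) == pytest.approx(1.0, abs=1e-12)

    def test_one_hot_quarter(self):
        w = np.array([1.0, 0.0, 0.0, 0.0])
        assert effective_fraction(w) == pytest.approx(0.25, abs=1e-12)

    def test_matches_direct_formula(self, rng):
        w = rng.dirichlet(np.ones(10))
        w0 = np.full(10, 0.1)
        direct = np.exp(-(w * np.log(w / w0)).sum())
        assert effective_fraction(w) == pytest.approx(direct, rel=1e-12)


class TestThetaScan:
    def test_frontier_monotonicity(self, rng):
        I = rng.uniform(1, 10, size=(15, 8))
        target = _target(rng.uniform(1, 10, 8), rng.uniform(0.2, 1, 8))
        scan = theta_scan(I, target, theta_grid=np.geomspace(0.1, 1e4, 12))
        assert not scan.failed
        assert np.all(np.diff(scan.chi2) >= -1e-6)
        assert np.all(np.diff(scan.phi_eff) >= -1e-6)
        assert scan.phi_eff[-1] > 0.99

    def test_selectors(self, rng):
        I = rng.uniform(1, 10, size=(15, 8))
        target = _target(rng.uniform(1, 10, 8), rng.uniform(0.2, 1, 8))
        scan = theta_scan(I, target, theta_grid=np.geomspace(0.1, 1e4, 12))
        th = scan.select_elbow()
        assert scan.thetas[0] <= th <= scan.thetas[-1]
        th_phi = scan.select_phi_eff(0.7)
        k = np.flatnonzero(scan.thetas == th_phi)[0]
        assert scan.phi_eff[k] >= 0.7 or k == len(scan.thetas) - 1


@pytest.fixture(scope="module")
def tiny_mixture(tiny_topology):
    spec = MixtureSpec(
        topology=tiny_topology,
        subpopulations=(Subpopulation("compact", 5.0), Subpopulation("ext", 0.0)),
        fractions=(0.7, 0.3),
        n_conformers=40,
        seed=3,
    )
    ens, labels = make_mixture_ensemble(spec)
    fr = np.array(spec.fractions)
    counts = np.bincount(labels)
    w_true = fr[labels] / counts[labels]
    q = default_q_grid(n=40)
    target = make_target_profile(ens, w_true, q, noise_frac=0.01, seed=5)
    return ens, labels, w_true, target


class TestIterativeProtocol:
    def test_identical_snapshots_stay_uniform(self, tiny_topology):
        from ensaxs.synthetic import sample_conformer

        c = sample_conformer(tiny_topology, 0.0, seed=1, n_sweeps=1)
        ens = Ensemble([c] * 5)
        q = default_q_grid(n=30)
        target = make_target_profile(ens, np.full(5, 0.2), q, noise_frac=0.01, seed=2)
        model = MaxEntReweighting.from_ensemble(ens, target)
        res = model.fit_iterative(theta=5.0)
        assert np.abs(res.weights - 0.2).max() < 1e-9
        # averaged (c1, c2) equal any single snapshot's fit (all identical)
        from ensaxs.debye import fit_form_factors

        fit, _ = fit_form_factors(c, target)
        assert res.c1 == pytest.approx(fit.c1, abs=1e-6)
        assert res.c2 == pytest.approx(fit.c2, abs=1e-6)

    def test_one_hot_average_returns_snapshot_params(self):
        c1s = np.array([0.97, 1.01, 1.03])
        c2s = np.array([-0.5, 0.2, 2.0])
        w = np.array([0.0, 1.0, 0.0])
        assert float(w @ c1s) == pytest.approx(1.01)
        assert float(w @ c2s) == pytest.approx(0.2)

    def test_round2_does_not_degrade_fit(self, tiny_mixture):
        ens, _, _, target = tiny_mixture
        model = MaxEntReweighting.from_ensemble(ens, target)
        res = model.fit_iterative(theta=2.0)
        assert len(res.history) == 2
        chi1 = res.history[0]["chi2"]
        chi2 = res.history[1]["chi2"]
        assert chi2 <= chi1 * 1.05

    def test_summary_and_tables(self, tiny_mixture):
        ens, _, _, target = tiny_mixture
        I = ensemble_profiles(ens, target.q)
        res = MaxEntReweighting(I, target).fit(theta=5.0)
        text = res.summary()
        assert "phi_eff" in text and "theta" in text
        tab = res.weight_table()
        assert len(tab) == len(ens)
        assert tab["w"].sum() == pytest.approx(1.0, abs=1e-9)
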