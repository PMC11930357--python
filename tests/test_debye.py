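import numpy as np
import pytest
from scipy.optimize import minimize_scalar
from scipy.spatial.transform import Rotation

from ensaxs.core import Conformer, ScatteringProfile, radius_of_gyration
from ensaxs.debye import (
    DebyeFactors,
    FormFactorParams,
    bead_exposure,
    debye_profile,
    ensemble_average_profile,
    fit_form_factors,
    fit_profile,
)
from ensaxs.profiles import guinier_fit
from .conftest import random_conformer


def _conf(coords, weights=None):
    n = len(coords)
    return Conformer(
        np.asarray(coords, float),
        np.arange(1, n + 1),
        np.array(["A"] * n),
        scatter_weight=weights,
    )


Q = np.linspace(0.0, 0.3, 31)


class TestDebyeProfile:
    def test_single_bead_closed_form(self):
        p = FormFactorParams(c1=1.0, c2=0.0, sigma_b=3.0)
        prof = debye_profile(_conf([[0, 0, 0]], weights=[2.0]), Q, p)
        expected = 4.0 * np.exp(-((Q * 3.0) ** 2))
        assert np.allclose(prof.I, expected, atol=1e-12)

    def test_two_beads_closed_form(self):
        d = 10.0
        p = FormFactorParams(c2=0.0, sigma_b=3.0)
        prof = debye_profile(_conf([[0, 0, 0], [d, 0, 0]]), Q, p)
        f2 = np.exp(-((Q * 3.0) ** 2))
        with np.errstate(invalid="ignore"):
            sinc = np.where(Q > 0, np.sin(Q * d) / (Q * d), 1.0)
        assert np.allclose(prof.I / f2, 2 * (1 + sinc), atol=1e-10)
        assert prof.I[0] / f2[0] == pytest.approx(4.0, abs=1e-12)

    def test_matches_brute_force_double_sum(self, globule):
        p = FormFactorParams(c1=0.98, c2=1.5)
        prof = debye_profile(globule, Q, p)
        # independent double loop
        h = bead_exposure(globule)
        f = (
            globule.scatter_weight[:, None]
            * np.exp(-0.5 * (Q * p.sigma_b * p.c1) ** 2)[None, :]
            + p.c2 * h[:, None] * np.exp(-0.5 * (Q * p.sigma_w) ** 2)[None, :]
        )
        I = np.zeros_like(Q)
        for i in range(globule.n_beads):
            for j in range(globule.n_beads):
                r = np.linalg.norm(globule.coords[i] - globule.coords[j])
                with np.errstate(invalid="ignore"):
                    s = np.where(Q * r > 0, np.sin(Q * r) / np.where(Q * r > 0, Q * r, 1), 1.0)
                I += f[i] * f[j] * s
        assert np.allclose(prof.I, I, rtol=1e-10)

    def test_forward_intensity_identity(self, globule):
        p = FormFactorParams(c1=1.0, c2=0.8)
        prof = debye_profile(globule, np.array([0.0]), p)
        h = bead_exposure(globule)
        expected = (globule.scatter_weight.sum() + p.c2 * h.sum()) ** 2
        assert prof.I[0] == pytest.approx(expected, rel=1e-12)

    def test_rigid_transform_invariance(self, globule, rng):
        R = Rotation.random(rng=rng).as_matrix()
        moved = globule.transformed(R, np.array([10.0, -4.0, 2.0]))
        a = debye_profile(globule, Q).I
        b = debye_profile(moved, Q).I
        assert np.allclose(a, b, rtol=1e-9)

    def test_negative_q_rejected(self, globule):
        with pytest.raises(ValueError):
            debye_profile(globule, np.array([-0.1, 0.1]))

    def test_guinier_limit_matches_coordinate_rg(self, globule):
        # point-bead limit: c2 = 0, vanishing bead width
        rg_coord = radius_of_gyration(globule, mass_weights=globule.scatter_weight)
        q = np.linspace(0.005, 0.4 / rg_coord, 40)
        prof = debye_profile(globule, q, FormFactorParams(sigma_b=1e-9, c2=0.0))
        g = guinier_fit(prof, qrg_limit=0.5)
        assert g.rg == pytest.approx(rg_coord, rel=0.01)

    def test_factors_match_direct_evaluation(self, globule):
        fac = DebyeFactors(globule, Q)
        for c1, c2 in [(0.95, -1.0), (1.0, 0.0), (1.05, 3.0)]:
            p = FormFactorParams(c1=c1, c2=c2)
            assert np.allclose(
                fac.intensity(p), debye_profile(globule, Q, p).I, rtol=1e-12
            )


class TestEnsembleAverage:
    def test_one_hot_returns_that_profile(self, rng):
        profs = [debye_profile(random_conformer(rng, 8), Q) for _ in range(4)]
        w = np.array([0.0, 0.0, 1.0, 0.0])
        avg = ensemble_average_profile(profs, w)
        assert np.array_equal(avg.I, profs[2].I)

    def test_matches_manual_weighted_sum(self, rng):
        profs = [debye_profile(random_conformer(rng, 8), Q) for _ in range(5)]
        w = rng.dirichlet(np.ones(5))
        avg = ensemble_average_profile(profs, w)
        manual = sum(wj * p.I for wj, p in zip(w, profs))
        assert np.allclose(avg.I, manual, rtol=1e-12)

    def test_qgrid_mismatch_rejected(self, rng):
        a = debye_profile(random_conformer(rng, 8), Q)
        b = debye_profile(random_conformer(rng, 8), Q * 1.01)
        with pytest.raises(ValueError):
            ensemble_average_profile([a, b], np.array([0.5, 0.5]))


class TestFitProfile:
    def test_exact_scale_recovered(self, globule):
        calc = debye_profile(globule, Q)
        data = ScatteringProfile(q=Q, I=2.5 * calc.I, sigma=0.01 * calc.I + 1.0)
        fit = fit_profile(calc, data)
        assert fit.scale == pytest.approx(2.5, rel=1e-12)
        assert fit.chi2 == pytest.approx(0.0, abs=1e-14)

    def test_closed_form_equals_numeric_minimum(self, globule, rng):
        calc = debye_profile(globule, Q)
        sigma = 0.02 * calc.I
        data = ScatteringProfile(
            q=Q, I=1.7 * calc.I + rng.normal(0, 1, Q.size) * sigma, sigma=sigma
        )
        fit = fit_profile(calc, data)
        res = minimize_scalar(
            lambda s: (((s * calc.I - data.I) / sigma) ** 2).sum(),
            bounds=(0.1, 10.0),
            method="bounded",
            options={"xatol": 1e-12},
        )
        assert fit.scale == pytest.approx(res.x, abs=1e-8)

    def test_pure_noise_reduced_chi2_near_one(self, globule):
        calc = debye_profile(globule, np.linspace(0.01, 0.3, 60))
        sigma = 0.02 * calc.I
        for seed in range(20):
            r = np.random.default_rng(seed)
            data = ScatteringProfile(
                q=calc.q, I=calc.I + r.normal(0, 1, calc.q.size) * sigma, sigma=sigma
            )
            fit = fit_profile(calc, data)
            assert 0.5 <= fit.chi2_reduced <= 2.0

    def test_extrapolation_forbidden(self, globule):
        calc = debye_profile(globule, np.linspace(0.05, 0.2, 20))
        data = ScatteringProfile(
            q=np.linspace(0.01, 0.3, 10), I=np.ones(10), sigma=np.ones(10)
        )
        with pytest.raises(ValueError, match="extrapolation"):
            fit_profile(calc, data)


class TestFitFormFactors:
    def test_recovers_generating_parameters(self, globule):
        p_true = FormFactorParams(c1=1.0, c2=1.0)
        truth = debye_profile(globule, Q[1:], p_true)
        data = ScatteringProfile(q=Q[1:], I=truth.I, sigma=0.005 * truth.I)
        fit, prof = fit_form_factors(globule, data)
        assert fit.c1 == pytest.approx(1.0, abs=0.02)
        assert fit.c2 == pytest.approx(1.0, abs=0.2)
        assert fit.chi2_reduced < 0.5  # noise-free data, near-exact fit

    def test_params_bounds_enforced(self):
        with pytest.raises(ValueError):
            FormFactorParams(c1=0.5)
        with pytest.raises(ValueError):
            FormFactorParams(c2=5.0)
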