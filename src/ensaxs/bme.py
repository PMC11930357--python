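"""Bayesian maximum-entropy (BME) reweighting of conformer ensembles.

Given per-snapshot SAXS profiles I_{j,i} and a target profile (I_exp, sigma),
BME finds ensemble weights w on the simplex minimizing

    L(w) = chi^2(w) / 2 - theta * S(w)

with chi^2(w) = sum_i ( (sum_j w_j I_{j,i} - I_exp,i) / sigma_i )^2 and the
relative entropy S(w) = -sum_j w_j log(w_j / w0_j) to the prior weights w0.
theta trades data fit against departure from the prior; the effective
fraction of the ensemble phi_eff = exp(S(w)) measures that departure.

The optimum is computed through the convex dual: weights are a Gibbs measure
over data-point multipliers mu,

    w_j(mu) = w0_j exp(-mu . x_j) / Z(mu),   x_{j,i} = I_{j,i} / sigma_i,

and mu minimizes Gamma(mu) = log Z(mu) + mu . y + (theta/2) |mu|^2 with
y_i = I_exp,i / sigma_i. Gamma is smooth and strictly convex; a damped Newton
iteration (with an L-BFGS-B fallback) solves it from mu = 0, i.e. w = w0.

The module follows a model/results layout: :class:`MaxEntReweighting` is
built from the data, ``fit`` returns a :class:`ReweightResult` carrying the
weights, fit statistics and a ``summary()`` table. The paper-style
two-round protocol that refits the (c1, c2) form-factor parameters with
weighted averaging between BME rounds is ``fit_iterative``.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.optimize import minimize
from scipy.special import logsumexp

from .core import Ensemble, ScatteringProfile
from .debye import (
    FormFactorParams,
    debye_profile,
    fit_form_factors,
    _scale_fit,
)

__all__ = [
    "MaxEntReweighting",
    "ReweightResult",
    "ThetaScan",
    "bme_weights",
    "theta_scan",
    "iterative_bme",
    "effective_fraction",
    "relative_entropy",
]


def relative_entropy(w: np.ndarray, w0: np.ndarray | None = None) -> float:
    """S(w) = -sum w_j log(w_j / w0_j), with 0 log 0 = 0. S <= 0, and 0 iff w = w0."""
    w = np.asarray(w, dtype=float)
    if w0 is None:
        w0 = np.full_like(w, 1.0 / w.size)
    w0 = np.asarray(w0, dtype=float)
    mask = w > 0
    if np.any(w0[mask] <= 0):
        raise ValueError("w has mass where w0 is zero; entropy undefined")
    return float(-(w[mask] * np.log(w[mask] / w0[mask])).sum())


def effective_fraction(w: np.ndarray, w0: np.ndarray | None = None) -> float:
    """phi_eff = exp(S(w)): fraction of the ensemble contributing substantially."""
    return float(np.exp(relative_entropy(w, w0)))


def _check_simplex(v: np.ndarray, n: int, name: str) -> np.ndarray:
    v = np.asarray(v, dtype=float)
    if v.shape != (n,):
        raise ValueError(f"{name} must have length {n}")
    if np.any(v < 0) or abs(v.sum() - 1.0) > 1e-8:
        raise ValueError(f"{name} must lie on the probability simplex")
    return v


@dataclass
class ReweightResult:
    """Results of a BME fit.

    Attributes mirror the quantities of the objective: ``chi2`` and
    ``entropy`` at the optimum, ``phi_eff = exp(S)``, the Lagrange
    multipliers of the dual route, and the (scale, c1, c2) in effect.
    """

    weights: np.ndarray
    theta: float
    chi2: float
    entropy: float
    lagrange_multipliers: np.ndarray | None = None
    scale: float = 1.0
    c1: float | None = None
    c2: float | None = None
    n_iter: int = 0
    converged: bool = True
    initial_weights: np.ndarray | None = None
    n_points: int = 0
    history: list = field(default_factory=list)
    model: "MaxEntReweighting | None" = None

    @property
    def phi_eff(self) -> float:
        return float(np.exp(self.entropy))

    @property
    def objective(self) -> float:
        """L(w) = chi^2/2 - theta S."""
        return 0.5 * self.chi2 - self.theta * self.entropy

    @property
    def chi2_reduced(self) -> float:
        return self.chi2 / max(self.n_points, 1)

    def average_profile(self) -> ScatteringProfile:
        if self.model is None:
            raise ValueError("result is detached from its model")
        I = self.weights @ self.model.I_matrix
        return ScatteringProfile(q=self.model.target.q, I=self.scale * I)

    def weight_table(self) -> pd.DataFrame:
        w0 = self.initial_weights
        return pd.DataFrame(
            {
                "snapshot": np.arange(self.weights.size),
                "w0": w0 if w0 is not None else np.nan,
                "w": self.weights,
            }
        )

    def summary(self) -> str:
        lines = [
            "Maximum-entropy ensemble reweighting",
            "=" * 44,
            f"{'snapshots (N)':<28}{self.weights.size:>16d}",
            f"{'data points (M)':<28}{self.n_points:>16d}",
            f"{'theta':<28}{self.theta:>16.6g}",
            f"{'chi^2':<28}{self.chi2:>16.6g}",
            f"{'reduced chi^2':<28}{self.chi2_reduced:>16.6g}",
            f"{'entropy S(w)':<28}{self.entropy:>16.6g}",
            f"{'phi_eff = exp(S)':<28}{self.phi_eff:>16.6g}",
            f"{'L = chi^2/2 - theta S':<28}{self.objective:>16.6g}",
            f"{'scale':<28}{self.scale:>16.6g}",
        ]
        if self.c1 is not None:
            lines.append(f"{'c1 (weighted avg)':<28}{self.c1:>16.6g}")
        if self.c2 is not None:
            lines.append(f"{'c2 (weighted avg)':<28}{self.c2:>16.6g}")
        lines.append(
            f"{'max weight':<28}{self.weights.max():>16.6g}"
        )
        lines.append(f"{'converged':<28}{str(self.converged):>16}")
        return "\n".join(lines)

    def to_dict(self) -> dict:
        return {
            "theta": self.theta,
            "chi2": self.chi2,
            "chi2_reduced": self.chi2_reduced,
            "entropy": self.entropy,
            "phi_eff": self.phi_eff,
            "objective": self.objective,
            "scale": self.scale,
            "c1": self.c1,
            "c2": self.c2,
            "n_iter": self.n_iter,
            "converged": self.converged,
            "weights": self.weights.tolist(),
        }


@dataclass
class ThetaScan:
    """Trade-off table for L-curve selection of theta."""

    thetas: np.ndarray
    chi2: np.ndarray
    entropy: np.ndarray
    phi_eff: np.ndarray
    failed: list[tuple[float, str]] = field(default_factory=list)

    def table(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "theta": self.thetas,
                "chi2": self.chi2,
                "entropy": self.entropy,
                "phi_eff": self.phi_eff,
            }
        )

    def select_elbow(self) -> float:
        """theta at the maximum-curvature elbow of the (log chi^2, S) curve."""
        if self.thetas.size < 3:
            return float(self.thetas[np.argmin(self.chi2)])
        u = np.log10(np.maximum(self.chi2, 1e-300))
        v = self.entropy.copy()
        # normalize both axes so curvature is scale-free
        for a in (u, v):
            rng = a.max() - a.min()
            if rng > 0:
                a -= a.min()
                a /= rng
        du, dv = np.gradient(u), np.gradient(v)
        ddu, ddv = np.gradient(du), np.gradient(dv)
        denom = (du**2 + dv**2) ** 1.5
        with np.errstate(divide="ignore", invalid="ignore"):
            curv = np.abs(du * ddv - dv * ddu) / denom
        curv[~np.isfinite(curv)] = -np.inf
        k = int(np.argmax(curv[1:-1])) + 1 if self.thetas.size > 2 else 0
        return float(self.thetas[k])

    def select_phi_eff(self, threshold: float = 0.7) -> float:
        """Smallest theta keeping phi_eff above the threshold (manual criterion)."""
        ok = np.flatnonzero(self.phi_eff >= threshold)
        if ok.size == 0:
            return float(self.thetas[-1])
        return float(self.thetas[ok.min()])


class MaxEntReweighting:
    """BME reweighting model for an ensemble against a target SAXS profile.

    Parameters
    ----------
    I_matrix : (N, M) array
        Per-snapshot calculated intensities on the target q-grid.
    target : ScatteringProfile
        Target profile with errors sigma > 0.
    w0 : (N,) array, optional
        Prior weights (default uniform).
    ensemble : Ensemble, optional
        Needed only for ``fit_iterative`` (profiles are recalculated).
    """

    def __init__(
        self,
        I_matrix: np.ndarray,
        target: ScatteringProfile,
        w0: np.ndarray | None = None,
        ensemble: Ensemble | None = None,
    ):
        I_matrix = np.atleast_2d(np.asarray(I_matrix, dtype=float))
        sigma = target.require_sigma()
        if I_matrix.shape[1] != len(target):
            raise ValueError("I_matrix and target q-grid lengths differ")
        n = I_matrix.shape[0]
        self.I_matrix = I_matrix
        self.target = target
        self.w0 = (
            np.full(n, 1.0 / n) if w0 is None else _check_simplex(w0, n, "w0")
        )
        self.ensemble = ensemble
        # sigma-standardized design
        self._x = I_matrix / sigma
        self._y = target.I / sigma

    @classmethod
    def from_ensemble(
        cls,
        ensemble: Ensemble,
        target: ScatteringProfile,
        params: FormFactorParams | None = None,
    ) -> "MaxEntReweighting":
        from .debye import ensemble_profiles

        I = ensemble_profiles(ensemble, target.q, params)
        return cls(I, target, w0=ensemble.initial_weights, ensemble=ensemble)

    # -- dual solver --------------------------------------------------------

    def _weights_from_mu(self, mu: np.ndarray, x: np.ndarray) -> np.ndarray:
        logw0 = np.where(self.w0 > 0, np.log(np.maximum(self.w0, 1e-300)), -np.inf)
        logits = logw0 - x @ mu
        logits -= logsumexp(logits)
        return np.exp(logits)

    def _solve_dual(self, theta: float, x: np.ndarray, y: np.ndarray,
                    tol_obj: float = 1e-10, tol_grad: float = 1e-8,
                    max_iter: int = 200) -> tuple[np.ndarray, np.ndarray, int, bool]:
        m = x.shape[1]
        xbar0 = self.w0 @ x
        xc = x - xbar0

        def gamma_parts(mu):
            logw0 = np.where(self.w0 > 0, np.log(np.maximum(self.w0, 1e-300)), -np.inf)
            logits = logw0 - xc @ mu
            lz = logsumexp(logits)
            w = np.exp(logits - lz)
            val = lz + mu @ (y - xbar0) + 0.5 * theta * (mu @ mu)
            grad = y - w @ x + theta * mu
            return val, grad, w

        mu = np.zeros(m)
        val, grad, w = gamma_parts(mu)
        n_iter = 0
        converged = False
        for n_iter in range(1, max_iter + 1):
            gnorm = float(np.linalg.norm(grad))
            if gnorm < tol_grad * max(1.0, float(np.linalg.norm(y))):
                converged = True
                break
            xbar = w @ xc
            dev = xc - xbar
            H = (dev * w[:, None]).T @ dev + theta * np.eye(m)
            try:
                step = np.linalg.solve(H, -grad)
            except np.linalg.LinAlgError:
                step = -grad / (theta + 1.0)
            # backtracking line search on the convex dual
            t = 1.0
            for _ in range(60):
                new_val, new_grad, new_w = gamma_parts(mu + t * step)
                if new_val <= val + 1e-4 * t * (grad @ step):
                    break
                t *= 0.5
            if abs(new_val - val) < tol_obj * max(1.0, abs(val)) and \
               float(np.linalg.norm(new_grad)) < tol_grad * max(1.0, float(np.linalg.norm(y))):
                mu, val, grad, w = mu + t * step, new_val, new_grad, new_w
                converged = True
                break
            mu, val, grad, w = mu + t * step, new_val, new_grad, new_w
        if not converged:
            res = minimize(
                lambda m_: gamma_parts(m_)[0],
                mu,
                jac=lambda m_: gamma_parts(m_)[1],
                method="L-BFGS-B",
                options={"maxiter": 5000, "ftol": 1e-15, "gtol": 1e-12},
            )
            mu = res.x
            val, grad, w = gamma_parts(mu)
            converged = float(np.linalg.norm(grad)) < 1e-5 * max(
                1.0, float(np.linalg.norm(y))
            )
            if not converged:
                raise RuntimeError(
                    f"BME dual failed to converge: |grad|={np.linalg.norm(grad):.3g}, "
                    f"theta={theta}, N={x.shape[0]}, M={m}"
                )
        return w, mu, n_iter, converged

    # -- public API ---------------------------------------------------------

    def fit(self, theta: float, fit_scale: bool = False,
            max_scale_iter: int = 50) -> ReweightResult:
        """Minimize L(w) = chi^2(w)/2 - theta S(w) over the simplex.

        With ``fit_scale`` a single global multiplicative scale applied to
        the calculated profiles is refit (closed form) alternately with the
        weights until both stabilize.
        """
        if theta <= 0:
            raise ValueError("theta must be > 0")
        sigma = self.target.require_sigma()
        scale = 1.0
        w = self.w0
        mu = None
        n_iter = 0
        converged = True
        for _ in range(max_scale_iter if fit_scale else 1):
            x = scale * self._x
            w, mu, it, converged = self._solve_dual(theta, x, self._y)
            n_iter += it
            if not fit_scale:
                break
            I_avg = w @ self.I_matrix
            new_scale, _, _ = _scale_fit(I_avg, self.target.I, sigma, fit_offset=False)
            if abs(new_scale - scale) < 1e-12 * max(1.0, abs(scale)):
                scale = new_scale
                break
            scale = new_scale
        resid = scale * (w @ self._x) - self._y
        chi2 = float(resid @ resid)
        return ReweightResult(
            weights=w,
            theta=float(theta),
            chi2=chi2,
            entropy=relative_entropy(w, self.w0),
            lagrange_multipliers=mu,
            scale=scale,
            n_iter=n_iter,
            converged=converged,
            initial_weights=self.w0,
            n_points=len(self.target),
            model=self,
        )

    def theta_scan(self, theta_grid: np.ndarray, fit_scale: bool = False) -> ThetaScan:
        """Fit each theta in the grid; failures are recorded, not raised."""
        thetas = np.asarray(theta_grid, dtype=float)
        if np.any(thetas <= 0) or np.any(np.diff(thetas) <= 0):
            raise ValueError("theta grid must be positive and increasing")
        chi2 = np.full(thetas.size, np.nan)
        ent = np.full(thetas.size, np.nan)
        phi = np.full(thetas.size, np.nan)
        failed = []
        for k, th in enumerate(thetas):
            try:
                r = self.fit(th, fit_scale=fit_scale)
            except RuntimeError as err:
                failed.append((float(th), str(err)))
                continue
            chi2[k], ent[k], phi[k] = r.chi2, r.entropy, r.phi_eff
        return ThetaScan(thetas=thetas, chi2=chi2, entropy=ent, phi_eff=phi,
                         failed=failed)

    def fit_iterative(
        self,
        theta: float,
        max_rounds: int = 2,
        params: FormFactorParams | None = None,
        fit_scale: bool = True,
    ) -> ReweightResult:
        """Two-round protocol with (c1, c2) averaging.

        1. fit (c1, c2) (and scale) per snapshot against the target;
        2. BME reweighting with the per-snapshot profiles;
        3. weighted average (c1bar, c2bar) = sum_j w_j (c1_j, c2_j);
        4. recompute all profiles at the fixed averaged parameters;
        5. BME again. Both rounds are logged on the result.
        """
        if self.ensemble is None:
            raise ValueError("fit_iterative requires the model to hold an ensemble")
        from dataclasses import replace as _replace

        from .debye import DebyeFactors

        base = params or FormFactorParams()
        history = []
        n = len(self.ensemble)
        c1s, c2s = np.empty(n), np.empty(n)
        I = np.empty_like(self.I_matrix)
        factors = []
        for j, conf in enumerate(self.ensemble):
            fac = DebyeFactors(conf, self.target.q)
            factors.append(fac)
            fit, prof = fit_form_factors(fac, self.target, params=base)
            c1s[j], c2s[j] = fit.c1, fit.c2
            I[j] = prof.I
        model = MaxEntReweighting(I, self.target, w0=self.w0, ensemble=self.ensemble)
        result = model.fit(theta, fit_scale=fit_scale)
        history.append(
            {"round": 1, "chi2": result.chi2, "phi_eff": result.phi_eff,
             "c1": None, "c2": None}
        )
        for rnd in range(2, max_rounds + 1):
            c1bar = float(result.weights @ c1s)
            c2bar = float(result.weights @ c2s)
            pbar = _replace(base, c1=c1bar, c2=c2bar)
            I2 = np.stack([fac.intensity(pbar) for fac in factors])
            model = MaxEntReweighting(I2, self.target, w0=self.w0,
                                      ensemble=self.ensemble)
            result = model.fit(theta, fit_scale=fit_scale)
            result.c1, result.c2 = c1bar, c2bar
            history.append(
                {"round": rnd, "chi2": result.chi2, "phi_eff": result.phi_eff,
                 "c1": c1bar, "c2": c2bar}
            )
        result.history = history
        return result


# -- functional wrappers (module surface) -----------------------------------


def bme_weights(
    I_matrix: np.ndarray,
    target: ScatteringProfile,
    w0: np.ndarray | None = None,
    theta: float = 20.0,
    fit_scale: bool = False,
) -> ReweightResult:
    """Functional form of :meth:`MaxEntReweighting.fit`."""
    return MaxEntReweighting(I_matrix, target, w0=w0).fit(theta, fit_scale=fit_scale)


def theta_scan(
    I_matrix: np.ndarray,
    target: ScatteringProfile,
    w0: np.ndarray | None = None,
    theta_grid: np.ndarray | None = None,
    fit_scale: bool = False,
) -> ThetaScan:
    """Functional form of :meth:`MaxEntReweighting.theta_scan`."""
    if theta_grid is None:
        theta_grid = np.geomspace(0.1, 1e4, 12)
    return MaxEntReweighting(I_matrix, target, w0=w0).theta_scan(
        theta_grid, fit_scale=fit_scale
    )


def iterative_bme(
    ensemble: Ensemble,
    target: ScatteringProfile,
    theta: float,
    max_rounds: int = 2,
    params: FormFactorParams | None = None,
) -> ReweightResult:
    """Functional form of :meth:`MaxEntReweighting.fit_iterative`."""
    model = MaxEntReweighting.from_ensemble(ensemble, target, params=params)
    return model.fit_iterative(theta, max_rounds=max_rounds, params=params)
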