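"""Theoretical SAXS profiles for bead models via the Debye formula.

I(q) = sum_ij f_i(q) f_j(q) sinc(q r_ij), with a two-parameter adjustable
bead form factor

    f_i(q) = f_i(0) exp(-(q sigma_b c1)^2 / 2) + c2 h_i exp(-(q sigma_w)^2 / 2)

where c1 plays the role of an effective excluded-volume adjustment (bead
width), c2 a hydration-layer amplitude on solvent-exposed beads, and h_i is a
cheap exposure proxy (1 minus the fraction of a full neighbour shell within
7 A). The (c1, c2) bounds follow the usual convention for adjustable
form-factor fitting: c1 in [0.95, 1.05], c2 in [-2, 4].
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np
from scipy.optimize import minimize_scalar
from scipy.spatial.distance import pdist, squareform

from .core import Conformer, Ensemble, ScatteringProfile

__all__ = [
    "FormFactorParams",
    "FitResult",
    "DebyeFactors",
    "bead_exposure",
    "debye_profile",
    "ensemble_profiles",
    "ensemble_average_profile",
    "fit_profile",
    "fit_form_factors",
]

C1_BOUNDS = (0.95, 1.05)
C2_BOUNDS = (-2.0, 4.0)
EXPOSURE_CUTOFF = 7.0
MAX_NEIGHBORS = 12


@dataclass(frozen=True)
class FormFactorParams:
    """Adjustable bead form-factor parameters."""

    c1: float = 1.0
    c2: float = 0.0
    sigma_b: float = 3.0  # bead form width, A
    sigma_w: float = 3.0  # hydration-layer width, A

    def __post_init__(self) -> None:
        if not C1_BOUNDS[0] <= self.c1 <= C1_BOUNDS[1]:
            raise ValueError(f"c1 must lie in {C1_BOUNDS}")
        if not C2_BOUNDS[0] <= self.c2 <= C2_BOUNDS[1]:
            raise ValueError(f"c2 must lie in {C2_BOUNDS}")
        if self.sigma_b <= 0 or self.sigma_w <= 0:
            raise ValueError("form widths must be > 0")


@dataclass(frozen=True)
class FitResult:
    """Result of fitting a calculated profile to data."""

    scale: float
    offset: float
    c1: float
    c2: float
    chi2: float
    chi2_reduced: float
    n_points: int

    def to_dict(self) -> dict:
        return {
            "scale": self.scale,
            "offset": self.offset,
            "c1": self.c1,
            "c2": self.c2,
            "chi2": self.chi2,
            "chi2_reduced": self.chi2_reduced,
            "n_points": self.n_points,
        }


def bead_exposure(conformer: Conformer, cutoff: float = EXPOSURE_CUTOFF,
                  max_neighbors: int = MAX_NEIGHBORS) -> np.ndarray:
    """Solvent-exposure proxy per bead: 1 - (neighbours within cutoff)/max."""
    d = squareform(pdist(conformer.coords))
    n = (d <= cutoff).sum(axis=1) - 1  # exclude self
    return np.clip(1.0 - n / max_neighbors, 0.0, 1.0)


def _form_factors(conformer: Conformer, q: np.ndarray, params: FormFactorParams,
                  exposure: np.ndarray | None = None) -> np.ndarray:
    """(n_beads, n_q) array of f_i(q)."""
    f0 = conformer.scatter_weight[:, None]
    core = f0 * np.exp(-0.5 * (q * params.sigma_b * params.c1) ** 2)[None, :]
    if params.c2 == 0.0:
        return core
    h = bead_exposure(conformer) if exposure is None else exposure
    hyd = params.c2 * h[:, None] * np.exp(-0.5 * (q * params.sigma_w) ** 2)[None, :]
    return core + hyd


class DebyeFactors:
    """Conformer-specific structure factors for fast (c1, c2) scans.

    With f_i(q) = a(q) f0_i + b(q) h_i (a, b scalar in q), the Debye sum
    splits into three q-dependent factors computed once:

        I(q) = a^2 S_ff + 2 a b S_fh + b^2 S_hh,
        S_xy(q) = sum_ij x_i y_j sinc(q r_ij).
    """

    def __init__(self, conformer: Conformer, q_grid: np.ndarray):
        q = np.asarray(q_grid, dtype=float)
        if np.any(q < 0):
            raise ValueError("q must be >= 0")
        self.q = q
        self.exposure = bead_exposure(conformer)
        f0 = conformer.scatter_weight
        h = self.exposure
        r = squareform(pdist(conformer.coords))
        # np.sinc(x) = sin(pi x)/(pi x); physics sinc(q r)
        sinc = np.sinc(q[:, None, None] * r[None, :, :] / np.pi)  # (M, n, n)
        self.s_ff = np.einsum("mij,i,j->m", sinc, f0, f0, optimize=True)
        self.s_fh = np.einsum("mij,i,j->m", sinc, f0, h, optimize=True)
        self.s_hh = np.einsum("mij,i,j->m", sinc, h, h, optimize=True)

    def intensity(self, params: FormFactorParams) -> np.ndarray:
        a = np.exp(-0.5 * (self.q * params.sigma_b * params.c1) ** 2)
        b = params.c2 * np.exp(-0.5 * (self.q * params.sigma_w) ** 2)
        return a * a * self.s_ff + 2.0 * a * b * self.s_fh + b * b * self.s_hh

    def profile(self, params: FormFactorParams) -> ScatteringProfile:
        return ScatteringProfile(
            q=self.q,
            I=self.intensity(params),
            metadata={"c1": params.c1, "c2": params.c2},
        )


def debye_profile(
    conformer: Conformer,
    q_grid: np.ndarray,
    params: FormFactorParams | None = None,
    exposure: np.ndarray | None = None,
) -> ScatteringProfile:
    """Debye-sum SAXS profile of a bead conformer (sigma unset).

    ``exposure`` can be passed to reuse a precomputed exposure proxy when
    scanning (c1, c2) for a fixed conformer.
    """
    q = np.asarray(q_grid, dtype=float)
    if np.any(q < 0):
        raise ValueError("q must be >= 0")
    params = params or FormFactorParams()
    f = _form_factors(conformer, q, params, exposure)  # (n, M)
    r = squareform(pdist(conformer.coords))  # (n, n)
    # np.sinc(x) = sin(pi x)/(pi x); sinc(q r) in the physics convention
    sinc = np.sinc(q[:, None, None] * r[None, :, :] / np.pi)  # (M, n, n)
    I = np.einsum("mij,im,jm->m", sinc, f, f, optimize=True)
    return ScatteringProfile(q=q, I=I, metadata={"c1": params.c1, "c2": params.c2})


def ensemble_profiles(
    ensemble: Ensemble,
    q_grid: np.ndarray,
    params: FormFactorParams | None = None,
) -> np.ndarray:
    """Per-conformer intensity matrix, shape (n_conformers, n_q)."""
    return np.stack(
        [debye_profile(c, q_grid, params).I for c in ensemble.conformers]
    )


def ensemble_average_profile(
    profiles: list[ScatteringProfile] | np.ndarray,
    weights: np.ndarray,
    q_grid: np.ndarray | None = None,
) -> ScatteringProfile:
    """Weighted average profile I_avg,i = sum_j w_j I_j,i."""
    w = np.asarray(weights, dtype=float)
    if np.any(w < 0) or abs(w.sum() - 1.0) > 1e-8:
        raise ValueError("weights must lie on the simplex")
    if isinstance(profiles, np.ndarray):
        if q_grid is None:
            raise ValueError("q_grid required with a raw intensity matrix")
        I = profiles
        q = np.asarray(q_grid, dtype=float)
    else:
        q = profiles[0].q
        for p in profiles[1:]:
            if p.q.shape != q.shape or not np.allclose(p.q, q):
                raise ValueError("profiles must share the q-grid")
        I = np.stack([p.I for p in profiles])
    if I.shape[0] != w.size:
        raise ValueError("one weight per profile required")
    return ScatteringProfile(q=q, I=w @ I)


def _interp_onto(calc: ScatteringProfile, q: np.ndarray) -> np.ndarray:
    if calc.q.shape == q.shape and np.allclose(calc.q, q):
        return calc.I
    if q.min() < calc.q.min() - 1e-12 or q.max() > calc.q.max() + 1e-12:
        raise ValueError("data q-range exceeds calculated profile; extrapolation forbidden")
    return np.interp(q, calc.q, calc.I)


def _scale_fit(I_calc: np.ndarray, I_data: np.ndarray, sigma: np.ndarray,
               fit_offset: bool) -> tuple[float, float, float]:
    """Closed-form weighted least-squares scale (and optional offset)."""
    w = 1.0 / sigma**2
    if fit_offset:
        A = np.stack([I_calc, np.ones_like(I_calc)], axis=1)
        AtW = A.T * w
        beta = np.linalg.solve(AtW @ A, AtW @ I_data)
        scale, offset = float(beta[0]), float(beta[1])
    else:
        scale = float((w * I_calc * I_data).sum() / (w * I_calc**2).sum())
        offset = 0.0
    chi2 = float((w * (scale * I_calc + offset - I_data) ** 2).sum())
    return scale, offset, chi2


def fit_profile(
    calc: ScatteringProfile,
    data: ScatteringProfile,
    fit_offset: bool = False,
) -> FitResult:
    """Fit a calculated profile to data by a multiplicative scale (and an
    optional constant offset), minimizing chi^2 in closed form."""
    sigma = data.require_sigma()
    if len(data) < 2:
        raise ValueError("need at least 2 data points")
    I_calc = _interp_onto(calc, data.q)
    scale, offset, chi2 = _scale_fit(I_calc, data.I, sigma, fit_offset)
    dof = max(len(data) - (2 if fit_offset else 1), 1)
    if scale <= 0:
        raise ValueError("fitted scale is non-positive; profiles are incompatible")
    return FitResult(
        scale=scale,
        offset=offset,
        c1=float(calc.metadata.get("c1", np.nan)),
        c2=float(calc.metadata.get("c2", np.nan)),
        chi2=chi2,
        chi2_reduced=chi2 / dof,
        n_points=len(data),
    )


def fit_form_factors(
    conformer: Conformer | "DebyeFactors",
    data: ScatteringProfile,
    params: FormFactorParams | None = None,
    fit_offset: bool = False,
    n_c1: int = 5,
    n_c2: int = 7,
) -> tuple[FitResult, ScatteringProfile]:
    """Best-fit (c1, c2) for one conformer against a target profile.

    Coarse grid over the (c1, c2) box followed by bounded 1-D refinement on
    each axis; the scale is re-fit in closed form at every evaluation.
    Accepts precomputed :class:`DebyeFactors` to amortize the Debye sum.
    Returns the fit and the (unscaled) profile at the best parameters.
    """
    base = params or FormFactorParams()
    sigma = data.require_sigma()
    factors = (
        conformer
        if isinstance(conformer, DebyeFactors)
        else DebyeFactors(conformer, data.q)
    )

    def chi2_at(c1: float, c2: float) -> float:
        I = factors.intensity(replace(base, c1=c1, c2=c2))
        _, _, chi2 = _scale_fit(I, data.I, sigma, fit_offset)
        return chi2

    c1_grid = np.linspace(*C1_BOUNDS, n_c1)
    c2_grid = np.linspace(*C2_BOUNDS, n_c2)
    # the grid contains the neutral point (1.0, 0.0)
    c2_grid = np.union1d(c2_grid, [0.0])
    chi2_tab = np.array([[chi2_at(a, b) for b in c2_grid] for a in c1_grid])
    i, j = np.unravel_index(np.argmin(chi2_tab), chi2_tab.shape)
    c1_best, c2_best = float(c1_grid[i]), float(c2_grid[j])
    # coordinate-wise bounded refinement
    res1 = minimize_scalar(lambda x: chi2_at(x, c2_best), bounds=C1_BOUNDS, method="bounded")
    if res1.fun < chi2_tab[i, j]:
        c1_best = float(res1.x)
    res2 = minimize_scalar(lambda x: chi2_at(c1_best, x), bounds=C2_BOUNDS, method="bounded")
    best_chi2 = chi2_at(c1_best, c2_best)
    if res2.fun < best_chi2:
        c2_best = float(res2.x)
    prof = factors.profile(replace(base, c1=c1_best, c2=c2_best))
    fit = fit_profile(prof, data, fit_offset=fit_offset)
    return fit, prof
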