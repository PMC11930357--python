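"""Guinier analysis, pair-distance distribution P(r) and Dmax estimation.

Two routes to P(r) are provided: directly from coordinates (a weighted
histogram of bead pair distances — exact for bead models and used as the
oracle) and from a scattering profile by regularized indirect Fourier
transform (non-negative least squares on a P(r) bin basis with a
second-difference smoothness penalty, endpoints pinned to zero).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.optimize import nnls
from scipy.spatial.distance import pdist

from .core import Conformer, Ensemble, ScatteringProfile

__all__ = [
    "GuinierResult",
    "PrCurve",
    "guinier_fit",
    "pr_from_coordinates",
    "pr_from_profile",
    "dmax_scan",
]


@dataclass(frozen=True)
class GuinierResult:
    rg: float          # radius of gyration, A
    i0: float          # forward scattering
    q_range: tuple[float, float]
    qmax_rg: float
    r_squared: float   # r^2 of the ln I vs q^2 linear fit
    n_points: int

    def to_dict(self) -> dict:
        return {
            "rg": self.rg,
            "i0": self.i0,
            "q_min": self.q_range[0],
            "q_max": self.q_range[1],
            "qmax_rg": self.qmax_rg,
            "r_squared": self.r_squared,
            "n_points": self.n_points,
        }


@dataclass(frozen=True)
class PrCurve:
    """Pair-distance distribution on an r grid (A)."""

    r: np.ndarray
    p: np.ndarray
    dmax: float
    alpha: float | None = None
    chi2: float | None = None  # forward-model fit chi^2 (profile route only)

    def rg(self) -> float:
        """Rg from the second moment: sqrt( int r^2 P dr / (2 int P dr) )."""
        num = float((self.r**2 * self.p).sum())
        den = float(self.p.sum())
        if den <= 0:
            raise ValueError("P(r) has no mass")
        return float(np.sqrt(num / (2.0 * den)))


def guinier_fit(
    profile: ScatteringProfile,
    qrg_limit: float = 1.3,
    min_points: int = 5,
) -> GuinierResult:
    """Guinier fit ln I = ln I0 - q^2 Rg^2 / 3 on the largest low-q window.

    Iterative trim rule: fit from the first point, shrink the window until
    qmax * Rg <= qrg_limit, refit to convergence.
    """
    q, I = profile.q, profile.I
    end = len(q)
    while True:
        if end < min_points:
            raise ValueError("no convergent Guinier window with enough points")
        qw, Iw = q[:end], I[:end]
        if np.any(Iw <= 0):
            raise ValueError("non-positive intensities in the Guinier window")
        x, y = qw**2, np.log(Iw)
        slope, intercept = np.polyfit(x, y, 1)
        if slope >= 0:
            # shrinking cannot cure a profile rising at low q
            raise ValueError("intensity does not decay at low q; no Guinier regime")
        rg = float(np.sqrt(-3.0 * slope))
        if qw[-1] * rg <= qrg_limit:
            break
        new_end = int(np.searchsorted(q * rg, qrg_limit, side="right"))
        end = new_end if new_end < end else end - 1
    resid = y - (slope * x + intercept)
    ss_tot = float(((y - y.mean()) ** 2).sum())
    r2 = 1.0 - float((resid**2).sum()) / ss_tot if ss_tot > 0 else 1.0
    return GuinierResult(
        rg=rg,
        i0=float(np.exp(intercept)),
        q_range=(float(qw[0]), float(qw[-1])),
        qmax_rg=float(qw[-1] * rg),
        r_squared=r2,
        n_points=end,
    )


def _pair_histogram(conf: Conformer, edges: np.ndarray) -> tuple[np.ndarray, float]:
    d = pdist(conf.coords)
    f = conf.scatter_weight
    n = len(f)
    iu, ju = np.triu_indices(n, k=1)
    wpair = f[iu] * f[ju]
    hist, _ = np.histogram(d, bins=edges, weights=wpair)
    return hist, float(d.max()) if d.size else 0.0


def pr_from_coordinates(
    obj: Conformer | Ensemble,
    r_bin: float = 2.0,
    weights: np.ndarray | None = None,
) -> PrCurve:
    """P(r) as the f_i f_j-weighted histogram of bead pair distances.

    For an ensemble, per-conformer histograms are mixed with the ensemble
    (or supplied) weights; Dmax is the largest pair distance over conformers
    with nonzero weight.
    """
    if r_bin <= 0:
        raise ValueError("r_bin must be > 0")
    if isinstance(obj, Conformer):
        confs, w = [obj], np.array([1.0])
    else:
        confs = list(obj.conformers)
        w = np.asarray(obj.weights if weights is None else weights, dtype=float)
    dmax = 0.0
    for wi, c in zip(w, confs):
        if wi > 0 and c.n_beads > 1:
            dmax = max(dmax, float(pdist(c.coords).max()))
    if dmax == 0.0:
        raise ValueError("no pair distances (single bead?)")
    edges = np.arange(0.0, dmax + r_bin, r_bin)
    if edges[-1] < dmax:
        edges = np.append(edges, dmax + r_bin)
    p = np.zeros(edges.size - 1)
    for wi, c in zip(w, confs):
        if wi > 0:
            h, _ = _pair_histogram(c, edges)
            p += wi * h
    centers = 0.5 * (edges[:-1] + edges[1:])
    return PrCurve(r=centers, p=p, dmax=dmax)


def _design_matrix(q: np.ndarray, r: np.ndarray, dr: float) -> np.ndarray:
    """Forward model I(q) = 4 pi sum_r P(r) sinc(q r) dr."""
    return 4.0 * np.pi * np.sinc(np.outer(q, r) / np.pi) * dr


def _gcv_score(A_w: np.ndarray, y: np.ndarray, D: np.ndarray, alpha: float,
               p_hat: np.ndarray) -> float:
    m = A_w.shape[0]
    G = np.linalg.solve(A_w.T @ A_w + alpha * (D.T @ D), A_w.T)
    df = float(np.trace(A_w @ G))
    resid = A_w @ p_hat - y
    denom = max(m - df, 1e-6)
    return m * float(resid @ resid) / denom**2


def pr_from_profile(
    profile: ScatteringProfile,
    dmax: float,
    alpha: float | None = None,
    n_bins: int = 101,
) -> PrCurve:
    """Regularized indirect Fourier transform of a profile to P(r).

    Non-negative least squares on ``n_bins`` nodes over [0, Dmax] with a
    second-difference smoothness penalty ``alpha`` and P(0) = P(Dmax) = 0.
    ``alpha=None`` selects the penalty by a 10-point logarithmic GCV scan.
    """
    if dmax <= 0:
        raise ValueError("Dmax must be > 0")
    if alpha is not None and alpha < 0:
        raise ValueError("alpha must be >= 0")
    q, I = profile.q, profile.I
    sigma = profile.sigma if profile.sigma is not None else np.ones_like(I)
    r = np.linspace(0.0, dmax, n_bins)
    dr = r[1] - r[0]
    A = _design_matrix(q, r, dr)
    # pinned endpoints: solve for interior nodes only
    A_int = A[:, 1:-1]
    A_w = A_int / sigma[:, None]
    y = I / sigma
    # second differences over the full grid, boundary zeros implicit
    n_int = n_bins - 2
    D = np.zeros((n_bins - 2, n_int))
    for k in range(n_bins - 2):  # row for node k+1 of the full grid
        for dx, c in ((-1, 1.0), (0, -2.0), (1, 1.0)):
            col = k + dx
            if 0 <= col < n_int:
                D[k, col] = c

    def solve(a: float) -> np.ndarray:
        top = np.vstack([A_w, np.sqrt(a) * D])
        rhs = np.concatenate([y, np.zeros(D.shape[0])])
        p, _ = nnls(top, rhs)
        return p

    if alpha == 0:
        if np.linalg.cond(A_w) > 1e10 or A_w.shape[0] < n_int:
            raise ValueError(
                "inversion is ill-conditioned at alpha=0; use alpha > 0 or alpha=None"
            )
        p_int = solve(0.0)
        alpha_used = 0.0
    else:
        if alpha is None:
            scale = np.linalg.norm(A_w, ord=2) ** 2
            candidates = scale * np.logspace(-9, -1, 10)
            scores = []
            sols = []
            for a in candidates:
                p_hat = solve(a)
                sols.append(p_hat)
                scores.append(_gcv_score(A_w, y, D, a, p_hat))
            k = int(np.argmin(scores))
            alpha_used, p_int = float(candidates[k]), sols[k]
        else:
            alpha_used, p_int = float(alpha), solve(alpha)
    p = np.zeros(n_bins)
    p[1:-1] = p_int
    resid = A_w @ p_int - y
    return PrCurve(r=r, p=p, dmax=float(dmax), alpha=alpha_used,
                   chi2=float(resid @ resid))


def dmax_scan(
    profile: ScatteringProfile,
    candidates: np.ndarray,
    alpha: float | None = None,
    tail_fraction: float = 0.05,
    rel_tol: float = 0.05,
    n_bins: int = 101,
) -> tuple[float, pd.DataFrame]:
    """Estimate Dmax by scanning candidate values.

    Each candidate is scored by the inversion chi^2 plus a penalty on P(r)
    mass in the last 5% of bins (mass crowded against the boundary signals an
    underestimated Dmax). chi^2 plateaus once the candidate exceeds the true
    Dmax, so the estimate is the smallest candidate whose score is within
    ``rel_tol`` of the minimum.
    """
    candidates = np.asarray(candidates, dtype=float)
    if candidates.size == 0 or np.any(candidates <= 0):
        raise ValueError("candidates must be positive")
    rows = []
    m = len(profile)
    for dm in candidates:
        curve = pr_from_profile(profile, dm, alpha=alpha, n_bins=n_bins)
        total = curve.p.sum()
        tail = curve.p[curve.r > (1.0 - tail_fraction) * dm].sum()
        tail_frac = float(tail / total) if total > 0 else 1.0
        score = float(curve.chi2) + m * tail_frac
        rows.append({"dmax": float(dm), "chi2": float(curve.chi2),
                     "tail_mass": tail_frac, "score": score})
    table = pd.DataFrame(rows)
    best = table["score"].min()
    ok = table[table["score"] <= best * (1.0 + rel_tol) + 1e-12]
    estimate = float(ok["dmax"].min())
    return estimate, table
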