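"""EOM-style genetic-algorithm selection of SAXS sub-ensembles.

A chromosome is a multiset of K pool indices (repetition allowed, matching
EOM practice); its fitness is the chi^2 of the scale-fitted uniform average
of the K member profiles against the target. Tournament selection,
single-point crossover, per-gene mutation to a random pool index and elitism
evolve the population; a fixed seed gives an identical run.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .core import Ensemble, ScatteringProfile
from .debye import _scale_fit
from .profiles import pr_from_coordinates
from .core import radius_of_gyration

__all__ = ["GAConfig", "GAResult", "DistributionPair", "ga_select",
           "distribution_report", "ensemble_metric"]


@dataclass(frozen=True)
class GAConfig:
    k: int = 20                 # sub-ensemble size
    population: int = 100
    generations: int = 200
    mutation_rate: float = 0.02
    crossover_rate: float = 0.8
    elitism: int = 2
    tournament: int = 3
    seed: int = 0

    def __post_init__(self) -> None:
        if self.k < 1:
            raise ValueError("K must be >= 1")
        for name in ("mutation_rate", "crossover_rate"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name} must lie in [0, 1]")
        if self.elitism < 0 or self.elitism > self.population:
            raise ValueError("elitism must lie in [0, population]")


@dataclass
class GAResult:
    indices: np.ndarray      # selected pool indices (multiset), sorted
    chi2: float
    trace: np.ndarray        # best fitness per generation
    scale: float

    def to_dict(self) -> dict:
        return {
            "indices": self.indices.tolist(),
            "chi2": self.chi2,
            "scale": self.scale,
            "generations": int(self.trace.size),
        }


def _fitness(pop: np.ndarray, X: np.ndarray, I_data: np.ndarray,
             sigma: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """chi^2 (scale-fitted) of each chromosome's uniform average profile."""
    chi2 = np.empty(pop.shape[0])
    scales = np.empty(pop.shape[0])
    for r, chromo in enumerate(pop):
        I_avg = X[chromo].mean(axis=0)
        s, _, c2 = _scale_fit(I_avg, I_data, sigma, fit_offset=False)
        chi2[r] = c2
        scales[r] = s
    return chi2, scales


def ga_select(
    pool_profiles: np.ndarray,
    target: ScatteringProfile,
    config: GAConfig | None = None,
) -> GAResult:
    """Select a K-member sub-ensemble whose averaged profile fits the target."""
    config = config or GAConfig()
    X = np.atleast_2d(np.asarray(pool_profiles, dtype=float))
    n_pool = X.shape[0]
    if n_pool == 0:
        raise ValueError("empty pool")
    if n_pool < config.k:
        raise ValueError("pool smaller than sub-ensemble size K")
    if X.shape[1] != len(target):
        raise ValueError("pool profiles and target q-grid lengths differ")
    sigma = target.require_sigma()
    rng = np.random.default_rng([int(config.seed) & 0x7FFFFFFF, 65537])

    pop = rng.integers(0, n_pool, size=(config.population, config.k))
    chi2, scales = _fitness(pop, X, target.I, sigma)
    trace = np.empty(config.generations + 1)
    best = int(np.argmin(chi2))
    trace[0] = chi2[best]
    best_chromo, best_chi2, best_scale = pop[best].copy(), chi2[best], scales[best]

    for g in range(1, config.generations + 1):
        order = np.argsort(chi2, kind="stable")
        new_pop = [pop[i].copy() for i in order[: config.elitism]]
        while len(new_pop) < config.population:
            # tournament selection of two parents
            parents = []
            for _ in range(2):
                contenders = rng.integers(0, config.population, size=config.tournament)
                parents.append(pop[contenders[np.argmin(chi2[contenders])]])
            a, b = parents[0].copy(), parents[1].copy()
            if config.k > 1 and rng.uniform() < config.crossover_rate:
                cut = int(rng.integers(1, config.k))
                a = np.concatenate([parents[0][:cut], parents[1][cut:]])
                b = np.concatenate([parents[1][:cut], parents[0][cut:]])
            for child in (a, b):
                mut = rng.uniform(size=config.k) < config.mutation_rate
                if mut.any():
                    child[mut] = rng.integers(0, n_pool, size=int(mut.sum()))
                if len(new_pop) < config.population:
                    new_pop.append(child)
        pop = np.stack(new_pop)
        chi2, scales = _fitness(pop, X, target.I, sigma)
        gen_best = int(np.argmin(chi2))
        if chi2[gen_best] < best_chi2:
            best_chromo, best_chi2 = pop[gen_best].copy(), float(chi2[gen_best])
            best_scale = float(scales[gen_best])
        trace[g] = best_chi2

    return GAResult(
        indices=np.sort(best_chromo),
        chi2=float(best_chi2),
        trace=trace,
        scale=float(best_scale),
    )


# ---------------------------------------------------------------------------
# before/after size-metric distributions


@dataclass(frozen=True)
class DistributionPair:
    """Normalized pool ('before') vs selected ('after') histograms."""

    edges: np.ndarray
    pool: np.ndarray
    selected: np.ndarray
    metric: str

    def table(self) -> pd.DataFrame:
        centers = 0.5 * (self.edges[:-1] + self.edges[1:])
        return pd.DataFrame(
            {self.metric: centers, "pool": self.pool, "selected": self.selected}
        )


def ensemble_metric(ensemble: Ensemble, metric: str = "rg") -> np.ndarray:
    """Per-conformer size metric: 'rg' or 'dmax' (max bead pair distance)."""
    if metric == "rg":
        return np.array([radius_of_gyration(c) for c in ensemble])
    if metric == "dmax":
        from scipy.spatial.distance import pdist

        return np.array([float(pdist(c.coords).max()) for c in ensemble])
    raise ValueError("metric must be 'rg' or 'dmax'")


def distribution_report(
    pool_values: np.ndarray,
    selected_indices: np.ndarray,
    metric: str = "dmax",
    n_bins: int = 30,
) -> DistributionPair:
    """Histogram the pool (uniform) against the selected multiset on a shared grid."""
    vals = np.asarray(pool_values, dtype=float)
    sel = vals[np.asarray(selected_indices, dtype=int)]
    lo, hi = float(vals.min()), float(vals.max())
    if hi <= lo:
        hi = lo + 1.0
    edges = np.linspace(lo, hi, n_bins + 1)
    pool_h, _ = np.histogram(vals, bins=edges, density=True)
    sel_h, _ = np.histogram(sel, bins=edges, density=True)
    return DistributionPair(edges=edges, pool=pool_h, selected=sel_h, metric=metric)
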