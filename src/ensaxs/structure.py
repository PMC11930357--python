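"""Weighted residue-contact maps and weight-modified GROMOS clustering.

Contact rule: two residues interact in a conformer when their CG beads are
within 11 A. The ensemble contact probability is the weight-averaged
indicator. Clustering follows the GROMOS leader algorithm modified so that
the *sum of weights* of neighbours (RMSD within a cutoff), rather than their
count, selects each cluster center; with uniform weights this reduces
exactly to classic GROMOS.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.spatial.distance import cdist

from .core import Conformer, Ensemble, Selection, subset_rmsd

__all__ = [
    "ContactMap",
    "ClusterAssignment",
    "contact_probability",
    "pairwise_rmsd_matrix",
    "gromos_cluster_weighted",
    "representative_structures",
]


@dataclass(frozen=True)
class ContactMap:
    """Residue-pair interaction probabilities P[a, b] in [0, 1]."""

    matrix: np.ndarray
    residues: np.ndarray  # residue ids along both axes
    mode: str  # "intra" | "inter"
    cutoff: float

    def value(self, res_a: int, res_b: int) -> float:
        ia = int(np.flatnonzero(self.residues == res_a)[0])
        ib = int(np.flatnonzero(self.residues == res_b)[0])
        return float(self.matrix[ia, ib])

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.matrix, index=self.residues, columns=self.residues)

    def plot(self, ax=None, **imshow_kw):
        import matplotlib.pyplot as plt

        if ax is None:
            _, ax = plt.subplots()
        ext = [self.residues[0], self.residues[-1], self.residues[-1], self.residues[0]]
        im = ax.imshow(self.matrix, vmin=0, vmax=1, extent=ext, **imshow_kw)
        ax.set_xlabel("residue")
        ax.set_ylabel("residue")
        ax.set_title(f"{self.mode}-chain contact probability (cutoff {self.cutoff} A)")
        plt.colorbar(im, ax=ax)
        return ax


def _chain_blocks(conf: Conformer) -> dict[str, np.ndarray]:
    return {c: np.flatnonzero(conf.chain_ids == c) for c in conf.chains}


def contact_probability(
    ensemble: Ensemble,
    weights: np.ndarray | None = None,
    cutoff: float = 11.0,
    mode: str = "intra",
) -> ContactMap:
    """Weighted residue-pair interaction probability map.

    ``mode="intra"`` restricts to same-chain pairs (averaged over chains for
    multi-chain systems); ``mode="inter"`` to cross-chain pairs of a 2-chain
    system, with the two subunit pairings averaged and the map symmetrized.
    """
    if mode not in ("intra", "inter"):
        raise ValueError("mode must be 'intra' or 'inter'")
    topo = ensemble.topology
    blocks = _chain_blocks(topo)
    chains = list(blocks)
    if mode == "inter" and len(chains) < 2:
        raise ValueError("inter-chain map requires at least 2 chains")
    if len(chains) > 2:
        raise ValueError("contact maps support 1- or 2-chain topologies")
    # all chains must share the residue numbering
    res = topo.residue_ids[blocks[chains[0]]]
    for c in chains[1:]:
        if not np.array_equal(topo.residue_ids[blocks[c]], res):
            raise ValueError("chains do not share residue numbering")
    w = np.asarray(ensemble.weights if weights is None else weights, dtype=float)
    if np.any(w < 0) or abs(w.sum() - 1.0) > 1e-8:
        raise ValueError("weights must lie on the simplex")

    n = res.size
    P = np.zeros((n, n))
    for wj, conf in zip(w, ensemble):
        if wj == 0:
            continue
        if mode == "intra":
            ind = np.zeros((n, n))
            for c in chains:
                xyz = conf.coords[blocks[c]]
                ind += cdist(xyz, xyz) <= cutoff
            P += wj * ind / len(chains)
        else:
            a = conf.coords[blocks[chains[0]]]
            b = conf.coords[blocks[chains[1]]]
            d = cdist(a, b) <= cutoff
            P += wj * 0.5 * (d + d.T)
    # accumulated float error can nudge certain pairs past 1 by ~1e-16
    P = np.clip(P, 0.0, 1.0)
    return ContactMap(matrix=P, residues=res, mode=mode, cutoff=cutoff)


@dataclass(frozen=True)
class ClusterAssignment:
    """Cluster labels per conformer, ordered by descending cluster weight."""

    labels: np.ndarray  # cluster index per conformer (0 = heaviest)
    centers: np.ndarray  # conformer index of each cluster center
    cluster_weights: np.ndarray
    cutoff: float

    @property
    def n_clusters(self) -> int:
        return self.centers.size

    def members(self, k: int) -> np.ndarray:
        return np.flatnonzero(self.labels == k)

    def table(self) -> pd.DataFrame:
        sizes = np.bincount(self.labels, minlength=self.n_clusters)
        return pd.DataFrame(
            {
                "cluster": np.arange(self.n_clusters),
                "center": self.centers,
                "weight": self.cluster_weights,
                "size": sizes,
            }
        )


def pairwise_rmsd_matrix(
    ensemble: Ensemble,
    superpose_sel: Selection | None = None,
    rmsd_sel: Selection | None = None,
    chain_swap: bool = False,
) -> np.ndarray:
    """Symmetric matrix of subset RMSDs between all conformer pairs."""
    n = len(ensemble)
    D = np.zeros((n, n))
    for i in range(n):
        for j in range(i + 1, n):
            D[i, j] = D[j, i] = subset_rmsd(
                ensemble[i], ensemble[j], superpose_sel, rmsd_sel,
                chain_swap=chain_swap,
            )
    return D


def gromos_cluster_weighted(
    ensemble: Ensemble,
    weights: np.ndarray | None = None,
    superpose_sel: Selection | None = None,
    rmsd_sel: Selection | None = None,
    cutoff: float = 20.0,
    chain_swap: bool = False,
    rmsd_matrix: np.ndarray | None = None,
) -> ClusterAssignment:
    """Weight-modified GROMOS clustering.

    Iteratively, each unassigned conformer is scored by the summed weight of
    its unassigned neighbours (RMSD <= cutoff, itself included); the highest
    score (ties to the lowest index) becomes a cluster center, its neighbours
    form the cluster and are removed. Clusters are relabelled by descending
    total weight.
    """
    if cutoff <= 0:
        raise ValueError("cutoff must be > 0")
    n = len(ensemble)
    w = np.asarray(ensemble.weights if weights is None else weights, dtype=float)
    if w.shape != (n,) or np.any(w < 0) or abs(w.sum() - 1.0) > 1e-8:
        raise ValueError("weights must lie on the simplex")
    D = (
        pairwise_rmsd_matrix(ensemble, superpose_sel, rmsd_sel, chain_swap)
        if rmsd_matrix is None
        else np.asarray(rmsd_matrix, dtype=float)
    )
    neighbor = D <= cutoff
    unassigned = np.ones(n, dtype=bool)
    labels = np.full(n, -1, dtype=int)
    centers: list[int] = []
    cluster_w: list[float] = []
    k = 0
    while unassigned.any():
        scores = (neighbor & unassigned[None, :]) @ w
        scores[~unassigned] = -np.inf
        center = int(np.argmax(scores))  # argmax takes the lowest index on ties
        members = np.flatnonzero(neighbor[center] & unassigned)
        labels[members] = k
        centers.append(center)
        cluster_w.append(float(w[members].sum()))
        unassigned[members] = False
        k += 1
    order = np.argsort(
        [-cw + 1e-15 * c for cw, c in zip(cluster_w, centers)], kind="stable"
    )
    relabel = np.empty(k, dtype=int)
    relabel[order] = np.arange(k)
    return ClusterAssignment(
        labels=relabel[labels],
        centers=np.asarray(centers)[order],
        cluster_weights=np.asarray(cluster_w)[order],
        cutoff=float(cutoff),
    )


def representative_structures(
    assignment: ClusterAssignment,
    ensemble: Ensemble,
    top_k: int = 6,
) -> list[tuple[Conformer, float, int]]:
    """Center conformer, cluster weight and size for the top_k heaviest clusters."""
    n_cl = assignment.n_clusters
    if top_k > n_cl:
        warnings.warn(
            f"requested top_{top_k} clusters but only {n_cl} exist; returning all",
            stacklevel=2,
        )
        top_k = n_cl
    out = []
    sizes = np.bincount(assignment.labels, minlength=n_cl)
    for k in range(top_k):
        center = int(assignment.centers[k])
        out.append(
            (ensemble[center], float(assignment.cluster_weights[k]), int(sizes[k]))
        )
    return out
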