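"""Core domain types and geometric primitives for CG bead ensembles.

The package represents a protein as one bead per residue (a C-alpha trace).
A :class:`Conformer` holds bead coordinates plus per-bead scattering weight
and net charge; an :class:`Ensemble` is an ordered list of topologically
identical conformers carrying a statistical weight vector on the simplex.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Iterable, Mapping, Sequence

import numpy as np

__all__ = [
    "Conformer",
    "Ensemble",
    "ScatteringProfile",
    "Selection",
    "SegmentAnnotation",
    "radius_of_gyration",
    "superpose",
    "subset_rmsd",
    "kabsch_rotation",
]

_SIMPLEX_TOL = 1e-9


@dataclass(frozen=True)
class Conformer:
    """A single CG conformer: one bead per residue.

    Parameters
    ----------
    coords : (n, 3) float array
        Bead positions in Angstrom.
    residue_ids : (n,) int array
        Residue numbers, strictly increasing within each chain (1-based).
    chain_ids : (n,) array of str
        Subunit label per bead.
    scatter_weight : (n,) float array, optional
        Forward scattering factor f_i(0) per bead; defaults to 1.
    charge : (n,) float array, optional
        Net charge per bead (e); defaults to 0.
    """

    coords: np.ndarray
    residue_ids: np.ndarray
    chain_ids: np.ndarray
    scatter_weight: np.ndarray = None  # type: ignore[assignment]
    charge: np.ndarray = None  # type: ignore[assignment]

    def __post_init__(self) -> None:
        coords = np.asarray(self.coords, dtype=float)
        if coords.ndim != 2 or coords.shape[1] != 3:
            raise ValueError("coords must be (n, 3)")
        n = coords.shape[0]
        if n == 0:
            raise ValueError("conformer must contain at least one bead")
        if not np.all(np.isfinite(coords)):
            raise ValueError("coordinates must be finite")
        rid = np.asarray(self.residue_ids, dtype=int)
        cid = np.asarray(self.chain_ids, dtype="U4")
        if rid.shape != (n,) or cid.shape != (n,):
            raise ValueError("residue_ids/chain_ids must match number of beads")
        sw = self.scatter_weight
        sw = np.ones(n) if sw is None else np.asarray(sw, dtype=float)
        ch = self.charge
        ch = np.zeros(n) if ch is None else np.asarray(ch, dtype=float)
        if sw.shape != (n,) or ch.shape != (n,):
            raise ValueError("per-bead arrays must match number of beads")
        if np.any(sw < 0):
            raise ValueError("scatter_weight must be >= 0")
        for c in np.unique(cid):
            r = rid[cid == c]
            if r.size == 0:
                raise ValueError(f"chain {c!r} is empty")
            if np.any(np.diff(r) <= 0):
                raise ValueError(f"residue_ids not strictly increasing in chain {c!r}")
        object.__setattr__(self, "coords", coords)
        object.__setattr__(self, "residue_ids", rid)
        object.__setattr__(self, "chain_ids", cid)
        object.__setattr__(self, "scatter_weight", sw)
        object.__setattr__(self, "charge", ch)

    @property
    def n_beads(self) -> int:
        return self.coords.shape[0]

    @property
    def chains(self) -> list[str]:
        """Chain labels in order of first appearance."""
        seen: dict[str, None] = {}
        for c in self.chain_ids:
            seen.setdefault(str(c), None)
        return list(seen)

    def same_topology(self, other: "Conformer") -> bool:
        return (
            self.n_beads == other.n_beads
            and np.array_equal(self.residue_ids, other.residue_ids)
            and np.array_equal(self.chain_ids, other.chain_ids)
        )

    def transformed(self, rotation: np.ndarray, translation: np.ndarray) -> "Conformer":
        """Return a copy with ``coords @ R.T + t`` applied."""
        return replace(self, coords=self.coords @ np.asarray(rotation).T + translation)

    def with_chain_swap(self, mapping: Mapping[str, str]) -> "Conformer":
        """Relabel chains and reorder beads so topology order is preserved.

        Used to evaluate the alternative subunit assignment of a symmetric
        dimer / two-molecule system.
        """
        new_cid = np.array([mapping.get(str(c), str(c)) for c in self.chain_ids], dtype="U4")
        # stable sort by (order of first appearance of original chain list, residue)
        order_of = {c: i for i, c in enumerate(self.chains)}
        keys = np.array([order_of[str(c)] for c in new_cid])
        idx = np.lexsort((self.residue_ids, keys))
        return Conformer(
            coords=self.coords[idx],
            residue_ids=self.residue_ids[idx],
            chain_ids=new_cid[idx],
            scatter_weight=self.scatter_weight[idx],
            charge=self.charge[idx],
        )


@dataclass
class Ensemble:
    """An ordered collection of topologically identical conformers.

    ``weights`` and ``initial_weights`` live on the probability simplex.
    """

    conformers: list[Conformer]
    weights: np.ndarray = None  # type: ignore[assignment]
    initial_weights: np.ndarray = None  # type: ignore[assignment]
    source: str = ""
    metadata: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if len(self.conformers) == 0:
            raise ValueError("ensemble must contain at least one conformer")
        ref = self.conformers[0]
        for k, c in enumerate(self.conformers[1:], start=1):
            if not ref.same_topology(c):
                raise ValueError(f"conformer {k} does not share the ensemble topology")
        n = len(self.conformers)
        if self.weights is None:
            self.weights = np.full(n, 1.0 / n)
        if self.initial_weights is None:
            self.initial_weights = np.array(self.weights, copy=True)
        self.weights = _check_simplex(np.asarray(self.weights, dtype=float), n, "weights")
        self.initial_weights = _check_simplex(
            np.asarray(self.initial_weights, dtype=float), n, "initial_weights"
        )

    def __len__(self) -> int:
        return len(self.conformers)

    def __iter__(self):
        return iter(self.conformers)

    def __getitem__(self, i: int) -> Conformer:
        return self.conformers[i]

    @property
    def topology(self) -> Conformer:
        return self.conformers[0]

    def coords_array(self) -> np.ndarray:
        """Stack coordinates as (n_conformers, n_beads, 3)."""
        return np.stack([c.coords for c in self.conformers])

    def with_weights(self, w: np.ndarray) -> "Ensemble":
        return Ensemble(
            conformers=self.conformers,
            weights=np.asarray(w, dtype=float),
            initial_weights=self.initial_weights,
            source=self.source,
            metadata=dict(self.metadata),
        )


def _check_simplex(w: np.ndarray, n: int, name: str) -> np.ndarray:
    if w.shape != (n,):
        raise ValueError(f"{name} must have length {n}")
    if np.any(w < -_SIMPLEX_TOL) or abs(w.sum() - 1.0) > 1e-8:
        raise ValueError(f"{name} must lie on the probability simplex")
    return np.clip(w, 0.0, None)


@dataclass(frozen=True)
class ScatteringProfile:
    """A 1-D SAXS profile: q (A^-1, strictly increasing, >= 0), I and sigma."""

    q: np.ndarray
    I: np.ndarray
    sigma: np.ndarray | None = None
    metadata: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        q = np.asarray(self.q, dtype=float)
        I = np.asarray(self.I, dtype=float)
        if q.ndim != 1 or q.shape != I.shape:
            raise ValueError("q and I must be 1-D arrays of equal length")
        if np.any(q < 0) or np.any(np.diff(q) <= 0):
            raise ValueError("q must be non-negative and strictly increasing")
        sig = self.sigma
        if sig is not None:
            sig = np.asarray(sig, dtype=float)
            if sig.shape != q.shape:
                raise ValueError("sigma must match q")
        object.__setattr__(self, "q", q)
        object.__setattr__(self, "I", I)
        object.__setattr__(self, "sigma", sig)

    def __len__(self) -> int:
        return self.q.size

    def require_sigma(self) -> np.ndarray:
        if self.sigma is None:
            raise ValueError(
                "profile has no error column; provide sigma before fitting"
            )
        if np.any(self.sigma <= 0):
            raise ValueError("sigma must be > 0 on all fitted points")
        return self.sigma


@dataclass(frozen=True)
class Selection:
    """Residue ranges per chain with a role tag.

    ``ranges`` is a sequence of (chain_id, start, end) with 1-based inclusive
    residue bounds, e.g. the clustering set 11-14, 19-74, 89-91, 102-107,
    113-173 on each subunit. ``chain_id`` of "*" matches every chain.
    """

    ranges: tuple[tuple[str, int, int], ...]
    role: str = "rmsd"

    def __post_init__(self) -> None:
        norm = tuple((str(c), int(a), int(b)) for c, a, b in self.ranges)
        for c, a, b in norm:
            if a > b:
                raise ValueError(f"invalid range {a}-{b} on chain {c!r}")
        object.__setattr__(self, "ranges", norm)

    @classmethod
    def from_ranges(cls, ranges: Iterable[tuple[int, int]], chains: str | Sequence[str] = "*",
                    role: str = "rmsd") -> "Selection":
        """Build a selection applying the same residue ranges to the given chains."""
        if isinstance(chains, str):
            chains = [chains]
        rr = [(c, a, b) for c in chains for a, b in ranges]
        return cls(tuple(rr), role=role)

    def mask(self, conformer: Conformer) -> np.ndarray:
        m = np.zeros(conformer.n_beads, dtype=bool)
        for c, a, b in self.ranges:
            in_chain = (
                np.ones(conformer.n_beads, dtype=bool)
                if c == "*"
                else conformer.chain_ids == c
            )
            m |= in_chain & (conformer.residue_ids >= a) & (conformer.residue_ids <= b)
        if not m.any():
            raise ValueError("selection matches no beads in this topology")
        return m


@dataclass(frozen=True)
class SegmentAnnotation:
    """Named sequence segments (N-tail, CD, HR, CSD, a1..a7, b1..b7)."""

    segments: Mapping[str, tuple[int, int]]
    n_res: int | None = None

    def __post_init__(self) -> None:
        segs = {str(k): (int(a), int(b)) for k, (a, b) in dict(self.segments).items()}
        for name, (a, b) in segs.items():
            if a > b or a < 1:
                raise ValueError(f"segment {name!r} has invalid bounds {a}-{b}")
            if self.n_res is not None and b > self.n_res:
                raise ValueError(f"segment {name!r} exceeds sequence length {self.n_res}")
        object.__setattr__(self, "segments", segs)

    def __getitem__(self, name: str) -> tuple[int, int]:
        return self.segments[name]

    def residues(self, name: str) -> np.ndarray:
        a, b = self.segments[name]
        return np.arange(a, b + 1)

    def names(self) -> list[str]:
        return list(self.segments)


# ---------------------------------------------------------------------------
# geometric primitives


def radius_of_gyration(conformer: Conformer, mass_weights: np.ndarray | None = None) -> float:
    """Mass-weighted radius of gyration in Angstrom.

    Rg = sqrt( sum_i m_i |r_i - rbar|^2 / sum_i m_i ) with rbar the weighted
    centroid. Default weights are uniform.
    """
    r = conformer.coords
    if mass_weights is None:
        m = np.ones(r.shape[0])
    else:
        m = np.asarray(mass_weights, dtype=float)
        if m.shape != (r.shape[0],):
            raise ValueError("mass_weights must have one entry per bead")
        if np.any(m < 0):
            raise ValueError("mass_weights must be >= 0")
        if m.sum() == 0:
            raise ValueError("mass_weights must not all be zero")
    centroid = (m[:, None] * r).sum(axis=0) / m.sum()
    d2 = ((r - centroid) ** 2).sum(axis=1)
    return float(np.sqrt((m * d2).sum() / m.sum()))


def kabsch_rotation(mobile: np.ndarray, reference: np.ndarray) -> np.ndarray:
    """Optimal proper rotation (det=+1) aligning centered ``mobile`` onto
    centered ``reference`` in the least-squares sense (Kabsch, SVD branch
    with sign correction)."""
    H = mobile.T @ reference
    U, s, Vt = np.linalg.svd(H)
    d = np.sign(np.linalg.det(Vt.T @ U.T))
    D = np.diag([1.0, 1.0, d])
    return Vt.T @ D @ U.T


def superpose(
    mobile: Conformer,
    reference: Conformer,
    selection: Selection | None = None,
) -> tuple[np.ndarray, np.ndarray, Conformer]:
    """Least-squares rigid superposition of ``mobile`` onto ``reference``.

    Returns ``(rotation, translation, transformed_mobile)`` such that
    ``mobile.coords @ rotation.T + translation`` minimizes the RMSD over the
    selected beads. Reflections are never returned.
    """
    if selection is None:
        m_mask = np.ones(mobile.n_beads, dtype=bool)
        r_mask = np.ones(reference.n_beads, dtype=bool)
    else:
        m_mask = selection.mask(mobile)
        r_mask = selection.mask(reference)
    a = mobile.coords[m_mask]
    b = reference.coords[r_mask]
    if a.shape != b.shape:
        raise ValueError("selection selects different bead counts in the two conformers")
    if a.shape[0] < 3:
        raise ValueError("superposition requires at least 3 selected beads")
    ac, bc = a.mean(axis=0), b.mean(axis=0)
    a0, b0 = a - ac, b - bc
    # collinear/degenerate geometry: second singular value vanishes
    s = np.linalg.svd(a0, compute_uv=False)
    if s[1] < 1e-8 * max(s[0], 1.0):
        raise ValueError("selected beads are (near-)collinear; superposition is degenerate")
    R = kabsch_rotation(a0, b0)
    t = bc - ac @ R.T
    return R, t, mobile.transformed(R, t)


def _rmsd(a: np.ndarray, b: np.ndarray) -> float:
    return float(np.sqrt(((a - b) ** 2).sum(axis=1).mean()))


def subset_rmsd(
    a: Conformer,
    b: Conformer,
    superpose_sel: Selection | None = None,
    rmsd_sel: Selection | None = None,
    chain_swap: bool = False,
) -> float:
    """C-alpha RMSD over ``rmsd_sel`` after superposing on ``superpose_sel``.

    With ``chain_swap`` both subunit label assignments of a 2-chain system are
    evaluated and the minimum returned (subunit labelling of a symmetric dimer
    or a two-molecule system is arbitrary).
    """
    if not a.same_topology(b):
        raise ValueError("conformers do not share a topology")

    def one(bb: Conformer) -> float:
        _, _, moved = superpose(a, bb, superpose_sel)
        mask = (
            np.ones(a.n_beads, dtype=bool) if rmsd_sel is None else rmsd_sel.mask(a)
        )
        return _rmsd(moved.coords[mask], bb.coords[mask])

    val = one(b)
    if chain_swap:
        chains = b.chains
        if len(chains) > 2:
            raise ValueError("chain_swap supports at most 2 chains")
        if len(chains) == 2:
            swapped = b.with_chain_swap({chains[0]: chains[1], chains[1]: chains[0]})
            val = min(val, one(swapped))
    return val
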