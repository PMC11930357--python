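"""Synthetic CG conformer ensembles with known ground truth.

This module stands in for coarse-grained MD trajectories of an HP1a-like
protein: rigid folded domains (a CD-like globule per chain and, for the
full-length dimer, a shared CSD-dimer core) joined by flexible tails and
linkers, with phosphoserine sites in the N-tail and basic/acidic charge
segments along the sequence. A compactness bias ``kappa`` rewards contacts
between phosphoserine beads and basic-segment beads, emulating the
phosphorylation-driven compaction of the real protein; ``kappa = 0`` samples
an unbiased excluded-volume chain.

Geometry is a standard C-alpha trace: virtual bond 3.8 A, hard-sphere
excluded volume 4.0 A. All generators are pure functions of (spec, seed).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
from scipy.spatial.transform import Rotation

from .core import Conformer, Ensemble, ScatteringProfile, SegmentAnnotation

__all__ = [
    "TopologySpec",
    "MixtureSpec",
    "Subpopulation",
    "hp1a_dimer_topology",
    "delta_csd_topology",
    "make_rigid_domain",
    "sample_conformer",
    "make_mixture_ensemble",
    "make_target_profile",
    "default_q_grid",
]

BOND_LENGTH = 3.8
MIN_SEPARATION = 4.0
CONTACT_CUTOFF = 8.0  # phospho-basic bias contact distance, A

# Charge layout emulating the acidic (a1..a7) / basic (b1..b7) segment
# alternation of HP1a. The b3/b4/b6/b7 anchors follow the protein
# (K42 region, K68-K72, 89-92, K102-K105); the remaining ranges are a
# synthetic emulation of the published segment numbering, not a sequence map.
BASIC_SEGMENTS_120 = ((33, 35), (40, 44), (68, 72), (82, 84), (89, 92), (102, 105))
ACIDIC_SEGMENTS_120 = ((15, 18), (46, 48), (55, 58), (75, 78), (95, 97), (108, 111))
BASIC_SEGMENTS_191 = BASIC_SEGMENTS_120
ACIDIC_SEGMENTS_191 = ACIDIC_SEGMENTS_120 + ((160, 166), (176, 180), (186, 189))


@dataclass(frozen=True)
class TopologySpec:
    """Chain layout of the synthetic protein.

    Residue ranges are 1-based inclusive and identical across chains.
    ``shared_domain`` marks a rigid core spanning both chains of a dimer
    (the CSD-dimer emulation); without it, ``n_chains > 1`` means separate
    molecules initially placed >60 A apart.
    """

    n_res: int
    n_chains: int = 1
    rigid_domains: tuple[tuple[int, int], ...] = ((19, 74),)
    shared_domain: tuple[int, int] | None = None
    phospho_sites: tuple[int, ...] = ()
    basic_segments: tuple[tuple[int, int], ...] = BASIC_SEGMENTS_120
    acidic_segments: tuple[tuple[int, int], ...] = ACIDIC_SEGMENTS_120
    domain_seed: int = 1117

    def __post_init__(self) -> None:
        if self.n_res < 3:
            raise ValueError("need at least 3 residues")
        if self.n_chains < 1:
            raise ValueError("n_chains must be >= 1")
        if self.shared_domain is not None and self.n_chains != 2:
            raise ValueError("shared_domain requires exactly 2 chains")
        spans = list(self.rigid_domains) + (
            [self.shared_domain] if self.shared_domain else []
        )
        spans.sort()
        prev_end = 0
        for a, b in spans:
            if a <= prev_end or b > self.n_res or a > b:
                raise ValueError(f"invalid/overlapping rigid range {a}-{b}")
            prev_end = b
        for s in self.phospho_sites:
            if not 1 <= s <= self.n_res:
                raise ValueError(f"phospho site {s} outside chain")

    @property
    def chain_labels(self) -> list[str]:
        return [chr(ord("A") + i) for i in range(self.n_chains)]

    def charges(self) -> np.ndarray:
        """Per-residue charge for one chain: basic +1, acidic -1, phosphoserine -2."""
        q = np.zeros(self.n_res)
        for a, b in self.basic_segments:
            q[a - 1 : b] = 1.0
        for a, b in self.acidic_segments:
            q[a - 1 : b] = -1.0
        for s in self.phospho_sites:
            q[s - 1] = -2.0
        return q

    def segment_annotation(self) -> SegmentAnnotation:
        segs: dict[str, tuple[int, int]] = {"N-tail": (1, self.rigid_domains[0][0] - 1)}
        segs["CD"] = self.rigid_domains[0]
        hr_end = self.shared_domain[0] - 1 if self.shared_domain else self.n_res
        segs["HR"] = (self.rigid_domains[0][1] + 1, hr_end)
        if self.shared_domain:
            segs["CSD"] = self.shared_domain
        for i, (a, b) in enumerate(self.basic_segments, start=2):
            segs[f"b{i}"] = (a, b)
        for i, (a, b) in enumerate(self.acidic_segments, start=1):
            segs[f"a{i}"] = (a, b)
        return SegmentAnnotation(segs, n_res=self.n_res)


def hp1a_dimer_topology(phosphorylated: bool = False) -> TopologySpec:
    """Full-length HP1a-like dimer: two 191-residue chains, one CD globule
    per chain and a shared CSD-dimer core."""
    return TopologySpec(
        n_res=191,
        n_chains=2,
        rigid_domains=((19, 74),),
        shared_domain=(113, 173),
        phospho_sites=(11, 12, 13, 14) if phosphorylated else (),
        basic_segments=BASIC_SEGMENTS_191,
        acidic_segments=ACIDIC_SEGMENTS_191,
    )


def delta_csd_topology(phosphorylated: bool = True, n_molecules: int = 1) -> TopologySpec:
    """CSD-deletion monomer (120 residues, CD globule + flexible tails);
    ``n_molecules = 2`` gives the two-molecule system."""
    return TopologySpec(
        n_res=120,
        n_chains=n_molecules,
        rigid_domains=((19, 74),),
        shared_domain=None,
        phospho_sites=(11, 12, 13, 14) if phosphorylated else (),
    )


# ---------------------------------------------------------------------------
# rigid-domain template


def _random_units(rng: np.random.Generator, k: int) -> np.ndarray:
    v = rng.normal(size=(k, 3))
    return v / np.linalg.norm(v, axis=1, keepdims=True)


def make_rigid_domain(
    n_res: int,
    seed: int,
    bond: float = BOND_LENGTH,
    min_sep: float = MIN_SEPARATION,
    max_attempts: int = 200,
) -> np.ndarray:
    """Deterministic compact globule used as a rigid-domain template.

    A self-avoiding walk with exact bond length whose growth greedily seeks
    the current centroid, accepted only if all non-bonded pairs are >= 4.0 A
    apart and the radius of gyration satisfies Rg <= 0.9 * 3.8 * n^0.33.
    """
    if n_res < 3:
        raise ValueError("rigid domain needs >= 3 residues")
    rg_cap = 0.9 * bond * n_res**0.33
    # growth condenses around an attractor offset from the first bead so the
    # chain termini (tail/linker attachment points) stay on the surface
    r_est = (3.0 * n_res * 60.0 / (4.0 * np.pi)) ** (1.0 / 3.0)
    for attempt in range(max_attempts):
        rng = np.random.default_rng([int(seed) & 0x7FFFFFFF, attempt])
        coords = np.empty((n_res, 3))
        coords[0] = 0.0
        attractor = r_est * _random_units(rng, 1)[0]
        coords[1] = bond * _random_units(rng, 1)[0]
        ok = True
        for i in range(2, n_res):
            cands = coords[i - 1] + bond * _random_units(rng, 60)
            d = np.linalg.norm(cands[:, None, :] - coords[None, : i - 1, :], axis=2)
            valid = np.flatnonzero((d >= min_sep).all(axis=1))
            if valid.size == 0:
                ok = False
                break
            pick = valid[np.argmin(np.linalg.norm(cands[valid] - attractor, axis=1))]
            coords[i] = cands[pick]
        if not ok:
            continue
        rg = math.sqrt(((coords - coords.mean(axis=0)) ** 2).sum(axis=1).mean())
        if rg <= rg_cap:
            return coords - coords.mean(axis=0)
    raise RuntimeError(
        f"failed to generate compact domain (n_res={n_res}, seed={seed}) "
        f"after {max_attempts} attempts; Rg cap {rg_cap:.2f} A"
    )


# ---------------------------------------------------------------------------
# conformer growth

_GROW_CANDIDATES = 40


class _GrowthFailure(Exception):
    pass


class _Builder:
    """Incremental chain builder with hard-sphere exclusion."""

    def __init__(self, n_total: int, bond: float, min_sep: float):
        self.coords = np.full((n_total, 3), np.nan)
        self.placed = np.zeros(n_total, dtype=bool)
        self.bond = bond
        self.min_sep = min_sep

    def _clash(self, cand: np.ndarray, exempt: list[int]) -> np.ndarray:
        """Rows of cand clashing with any placed bead (exempt indices skipped)."""
        idx = np.flatnonzero(self.placed)
        idx = idx[~np.isin(idx, exempt)]
        if idx.size == 0:
            return np.zeros(len(cand), dtype=bool)
        d = np.linalg.norm(cand[:, None, :] - self.coords[None, idx, :], axis=2)
        return (d < self.min_sep).any(axis=1)

    def place(self, i: int, pos: np.ndarray) -> None:
        self.coords[i] = pos
        self.placed[i] = True

    def grow_bead(self, rng: np.random.Generator, i: int, prev: int) -> None:
        cands = self.coords[prev] + self.bond * _random_units(rng, _GROW_CANDIDATES)
        bad = self._clash(cands, exempt=[prev])
        good = np.flatnonzero(~bad)
        if good.size == 0:
            raise _GrowthFailure(f"no valid growth step for bead {i}")
        self.place(i, cands[rng.choice(good)])

    def place_rigid(
        self,
        rng: np.random.Generator,
        indices: np.ndarray,
        template: np.ndarray,
        attach_local: int | None,
        anchor: int | None,
        max_tries: int = 120,
    ) -> None:
        """Place a rigid template. ``attach_local`` is the template bead bonded
        to placed bead ``anchor``; both None places the template freely at the
        origin with a random orientation."""
        for _ in range(max_tries):
            rot = Rotation.random(rng=rng).as_matrix()
            body = template @ rot.T
            if anchor is None:
                pos = body
                exempt: list[int] = []
            else:
                u = _random_units(rng, 1)[0]
                attach_pos = self.coords[anchor] + self.bond * u
                pos = body - body[attach_local] + attach_pos
                exempt = [anchor]
            bad = self._clash(pos, exempt=exempt)
            # the bead bonded to the anchor sits at 3.8 A < min_sep by design
            if anchor is not None:
                d_anchor = np.linalg.norm(pos - self.coords[anchor], axis=1)
                mask = np.ones(len(pos), dtype=bool)
                mask[attach_local] = False
                if (d_anchor[mask] < self.min_sep).any():
                    continue
            if not bad.any():
                for k, p in zip(indices, pos):
                    self.place(int(k), p)
                return
        raise _GrowthFailure("could not place rigid domain without clashes")


@dataclass
class _FlexRun:
    """A contiguous run of flexible beads (global indices, chain order)."""

    indices: np.ndarray  # global bead indices in residue order
    head_free: bool  # chain-start side is a free terminus
    tail_free: bool
    head_anchor: int | None  # global index of the rigid bead preceding the run
    tail_anchor: int | None
    molecule: int


class _Layout:
    """Static description of a topology: bead indexing, rigid blocks,
    flexible runs, charge classes."""

    def __init__(self, topo: TopologySpec):
        self.topo = topo
        n, nc = topo.n_res, topo.n_chains
        self.n_beads = n * nc
        self.residue_ids = np.tile(np.arange(1, n + 1), nc)
        self.chain_ids = np.repeat(np.array(topo.chain_labels, dtype="U4"), n)
        self.charges = np.tile(topo.charges(), nc)
        self.scatter = np.ones(self.n_beads)
        linked = topo.shared_domain is not None
        self.molecule = (
            np.zeros(self.n_beads, dtype=int)
            if linked
            else np.repeat(np.arange(nc), n)
        )
        self.n_molecules = 1 if linked else nc
        self.phospho_idx = np.flatnonzero(self.charges <= -2.0)
        self.basic_idx = np.flatnonzero(self.charges >= 1.0)

        rigid = np.zeros(self.n_beads, dtype=bool)
        for c in range(nc):
            off = c * n
            for a, b in topo.rigid_domains:
                rigid[off + a - 1 : off + b] = True
        if topo.shared_domain:
            a, b = topo.shared_domain
            for c in range(nc):
                off = c * n
                rigid[off + a - 1 : off + b] = True
        self.rigid_mask = rigid

        self.runs: list[_FlexRun] = []
        for c in range(nc):
            off = c * n
            i = 0
            while i < n:
                if rigid[off + i]:
                    i += 1
                    continue
                j = i
                while j < n and not rigid[off + j]:
                    j += 1
                head_free = i == 0
                tail_free = j == n
                self.runs.append(
                    _FlexRun(
                        indices=np.arange(off + i, off + j),
                        head_free=head_free,
                        tail_free=tail_free,
                        head_anchor=None if head_free else off + i - 1,
                        tail_anchor=None if tail_free else off + j,
                        molecule=int(self.molecule[off + i]),
                    )
                )
                i = j

    def domain_templates(self) -> list[tuple[np.ndarray, np.ndarray]]:
        """(global bead indices, template coords) per rigid body, shared first."""
        topo = self.topo
        n = topo.n_res
        out = []
        if topo.shared_domain:
            # dimer core: two adjacent copies of one globule, deterministic
            a, b = topo.shared_domain
            length = b - a + 1
            half = make_rigid_domain(length, topo.domain_seed)
            flip = half @ np.diag([-1.0, 1.0, -1.0])
            gap = half[:, 0].max() - flip[:, 0].min() + 4.5
            other = flip + np.array([gap, 0.0, 0.0])
            tmpl = np.vstack([half, other])
            tmpl -= tmpl.mean(axis=0)
            idx = np.concatenate(
                [np.arange(a - 1, b), n + np.arange(a - 1, b)]
            )
            out.append((idx, tmpl))
        for k, (a, b) in enumerate(topo.rigid_domains):
            tmpl = make_rigid_domain(b - a + 1, topo.domain_seed + 13 * (k + 1))
            for c in range(topo.n_chains):
                off = c * n
                out.append((off + np.arange(a - 1, b), tmpl))
        return out


def _build_initial(layout: _Layout, rng: np.random.Generator) -> np.ndarray:
    """Grow one conformer: rigid bodies first, then flexible runs outward."""
    topo = layout.topo
    b = _Builder(layout.n_beads, BOND_LENGTH, MIN_SEPARATION)
    templates = layout.domain_templates()

    # place rigid bodies: within a molecule, the first is free, later ones are
    # attached through the flexible bridge grown afterwards -- we therefore
    # place each molecule's bodies independently and grow bridges by biased
    # closure (see below). Supported layouts have at most one rigid body per
    # molecule plus, for the dimer, the shared core.
    placed_first_of_mol: dict[int, bool] = {}
    offsets = {}
    if layout.n_molecules > 1:
        # separated molecules: successive origins > 60 A apart
        base = np.zeros(3)
        for m in range(layout.n_molecules):
            offsets[m] = base.copy()
            base = base + 80.0 * _random_units(rng, 1)[0]
    else:
        offsets[0] = np.zeros(3)

    free_bodies = []
    for idx, tmpl in templates:
        mol = int(layout.molecule[idx[0]])
        if not placed_first_of_mol.get(mol, False):
            rot = Rotation.random(rng=rng).as_matrix()
            pos = tmpl @ rot.T + offsets[mol]
            for k, p in zip(idx, pos):
                b.place(int(k), p)
            placed_first_of_mol[mol] = True
        else:
            free_bodies.append((idx, tmpl))

    # grow flexible runs; runs adjacent to an unplaced rigid body trigger its
    # placement when reached.
    pending = {int(idx[0]): (idx, tmpl) for idx, tmpl in free_bodies}
    pending.update({int(idx[-1]): (idx, tmpl) for idx, tmpl in free_bodies})

    # grow runs once one of their anchors is placed; a run reaching an
    # unplaced rigid body attaches it, which unlocks further runs.
    remaining = list(layout.runs)
    while remaining:
        progressed = False
        deferred = []
        for run in remaining:
            if run.head_anchor is not None and b.placed[run.head_anchor]:
                prev = run.head_anchor
                for i in run.indices:
                    b.grow_bead(rng, int(i), int(prev))
                    prev = int(i)
                _maybe_place_pending(b, rng, pending, run.tail_anchor, prev)
            elif run.tail_anchor is not None and b.placed[run.tail_anchor]:
                prev = run.tail_anchor
                for i in run.indices[::-1]:
                    b.grow_bead(rng, int(i), int(prev))
                    prev = int(i)
                _maybe_place_pending(b, rng, pending, run.head_anchor, prev)
            elif run.head_anchor is None and run.tail_anchor is None:
                # fully flexible molecule: seed at the molecule origin
                first = int(run.indices[0])
                b.place(first, offsets[run.molecule])
                prev = first
                for i in run.indices[1:]:
                    b.grow_bead(rng, int(i), int(prev))
                    prev = int(i)
            else:
                deferred.append(run)
                continue
            progressed = True
        if deferred and not progressed:
            raise _GrowthFailure("disconnected topology: cannot anchor all runs")
        remaining = deferred
    if not b.placed.all():
        raise _GrowthFailure("internal: unplaced beads remain")
    return b.coords


def _maybe_place_pending(b, rng, pending, anchor_bead, prev):
    """Attach a not-yet-placed rigid body when a run has grown up to it."""
    if anchor_bead is None or b.placed[anchor_bead]:
        return
    if anchor_bead in pending:
        idx, tmpl = pending[anchor_bead]
        attach_local = int(np.flatnonzero(idx == anchor_bead)[0])
        b.place_rigid(rng, idx, tmpl, attach_local, anchor=prev)
        for key in (int(idx[0]), int(idx[-1])):
            pending.pop(key, None)


# --- Metropolis refinement -------------------------------------------------


def _total_contacts(coords: np.ndarray, p_idx: np.ndarray, b_idx: np.ndarray) -> int:
    """Total phospho-basic contact count (pairs within 8 A)."""
    if p_idx.size == 0 or b_idx.size == 0:
        return 0
    diff = coords[p_idx][:, None, :] - coords[b_idx][None, :, :]
    return int(((diff * diff).sum(axis=2) < CONTACT_CUTOFF * CONTACT_CUTOFF).sum())


def _rotation_about_axis(rng, origin: np.ndarray, axis: np.ndarray | None):
    if axis is None:
        axis = _random_units(rng, 1)[0]
    else:
        nrm = np.linalg.norm(axis)
        if nrm < 1e-9:
            axis = _random_units(rng, 1)[0]
        else:
            axis = axis / nrm
    angle = rng.uniform(0, 2 * np.pi)
    R = Rotation.from_rotvec(angle * axis).as_matrix()
    return lambda x: (x - origin) @ R.T + origin


def _regrow_tail(
    rng: np.random.Generator,
    coords: np.ndarray,
    run: _FlexRun,
    n_regrow: int,
) -> tuple[np.ndarray, np.ndarray] | None:
    """Propose regrowing the outer ``n_regrow`` beads of a free-ended run.

    Returns (moved indices, new positions) or None on a dead end.
    """
    idx = run.indices
    sides = ([True] if run.head_free else []) + ([False] if run.tail_free else [])
    head = sides[int(rng.integers(len(sides)))]
    n_regrow = min(n_regrow, idx.size)
    if head:
        moved = idx[:n_regrow][::-1]  # regrow outward toward residue 1
        prev = idx[n_regrow] if n_regrow < idx.size else run.tail_anchor
    else:
        moved = idx[idx.size - n_regrow :]
        prev = idx[idx.size - n_regrow - 1] if n_regrow < idx.size else run.head_anchor
    if prev is None:
        return None
    keep = np.ones(coords.shape[0], dtype=bool)
    keep[moved] = False
    keep[int(prev)] = False  # the anchor: bonded to the first regrown bead
    occupied = coords[keep]
    anchor_pos = coords[int(prev)]
    new_pos = np.empty((moved.size, 3))
    prev_pos = anchor_pos
    for k in range(moved.size):
        cands = prev_pos + BOND_LENGTH * _random_units(rng, 24)
        min_sep2 = MIN_SEPARATION * MIN_SEPARATION
        ok = np.ones(len(cands), dtype=bool)
        if occupied.size:
            diff = cands[:, None, :] - occupied[None, :, :]
            ok &= ((diff * diff).sum(axis=2) >= min_sep2).all(axis=1)
        if k > 0:  # the anchor is non-bonded to later beads
            da = cands - anchor_pos
            ok &= (da * da).sum(axis=1) >= min_sep2
        if k > 1:  # earlier regrown beads except the bonded predecessor
            dn = cands[:, None, :] - new_pos[None, : k - 1, :]
            ok &= ((dn * dn).sum(axis=2) >= min_sep2).all(axis=1)
        good = np.flatnonzero(ok)
        if good.size == 0:
            return None
        pick = good[int(rng.integers(good.size))]
        new_pos[k] = cands[pick]
        prev_pos = new_pos[k]
    return np.asarray(moved, dtype=int), new_pos


def _metropolis_refine(
    layout: _Layout,
    coords: np.ndarray,
    kappa: float,
    rng: np.random.Generator,
    n_sweeps: int,
) -> np.ndarray:
    """Seeded Metropolis Monte Carlo on the flexible segments.

    Moves: tail regrowth (global), pivot and crankshaft (local), plus rigid
    translations/rotations of whole molecules in multi-molecule systems.
    Energy E = -kappa * (# phospho-basic contacts within 8 A); every move is
    accepted with min(1, exp(-dE)) after a hard-sphere clash check.
    """
    coords = coords.copy()
    flex_runs = [r for r in layout.runs if r.indices.size > 0]
    if not flex_runs:
        return coords
    p_idx, b_idx = layout.phospho_idx, layout.basic_idx
    n_flex = int(sum(r.indices.size for r in flex_runs))
    n_moves = n_sweeps * max(n_flex, 1)
    multi_mol = layout.n_molecules > 1
    free_runs = [r for r in flex_runs if r.head_free or r.tail_free]
    e_cur = _total_contacts(coords, p_idx, b_idx)

    for _ in range(n_moves):
        moved = None
        new_pos = None
        exempt: list[int] = []  # static beads bonded across the hinge
        clash_free = False
        u_kind = rng.uniform()
        if multi_mol and u_kind < 0.15:
            mol = int(rng.integers(1, layout.n_molecules))
            moved = np.flatnonzero(layout.molecule == mol)
            centroid = coords[moved].mean(axis=0)
            move = _rotation_about_axis(rng, centroid, None)
            new_pos = move(coords[moved]) + rng.normal(scale=4.0, size=3)
        elif free_runs and u_kind < 0.55:
            run = free_runs[int(rng.integers(len(free_runs)))]
            n_re = int(rng.integers(2, run.indices.size + 1))
            prop = _regrow_tail(rng, coords, run, n_re)
            if prop is None:
                continue
            moved, new_pos = prop
            clash_free = True  # regrowth proposals are built clash-free
        else:
            run = flex_runs[int(rng.integers(len(flex_runs)))]
            idx = run.indices
            free_sides = ([True] if run.head_free else []) + (
                [False] if run.tail_free else []
            )
            use_pivot = bool(free_sides) and rng.uniform() < 0.5
            if use_pivot:
                head = free_sides[int(rng.integers(len(free_sides)))]
                k = int(rng.integers(idx.size))
                if head:
                    moved = idx[:k] if k > 0 else idx[:1]
                    pivot = idx[k] if k > 0 else (
                        idx[1] if idx.size > 1 else run.tail_anchor
                    )
                else:
                    moved = idx[k + 1 :] if k + 1 < idx.size else idx[-1:]
                    pivot = idx[k] if k + 1 < idx.size else (
                        idx[-2] if idx.size > 1 else run.head_anchor
                    )
                if pivot is None or moved.size == 0:
                    continue
                move = _rotation_about_axis(rng, coords[int(pivot)], None)
                new_pos = move(coords[moved])
                exempt = [int(pivot)]
            else:
                # crankshaft between two hinges (anchors allowed as hinges)
                ext = list(idx)
                if run.head_anchor is not None:
                    ext = [run.head_anchor] + ext
                if run.tail_anchor is not None:
                    ext = ext + [run.tail_anchor]
                if len(ext) < 3:
                    continue
                i = int(rng.integers(0, len(ext) - 2))
                j = int(rng.integers(i + 2, min(i + 10, len(ext) - 1) + 1))
                hinge_a, hinge_b = ext[i], ext[j]
                moved = np.array(ext[i + 1 : j], dtype=int)
                axis = coords[hinge_b] - coords[hinge_a]
                move = _rotation_about_axis(rng, coords[hinge_a], axis)
                new_pos = move(coords[moved])
                exempt = [int(hinge_a), int(hinge_b)]

        if not clash_free:
            static = np.ones(coords.shape[0], dtype=bool)
            static[moved] = False
            for e in exempt:
                # hinge beads keep their 3.8 A bond under the rigid move
                static[e] = False
            st = coords[static]
            diff = new_pos[:, None, :] - st[None, :, :]
            if ((diff * diff).sum(axis=2) < MIN_SEPARATION * MIN_SEPARATION).any():
                continue
        trial = coords.copy()
        trial[moved] = new_pos
        if kappa > 0:
            e_new = _total_contacts(trial, p_idx, b_idx)
            log_acc = kappa * (e_new - e_cur)  # E = -kappa * contacts
            if log_acc < 0 and rng.uniform() > math.exp(log_acc):
                continue
            e_cur = e_new
        coords = trial
    return coords


def sample_conformer(
    topology: TopologySpec,
    kappa: float = 0.0,
    seed: int = 0,
    n_sweeps: int = 6,
    max_attempts: int = 60,
) -> Conformer:
    """Draw one conformer from the synthetic model.

    Rigid domains are internally fixed bodies; flexible segments are grown as
    3.8 A excluded-volume random walks and then refined by seeded Metropolis
    pivot/crankshaft moves with energy ``-kappa * n_contacts`` counting
    phosphoserine/basic-bead pairs within 8 A. ``kappa = 0`` is unbiased;
    larger ``kappa`` compacts the tails onto the basic segments.
    """
    if kappa < 0:
        raise ValueError("kappa must be >= 0")
    layout = _Layout(topology)
    last_err: Exception | None = None
    for attempt in range(max_attempts):
        rng = np.random.default_rng([int(seed) & 0x7FFFFFFF, 7919, attempt])
        try:
            coords = _build_initial(layout, rng)
            if layout.n_molecules > 1:
                # required initial separation before relaxation
                cents = [
                    coords[layout.molecule == m].mean(axis=0)
                    for m in range(layout.n_molecules)
                ]
                sep_ok = all(
                    np.linalg.norm(cents[a] - cents[bb]) > 60.0
                    for a in range(len(cents))
                    for bb in range(a + 1, len(cents))
                )
                if not sep_ok:
                    raise _GrowthFailure("molecules closer than 60 A after growth")
            coords = _metropolis_refine(layout, coords, kappa, rng, n_sweeps)
            return Conformer(
                coords=coords,
                residue_ids=layout.residue_ids,
                chain_ids=layout.chain_ids,
                scatter_weight=layout.scatter,
                charge=layout.charges,
            )
        except _GrowthFailure as err:  # retry with a fresh stream
            last_err = err
    raise RuntimeError(
        f"conformer generation failed after {max_attempts} attempts: {last_err}"
    )


# ---------------------------------------------------------------------------
# mixtures and targets


@dataclass(frozen=True)
class Subpopulation:
    name: str
    kappa: float


@dataclass(frozen=True)
class MixtureSpec:
    """A mixture of compact/extended subpopulations with known fractions."""

    topology: TopologySpec
    subpopulations: tuple[Subpopulation, ...] = (
        Subpopulation("compact", 5.0),
        Subpopulation("extended", 0.0),
    )
    fractions: tuple[float, ...] = (0.7, 0.3)
    n_conformers: int = 500
    seed: int = 0

    def __post_init__(self) -> None:
        f = np.asarray(self.fractions, dtype=float)
        if len(self.subpopulations) != f.size:
            raise ValueError("one fraction per subpopulation required")
        if np.any(f < 0) or abs(f.sum() - 1.0) > 1e-9:
            raise ValueError("fractions must lie on the simplex")
        if self.n_conformers < len(self.subpopulations):
            raise ValueError("n_conformers smaller than number of subpopulations")


def allocate_counts(n: int, fractions: np.ndarray) -> np.ndarray:
    """Deterministic allocation: floor(n*f) plus remainder by largest
    fractional part; ties to the largest fraction, then the lowest index."""
    f = np.asarray(fractions, dtype=float)
    raw = n * f
    counts = np.floor(raw).astype(int)
    rem = n - counts.sum()
    frac = raw - counts
    order = sorted(range(f.size), key=lambda i: (-frac[i], -f[i], i))
    for i in order[:rem]:
        counts[i] += 1
    return counts


def make_mixture_ensemble(spec: MixtureSpec) -> tuple[Ensemble, np.ndarray]:
    """Generate the mixture ensemble; returns (ensemble, labels).

    ``labels[j]`` is the subpopulation index of conformer j; initial weights
    are uniform 1/N.
    """
    counts = allocate_counts(spec.n_conformers, np.asarray(spec.fractions))
    conformers: list[Conformer] = []
    labels: list[int] = []
    ss = np.random.SeedSequence(int(spec.seed) & 0x7FFFFFFF)
    child_seeds = [int(s.generate_state(1)[0] & 0x7FFFFFFF) for s in ss.spawn(spec.n_conformers)]
    j = 0
    for pop_idx, (pop, cnt) in enumerate(zip(spec.subpopulations, counts)):
        for _ in range(cnt):
            conformers.append(
                sample_conformer(spec.topology, kappa=pop.kappa, seed=child_seeds[j])
            )
            labels.append(pop_idx)
            j += 1
    ens = Ensemble(
        conformers=conformers,
        source=f"synthetic mixture seed={spec.seed}",
        metadata={
            "labels": list(labels),
            "fractions": list(spec.fractions),
            "subpopulations": [p.name for p in spec.subpopulations],
            "kappas": [p.kappa for p in spec.subpopulations],
            "seed": spec.seed,
        },
    )
    return ens, np.asarray(labels)


def default_q_grid(q_min: float = 0.01, q_max: float = 0.30, n: int = 60) -> np.ndarray:
    """Default SEC-SAXS-like momentum-transfer grid (A^-1, log-spaced)."""
    return np.geomspace(q_min, q_max, n)


def make_target_profile(
    ensemble: Ensemble,
    true_weights: np.ndarray,
    q_grid: np.ndarray | None = None,
    noise_frac: float = 0.02,
    seed: int = 0,
    params=None,
) -> ScatteringProfile:
    """Noisy target profile from a ground-truth weighting of the ensemble.

    I_true(q) = sum_j w*_j I_j(q) (Debye); sigma(q) = noise_frac * I_true *
    (1 + q/q_max); I = I_true + N(0, sigma) with the given seed.
    """
    from .debye import debye_profile, FormFactorParams

    if q_grid is None:
        q_grid = default_q_grid()
    w = np.asarray(true_weights, dtype=float)
    if w.shape != (len(ensemble),) or np.any(w < 0) or abs(w.sum() - 1) > 1e-9:
        raise ValueError("true_weights must be a simplex vector over the ensemble")
    if noise_frac < 0:
        raise ValueError("noise_frac must be >= 0")
    params = params or FormFactorParams()
    I_true = np.zeros_like(q_grid, dtype=float)
    for wj, conf in zip(w, ensemble):
        if wj == 0:
            continue
        I_true += wj * debye_profile(conf, q_grid, params).I
    sigma = noise_frac * I_true * (1.0 + q_grid / q_grid.max())
    rng = np.random.default_rng([int(seed) & 0x7FFFFFFF, 104729])
    noise = rng.normal(0.0, 1.0, size=q_grid.size) * sigma if noise_frac > 0 else 0.0
    return ScatteringProfile(
        q=q_grid,
        I=I_true + noise,
        sigma=sigma if noise_frac > 0 else None,
        metadata={"noise_frac": noise_frac, "seed": seed, "synthetic": True},
    )
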