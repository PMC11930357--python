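import numpy as np
import pytest
from scipy.spatial.distance import pdist, squareform

from ensaxs.core import Selection, radius_of_gyration
from ensaxs.debye import debye_profile
from ensaxs.synthetic import (
    BOND_LENGTH,
    MIN_SEPARATION,
    MixtureSpec,
    Subpopulation,
    TopologySpec,
    allocate_counts,
    default_q_grid,
    delta_csd_topology,
    hp1a_dimer_topology,
    make_mixture_ensemble,
    make_rigid_domain,
    make_target_profile,
    sample_conformer,
)


class TestRigidDomain:
    def test_three_residues_bond_lengths(self):
        c = make_rigid_domain(3, seed=0)
        for i in (0, 1):
            assert np.linalg.norm(c[i + 1] - c[i]) == pytest.approx(
                BOND_LENGTH, abs=1e-9
            )

    def test_deterministic(self):
        a = make_rigid_domain(30, seed=11)
        b = make_rigid_domain(30, seed=11)
        assert np.array_equal(a, b)

    def test_excluded_volume_and_compactness(self):
        c = make_rigid_domain(50, seed=7)
        d = squareform(pdist(c))
        nonbonded = ~np.eye(50, dtype=bool)
        for i in range(49):
            nonbonded[i, i + 1] = nonbonded[i + 1, i] = False
        assert d[nonbonded].min() >= MIN_SEPARATION - 1e-9
        rg = np.sqrt(((c - c.mean(0)) ** 2).sum(1).mean())
        assert rg <= 0.9 * BOND_LENGTH * 50**0.33


def _flexible_bond_ok(conf, topo):
    """All sequential bonds within a chain are 3.8 A on flexible stretches."""
    rigid = np.zeros(topo.n_res + 1, dtype=bool)
    for a, b in topo.rigid_domains:
        rigid[a : b + 1] = True
    if topo.shared_domain:
        a, b = topo.shared_domain
        rigid[a : b + 1] = True
    ok = True
    for ch in conf.chains:
        m = conf.chain_ids == ch
        xyz = conf.coords[m]
        rid = conf.residue_ids[m]
        for k in range(len(rid) - 1):
            if rid[k + 1] != rid[k] + 1:
                continue
            if rigid[rid[k]] and rigid[rid[k + 1]]:
                continue  # internal rigid bond fixed by the template
            d = np.linalg.norm(xyz[k + 1] - xyz[k])
            ok &= abs(d - BOND_LENGTH) < 1e-6
    return ok


class TestSampleConformer:
    def test_deterministic(self, tiny_topology):
        a = sample_conformer(tiny_topology, kappa=2.0, seed=5)
        b = sample_conformer(tiny_topology, kappa=2.0, seed=5)
        assert np.array_equal(a.coords, b.coords)

    def test_rigid_domain_internal_distances_constant(self, tiny_topology):
        sel = Selection.from_ranges([tiny_topology.rigid_domains[0]])
        ref = None
        for s in range(4):
            c = sample_conformer(tiny_topology, kappa=0.0, seed=s, n_sweeps=2)
            d = pdist(c.coords[sel.mask(c)])
            if ref is None:
                ref = d
            else:
                assert np.allclose(d, ref, atol=1e-9)

    def test_flexible_bonds_exact(self, tiny_topology):
        c = sample_conformer(tiny_topology, kappa=3.0, seed=9)
        assert _flexible_bond_ok(c, tiny_topology)

    def test_excluded_volume_after_refinement(self, tiny_topology):
        c = sample_conformer(tiny_topology, kappa=5.0, seed=3)
        d = squareform(pdist(c.coords))
        n = c.n_beads
        bonded = np.zeros((n, n), dtype=bool)
        for k in range(n - 1):
            bonded[k, k + 1] = bonded[k + 1, k] = True
        np.fill_diagonal(bonded, True)
        assert d[~bonded].min() >= MIN_SEPARATION - 1e-6

    def test_compaction_bias_monotone(self, tiny_topology):
        r0 = [
            radius_of_gyration(sample_conformer(tiny_topology, 0.0, seed=s))
            for s in range(40)
        ]
        r5 = [
            radius_of_gyration(sample_conformer(tiny_topology, 5.0, seed=s))
            for s in range(40)
        ]
        assert np.mean(r0) > np.mean(r5)

    def test_dimer_topology_builds(self):
        topo = hp1a_dimer_topology(phosphorylated=True)
        c = sample_conformer(topo, kappa=0.0, seed=2, n_sweeps=1)
        assert c.n_beads == 2 * 191
        assert set(c.chains) == {"A", "B"}

    def test_two_molecule_initial_separation(self):
        topo = delta_csd_topology(phosphorylated=True, n_molecules=2)
        c = sample_conformer(topo, kappa=0.0, seed=4, n_sweeps=0)
        a = c.coords[c.chain_ids == "A"].mean(axis=0)
        b = c.coords[c.chain_ids == "B"].mean(axis=0)
        assert np.linalg.norm(a - b) > 60.0

    def test_negative_kappa_rejected(self, tiny_topology):
        with pytest.raises(ValueError):
            sample_conformer(tiny_topology, kappa=-1.0, seed=0)


class TestTopologySpec:
    def test_overlapping_domains_rejected(self):
        with pytest.raises(ValueError):
            TopologySpec(n_res=50, rigid_domains=((5, 20), (18, 30)))

    def test_charges_layout(self):
        topo = delta_csd_topology(phosphorylated=True)
        q = topo.charges()
        assert np.all(q[[10, 11, 12, 13]] == -2.0)  # phosphoserines 11-14
        assert np.all(q[67:72] == 1.0)  # b4 = 68-72
        assert q.sum() != 0

    def test_segment_annotation_bounds(self):
        ann = hp1a_dimer_topology().segment_annotation()
        assert ann["CSD"] == (113, 173)
        assert ann["CD"] == (19, 74)


class TestMixture:
    @pytest.mark.parametrize(
        "n,fractions,expected",
        [
            (10, (0.7, 0.3), (7, 3)),
            (3, (0.5, 0.5), (2, 1)),  # remainder goes to the lowest index on ties
            (7, (0.5, 0.25, 0.25), (3, 2, 2)),
        ],
    )
    def test_allocation(self, n, fractions, expected):
        assert tuple(allocate_counts(n, np.array(fractions))) == expected

    def test_labels_partition(self, tiny_topology):
        spec = MixtureSpec(
            topology=tiny_topology,
            subpopulations=(Subpopulation("c", 4.0), Subpopulation("e", 0.0)),
            fractions=(0.7, 0.3),
            n_conformers=10,
            seed=1,
        )
        ens, labels = make_mixture_ensemble(spec)
        assert len(ens) == 10
        assert np.array_equal(np.sort(np.unique(labels)), [0, 1])
        assert (labels == 0).sum() == 7 and (labels == 1).sum() == 3
        assert np.allclose(ens.weights, 0.1)

    def test_too_few_conformers(self, tiny_topology):
        with pytest.raises(ValueError):
            MixtureSpec(topology=tiny_topology, n_conformers=1, seed=0)


class TestTargetProfile:
    def test_zero_noise_is_exact_weighted_sum(self, tiny_ensemble):
        q = default_q_grid(n=20)
        w = np.full(len(tiny_ensemble), 1 / len(tiny_ensemble))
        target = make_target_profile(tiny_ensemble, w, q, noise_frac=0.0, seed=0)
        manual = sum(
            wj * debye_profile(c, q).I for wj, c in zip(w, tiny_ensemble)
        )
        assert np.allclose(target.I, manual, rtol=1e-12)
        assert target.sigma is None

    def test_same_seed_identical(self, tiny_ensemble):
        q = default_q_grid(n=20)
        w = np.full(len(tiny_ensemble), 1 / len(tiny_ensemble))
        a = make_target_profile(tiny_ensemble, w, q, noise_frac=0.02, seed=9)
        b = make_target_profile(tiny_ensemble, w, q, noise_frac=0.02, seed=9)
        assert np.array_equal(a.I, b.I)

    def test_noise_chi2_distribution(self, tiny_ensemble):
        # chi^2 of the noise-free average against the noisy profile ~ chi^2_M
        q = default_q_grid(n=40)
        m = q.size
        w = np.full(len(tiny_ensemble), 1 / len(tiny_ensemble))
        clean = make_target_profile(tiny_ensemble, w, q, noise_frac=0.0, seed=0)
        for seed in range(5):
            noisy = make_target_profile(tiny_ensemble, w, q, noise_frac=0.02, seed=seed)
            chi2 = (((clean.I - noisy.I) / noisy.sigma) ** 2).sum()
            assert abs(chi2 - m) < 3 * np.sqrt(2 * m)
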