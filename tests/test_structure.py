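import numpy as np
import pytest

from ensaxs.core import Conformer, Ensemble
from ensaxs.structure import (
    contact_probability,
    gromos_cluster_weighted,
    pairwise_rmsd_matrix,
    representative_structures,
)
from ensaxs.synthetic import make_rigid_domain
from .conftest import random_conformer


def _two_bead_ensemble(distances):
    confs = [
        Conformer(
            np.array([[0.0, 0, 0], [d, 0, 0]]), np.array([1, 2]), np.array(["A", "A"])
        )
        for d in distances
    ]
    return Ensemble(confs)


class TestContactProbability:
    def test_always_in_contact(self):
        ens = _two_bead_ensemble([5.0, 5.0, 5.0])
        cm = contact_probability(ens, cutoff=11.0, mode="intra")
        assert cm.value(1, 2) == pytest.approx(1.0)

    def test_indicator_mean_is_half(self):
        ens = _two_bead_ensemble([12.0, 5.0, 12.0, 5.0])
        cm = contact_probability(ens, cutoff=11.0, mode="intra")
        assert cm.value(1, 2) == pytest.approx(0.5)

    def test_matches_brute_force_loop(self, rng):
        confs = [random_conformer(np.random.default_rng(i), n=8) for i in range(6)]
        w = rng.dirichlet(np.ones(6))
        ens = Ensemble(confs, weights=w)
        cm = contact_probability(ens, cutoff=11.0, mode="intra")
        for a in range(8):
            for b in range(8):
                p = 0.0
                for wj, c in zip(w, confs):
                    d = np.linalg.norm(c.coords[a] - c.coords[b])
                    p += wj * (d <= 11.0)
                assert cm.matrix[a, b] == pytest.approx(p, abs=1e-12)

    def test_bounds_and_symmetry(self, rng):
        confs = [random_conformer(np.random.default_rng(i), n=10, chains=2)
                 for i in range(5)]
        ens = Ensemble(confs)
        for mode in ("intra", "inter"):
            cm = contact_probability(ens, mode=mode)
            assert np.all(cm.matrix >= 0) and np.all(cm.matrix <= 1)
            assert np.allclose(cm.matrix, cm.matrix.T, atol=1e-12)

    def test_inter_requires_two_chains(self, rng):
        ens = Ensemble([random_conformer(rng, n=6)])
        with pytest.raises(ValueError):
            contact_probability(ens, mode="inter")


def brute_force_weighted_gromos(D, w, cutoff):
    """Independent implementation of the stated leader rule."""
    n = len(w)
    unassigned = set(range(n))
    labels = [-1] * n
    clusters = []
    while unassigned:
        best, best_score = None, -1.0
        for j in sorted(unassigned):
            score = sum(w[k] for k in unassigned if D[j, k] <= cutoff)
            if score > best_score + 1e-15:
                best, best_score = j, score
        members = [k for k in sorted(unassigned) if D[best, k] <= cutoff]
        clusters.append((best, sum(w[k] for k in members), members))
        for k in members:
            unassigned.discard(k)
    # order by descending weight (ties by center index)
    clusters.sort(key=lambda t: (-t[1], t[0]))
    for lab, (_, _, members) in enumerate(clusters):
        for k in members:
            labels[k] = lab
    return labels, [c[0] for c in clusters], [c[1] for c in clusters]


class TestGromosClustering:
    def test_all_identical_single_cluster(self, globule):
        ens = Ensemble([globule] * 5)
        asg = gromos_cluster_weighted(ens, cutoff=1.0)
        assert asg.n_clusters == 1
        assert asg.cluster_weights[0] == pytest.approx(1.0)
        assert asg.centers[0] == 0

    def test_two_separated_groups_ordered_by_weight(self):
        # two distinct rigid shapes whose mutual RMSD far exceeds the cutoff
        shape_a = make_rigid_domain(12, seed=1)
        shape_b = make_rigid_domain(12, seed=2)
        confs = [Conformer(shape_a, np.arange(1, 13), np.array(["A"] * 12))] * 3
        confs += [Conformer(shape_b, np.arange(1, 13), np.array(["A"] * 12))] * 2
        w = np.array([0.2, 0.2, 0.2, 0.2, 0.2])
        ens = Ensemble(list(confs), weights=w)
        D = pairwise_rmsd_matrix(ens)
        cutoff = 0.5 * D.max()
        assert D[0, 3] > cutoff  # groups really are separated
        asg = gromos_cluster_weighted(ens, cutoff=cutoff, rmsd_matrix=D)
        assert asg.n_clusters == 2
        assert np.allclose(asg.cluster_weights, [0.6, 0.4])

    def test_matches_independent_oracle(self, rng):
        for trial in range(30):
            r = np.random.default_rng(trial)
            n = int(r.integers(2, 9))
            confs = [random_conformer(np.random.default_rng(100 * trial + i), n=5)
                     for i in range(n)]
            w = r.dirichlet(np.ones(n))
            ens = Ensemble(confs, weights=w)
            cutoff = float(r.uniform(2, 15))
            D = pairwise_rmsd_matrix(ens)
            asg = gromos_cluster_weighted(ens, cutoff=cutoff, rmsd_matrix=D)
            labels, centers, weights = brute_force_weighted_gromos(D, w, cutoff)
            assert list(asg.labels) == labels
            assert list(asg.centers) == centers
            assert np.allclose(asg.cluster_weights, weights)

    def test_uniform_weights_reduce_to_classic_gromos(self, rng):
        for trial in range(10):
            r = np.random.default_rng(500 + trial)
            n = int(r.integers(3, 9))
            confs = [random_conformer(np.random.default_rng(900 + 50 * trial + i), n=5)
                     for i in range(n)]
            ens = Ensemble(confs)
            cutoff = float(r.uniform(2, 15))
            D = pairwise_rmsd_matrix(ens)
            asg = gromos_cluster_weighted(ens, cutoff=cutoff, rmsd_matrix=D)
            # classic GROMOS: neighbour counts
            labels, centers, _ = brute_force_weighted_gromos(
                D, np.ones(n) / n, cutoff
            )
            assert list(asg.labels) == labels
            assert list(asg.centers) == centers

    def test_cluster_weights_sum_to_one(self, tiny_ensemble, rng):
        w = rng.dirichlet(np.ones(len(tiny_ensemble)))
        asg = gromos_cluster_weighted(tiny_ensemble, weights=w, cutoff=15.0)
        assert asg.cluster_weights.sum() == pytest.approx(1.0, abs=1e-9)
        assert np.all(np.diff(asg.cluster_weights) <= 1e-12)


class TestRepresentatives:
    def test_warns_when_fewer_clusters(self, globule):
        ens = Ensemble([globule] * 4)
        asg = gromos_cluster_weighted(ens, cutoff=1.0)
        with pytest.warns(UserWarning, match="returning all"):
            reps = representative_structures(asg, ens, top_k=6)
        assert len(reps) == 1

    def test_centers_belong_to_their_clusters(self, tiny_ensemble):
        asg = gromos_cluster_weighted(tiny_ensemble, cutoff=12.0)
        reps = representative_structures(asg, tiny_ensemble,
                                         top_k=asg.n_clusters)
        total = sum(wt for _, wt, _ in reps)
        assert total <= 1.0 + 1e-9
        for k in range(asg.n_clusters):
            assert asg.labels[asg.centers[k]] == k
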