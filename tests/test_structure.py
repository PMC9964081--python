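"""Ancestry NMF and DAPC: simplex constraints, descent, separability, CV."""

import numpy as np
import pytest

import clonalpop as cp
from clonalpop.structure import AncestryNMF, DAPC, masked_cross_entropy


class TestAncestry:
    def test_k1_is_all_ones(self, two_pop_bundle):
        gm = two_pop_bundle[0]
        anc = cp.estimate_ancestry(gm, 1, seed=0)
        assert np.allclose(anc.Q, 1.0)

    def test_rows_on_simplex_and_freq_blocks_normalised(self, two_pop_bundle):
        gm = two_pop_bundle[0]
        anc = cp.estimate_ancestry(gm, 3, seed=1)
        assert np.allclose(anc.Q.sum(axis=1), 1.0, atol=1e-6)
        assert (anc.Q >= 0).all()
        blocks = anc.G_freq.reshape(3, -1, 3)
        assert np.allclose(blocks.sum(axis=2), 1.0, atol=1e-6)

    def test_monotone_descent(self, two_pop_bundle):
        gm = two_pop_bundle[0]
        est = AncestryNMF(n_components=3, random_state=2).fit(gm)
        losses = np.asarray(est.loss_curve_)
        assert (np.diff(losses) <= 1e-8).all()

    def test_two_population_separability(self, two_pop_bundle):
        """At theta=0.25, >=90% of samples put >=0.8 ancestry in their own cluster."""
        gm, pm, _, _ = two_pop_bundle
        anc = cp.estimate_ancestry(gm, 2, seed=3)
        labels = pm.labels_for(gm.sample_ids)
        own_cluster = {
            pop: int(anc.Q[labels == pop].mean(axis=0).argmax())
            for pop in pm.populations
        }
        assert own_cluster["pop01"] != own_cluster["pop02"]
        own = np.array([anc.Q[i, own_cluster[labels[i]]] for i in range(gm.n)])
        assert (own >= 0.8).mean() >= 0.9

    def test_sample_reordering_equivariance(self, two_pop_bundle):
        gm = two_pop_bundle[0]
        perm = np.random.default_rng(5).permutation(gm.n)
        q1 = cp.estimate_ancestry(gm, 2, seed=3).Q[perm]
        q2 = cp.estimate_ancestry(gm.take_samples(perm), 2, seed=3).Q
        err = min(
            np.abs(q1 - q2).max(), np.abs(q1 - q2[:, ::-1]).max()
        )  # up to cluster relabeling
        assert err < 1e-8

    def test_k_exceeding_samples_rejected(self, tiny_gm):
        with pytest.raises(ValueError):
            cp.estimate_ancestry(tiny_gm, 5, seed=0)


class TestSelectK:
    def test_recovers_three_clusters(self):
        cfg = cp.SimulationConfig(
            n_pops=3, loci=1500, fst_target=0.25, fis=0.0, genets_per_pop=12,
            mean_ramets=1.0, error_rate=0.0, missing_rate=0.1, seed=5,
        )
        gm, _, _, _ = cp.simulate(cfg)
        best, curve = cp.select_k(gm, range(1, 6), seed=6, n_reps=3)
        assert best == 3
        assert sorted(curve) == [1, 2, 3, 4, 5]

    def test_panmictic_prefers_k1(self):
        cfg = cp.SimulationConfig(
            n_pops=1, loci=800, fst_target=0.0, fis=0.0, genets_per_pop=30,
            mean_ramets=1.0, error_rate=0.0, missing_rate=0.1, seed=9,
        )
        gm, _, _, _ = cp.simulate(cfg)
        best, curve = cp.select_k(gm, range(1, 5), seed=10, n_reps=3)
        assert best == 1
        ks = sorted(curve)
        assert all(curve[a] <= curve[b] for a, b in zip(ks, ks[1:]))


def test_masked_cross_entropy_perfect_prediction():
    codes = np.array([[0, 2], [0, 2]])
    Q = np.ones((2, 1))
    G = np.array([[1.0, 0.0, 0.0, 0.0, 0.0, 1.0]])
    ce = masked_cross_entropy(Q, G, codes, np.ones_like(codes, dtype=bool))
    assert ce == pytest.approx(0.0, abs=1e-6)


class TestDapc:
    def test_fixed_difference_perfect_separation(self):
        calls = np.vstack([np.zeros((6, 30), int), np.full((6, 30), 2)])
        gm = cp.GenotypeMatrix(
            [f"s{i}" for i in range(12)], [f"1:{j}" for j in range(30)], calls
        )
        pm = cp.PopulationMap({f"s{i}": ("A" if i < 6 else "B") for i in range(12)})
        res = cp.dapc(gm, pm, n_pcs=3)
        axis1 = res.discriminants[:, 0]
        assert max(axis1[:6]) < min(axis1[6:]) or min(axis1[:6]) > max(axis1[6:])

    def test_axis_variance_sorted_and_bounded(self, two_pop_bundle):
        gm, pm, _, _ = two_pop_bundle
        res = cp.dapc(gm, pm, n_pcs=5)
        av = res.axis_variance
        assert (np.diff(av) <= 1e-12).all()
        assert (av >= 0).all() and av.sum() <= 1 + 1e-9
        assert res.discriminants.shape[1] <= min(len(pm.populations) - 1, 5)

    def test_locus_reordering_invariance(self, two_pop_bundle):
        gm, pm, _, _ = two_pop_bundle
        perm = np.random.default_rng(6).permutation(gm.m)
        r1 = cp.dapc(gm, pm, n_pcs=4)
        r2 = cp.dapc(gm.take_loci(perm), pm, n_pcs=4)
        assert np.allclose(np.abs(r1.discriminants), np.abs(r2.discriminants), atol=1e-6)

    def test_singleton_population_rejected(self, tiny_gm):
        pm = cp.PopulationMap({"s1": "A", "s2": "A", "s3": "A", "s4": "B"})
        with pytest.raises(ValueError, match="B"):
            cp.dapc(tiny_gm, pm, n_pcs=2)

    def test_null_assignment_near_chance(self):
        """Random labels on panmictic data: CV reassignment ~ chance."""
        cfg = cp.SimulationConfig(
            n_pops=1, loci=500, fst_target=0.0, fis=0.0, genets_per_pop=60,
            mean_ramets=1.0, error_rate=0.0, missing_rate=0.0, seed=12,
        )
        gm, _, _, _ = cp.simulate(cfg)
        rng = np.random.default_rng(13)
        labels = rng.permutation(np.repeat(["A", "B", "C", "D"], gm.n // 4))
        pm = cp.PopulationMap(dict(zip(gm.sample_ids, labels)))
        _, scores = cp.crossvalidate_pcs(gm, pm, [5], n_reps=20, seed=14)
        assert scores[5] <= 1.5 / 4


class TestCrossvalidatePcs:
    def test_strong_separation_high_reassignment(self, two_pop_bundle):
        gm, pm, _, _ = two_pop_bundle
        best, scores = cp.crossvalidate_pcs(gm, pm, [2, 5, 10], n_reps=10, seed=15)
        assert scores[best] >= 0.95

    def test_deterministic_and_tie_breaks_small(self, two_pop_bundle):
        gm, pm, _, _ = two_pop_bundle
        a = cp.crossvalidate_pcs(gm, pm, [2, 5], n_reps=5, seed=16)
        b = cp.crossvalidate_pcs(gm, pm, [2, 5], n_reps=5, seed=16)
        assert a == b
        if abs(a[1][2] - a[1][5]) < 1e-12:
            assert a[0] == 2
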