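"""Prevosti distance, threshold detection, UPGMA cut, clonal richness, maps."""

import numpy as np
import pytest
from hypothesis import given
from hypothesis import strategies as st
from hypothesis.extra.numpy import arrays
from sklearn.metrics import adjusted_rand_score

import clonalpop as cp
from clonalpop.clonality import (
    DistanceMatrix,
    assign_clones,
    clonal_richness,
    detect_threshold,
    genetic_distance,
    upgma,
)
from clonalpop.genotype_io import MISSING


def _gm(rows):
    rows = np.asarray(rows)
    return cp.GenotypeMatrix(
        [f"s{i}" for i in range(rows.shape[0])],
        [f"1:{j}" for j in range(rows.shape[1])],
        rows,
    )


class TestPrevostiDistance:
    def test_identical_rows_zero(self):
        d = genetic_distance(_gm([[0, 1, 2], [0, 1, 2]]))
        assert d.d[0, 1] == 0.0

    def test_opposite_homozygotes_one(self):
        d = genetic_distance(_gm([[0, 0], [2, 2]]))
        assert d.d[0, 1] == pytest.approx(1.0)

    def test_missing_locus_excluded(self):
        d = genetic_distance(_gm([[0, 1, MISSING], [0, 2, 2]]))
        assert d.d[0, 1] == pytest.approx(0.25)  # (0+1)/(2*2)
        assert d.comparable_loci[0, 1] == 2

    def test_no_comparable_loci_names_pair(self):
        with pytest.raises(ValueError, match="s0.*s1"):
            genetic_distance(_gm([[0, MISSING], [MISSING, 1]]))

    @given(
        rows=arrays(
            np.int8,
            st.tuples(st.integers(2, 6), st.integers(3, 8)),
            elements=st.sampled_from([0, 1, 2]),
        )
    )
    def test_metric_properties(self, rows):
        d = genetic_distance(_gm(rows))
        assert np.allclose(d.d, d.d.T)
        assert (d.d >= 0).all() and (d.d <= 1).all()
        assert np.allclose(np.diag(d.d), 0)


def _dm(values):
    """DistanceMatrix whose off-diagonal upper triangle is `values`."""
    k = int((1 + np.sqrt(1 + 8 * len(values))) / 2)
    d = np.zeros((k, k))
    d[np.triu_indices(k, 1)] = values
    d = d + d.T
    return DistanceMatrix([f"s{i}" for i in range(k)], d, np.full((k, k), 10))


class TestDetectThreshold:
    def test_gap_midpoint(self):
        d_star = detect_threshold(_dm([0.001, 0.002, 0.003, 0.06, 0.07, 0.065,
                                       0.001, 0.002, 0.06, 0.07]))
        assert d_star == pytest.approx(0.0315)

    def test_all_distinct_floor_returns_none(self):
        """Minimum pairwise distance >= 0.04: no clonal pairs, no threshold."""
        assert detect_threshold(_dm([0.041, 0.05, 0.06])) is None

    def test_no_gap_returns_none(self):
        vals = np.linspace(0.001, 0.099, 45)  # continuum, max gap < bin width
        assert detect_threshold(_dm(vals)) is None

    def test_far_mode_above_ceiling_still_detected(self):
        d_star = detect_threshold(_dm([0.0, 0.0, 0.3, 0.0, 0.3, 0.3]))
        assert d_star is not None and 0.0 < d_star <= 0.10


class TestUpgma:
    def test_first_merge_is_smallest_distance(self):
        d = _dm([0.02, 0.10, 0.10])
        Z = upgma(d)
        assert set(Z[0, :2].astype(int)) == {0, 1}
        assert Z[0, 2] == pytest.approx(0.02)

    def test_ultrametric_root_height(self):
        rng = np.random.default_rng(0)
        vals = rng.uniform(0.01, 0.5, size=15)
        Z = upgma(_dm(vals))
        assert Z[-1, 2] == Z[:, 2].max()

    def test_identical_samples_merge_at_zero(self):
        Z = upgma(_dm([0.0, 0.3, 0.3]))
        assert Z[0, 2] == 0.0


class TestAssignClones:
    @pytest.mark.parametrize(
        "sizes, cr",
        [([5, 23], 1 / 27), ([1, 1, 19], 2 / 20), ([11], 0.0)],
    )
    def test_published_plot_configurations(self, sizes, cr):
        """Cluster-size layouts of the study's circular plots and a
        monoclonal population reproduce the printed clonal richness."""
        vals = []
        bounds = np.cumsum([0] + sizes)
        n = bounds[-1]
        d = np.full((n, n), 0.3)
        for a, b in zip(bounds, bounds[1:]):
            d[a:b, a:b] = 0.0
        np.fill_diagonal(d, 0.0)
        dm = DistanceMatrix([f"s{i}" for i in range(n)], d, np.full((n, n), 10))
        a = assign_clones(upgma(dm), 0.03, dm.sample_ids)
        assert a.G == len(sizes)
        assert sorted(a.ramets_per_genet.values()) == sorted(sizes)
        assert a.CR == pytest.approx(cr)

    def test_none_threshold_all_unique(self):
        dm = _dm([0.0, 0.0, 0.0])
        a = assign_clones(upgma(dm), None, dm.sample_ids)
        assert a.G == a.N == 3 and a.CR == 1.0

    def test_conservation_and_bounds(self, clonal_bundle):
        gm, _, _, _ = clonal_bundle
        delim = cp.CloneDelimiter().fit(gm)
        a = delim.assignment_
        assert sum(a.ramets_per_genet.values()) == a.N
        assert 1 <= a.G <= a.N
        assert (a.CR == 1.0) == (a.G == a.N)
        assert (a.CR == 0.0) == (a.G == 1)

    def test_g_nonincreasing_in_threshold(self, clonal_bundle):
        gm, _, _, _ = clonal_bundle
        dist = genetic_distance(gm)
        Z = upgma(dist)
        gs = [
            assign_clones(Z, t, dist.sample_ids).G
            for t in np.linspace(0.001, 0.6, 25)
        ]
        assert all(a >= b for a, b in zip(gs, gs[1:]))


def test_clonal_richness_bounds_and_singleton():
    assert clonal_richness(1, 1) == 1.0
    assert clonal_richness(1, 5) == 0.0
    assert clonal_richness(5, 5) == 1.0
    with pytest.raises(ValueError):
        clonal_richness(6, 5)


class TestRecovery:
    def test_zero_noise_exact(self):
        cfg = cp.SimulationConfig(
            n_pops=1, loci=500, fst_target=0.0, fis=0.0, genets_per_pop=5,
            ramet_counts=[[5, 3, 2, 4, 1]], error_rate=0.0, missing_rate=0.0, seed=7,
        )
        gm, _, _, truth = cp.simulate(cfg)
        delim = cp.CloneDelimiter().fit(gm)
        pred = [delim.assignment_.genet_of[s] for s in delim.kept_samples_]
        true = [truth.genet_of[s] for s in delim.kept_samples_]
        assert adjusted_rand_score(true, pred) == 1.0

    def test_noisy_recovery(self, clonal_bundle):
        gm, _, _, truth = clonal_bundle
        delim = cp.CloneDelimiter().fit(gm)
        pred = [delim.assignment_.genet_of[s] for s in delim.kept_samples_]
        true = [truth.genet_of[s] for s in delim.kept_samples_]
        assert adjusted_rand_score(true, pred) >= 0.95

    def test_manual_threshold_override(self, clonal_bundle):
        gm, _, _, truth = clonal_bundle
        delim = cp.CloneDelimiter(threshold=0.05).fit(gm)
        assert delim.d_star_ == 0.05
        assert delim.assignment_.G == len(set(truth.genet_of.values()))


class TestClonalMap:
    def _assignment(self, genets):
        ramets: dict[str, int] = {}
        for g in genets.values():
            ramets[g] = ramets.get(g, 0) + 1
        return cp.CloneAssignment(
            genet_of=genets, d_star=0.01, G=len(ramets), N=len(genets),
            ramets_per_genet=ramets,
            CR=clonal_richness(len(ramets), len(genets)),
        )

    def test_interleaved_line_full_intermixing(self):
        genets = {f"s{i}": ("A" if i % 2 == 0 else "B") for i in range(8)}
        coords = cp.SampleCoordinates({f"s{i}": (float(i), 0.0) for i in range(8)})
        _, idx = cp.clonal_map(self._assignment(genets), coords)
        assert idx == 1.0

    def test_disjoint_clusters_no_intermixing(self):
        genets = {f"s{i}": ("A" if i < 4 else "B") for i in range(8)}
        coords = cp.SampleCoordinates(
            {f"s{i}": (float(i % 4) * 0.01, 0.0 if i < 4 else 5.0) for i in range(8)}
        )
        _, idx = cp.clonal_map(self._assignment(genets), coords)
        assert idx == 0.0

    def test_guerrilla_beats_phalanx(self):
        idxs = {}
        for layout in ("guerrilla", "phalanx"):
            cfg = cp.SimulationConfig(
                n_pops=1, loci=400, fst_target=0.0, fis=0.0, genets_per_pop=4,
                ramet_counts=[[6, 6, 6, 6]], error_rate=0.0, missing_rate=0.0,
                layout=layout, seed=11,
            )
            gm, _, coords, _ = cp.simulate(cfg)
            delim = cp.CloneDelimiter().fit(gm)
            _, idxs[layout] = cp.clonal_map(delim.assignment_, coords)
        assert idxs["guerrilla"] > idxs["phalanx"]

    def test_missing_coordinates_warn_and_omit(self):
        genets = {"a": "A", "b": "A", "c": "B"}
        coords = cp.SampleCoordinates({"a": (0.0, 0.0), "b": (1.0, 0.0)})
        with pytest.warns(UserWarning, match="c"):
            df, _ = cp.clonal_map(self._assignment(genets), coords)
        assert set(df["sample"]) == {"a", "b"}
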