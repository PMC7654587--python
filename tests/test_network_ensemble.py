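import numpy as np
import pandas as pd
import pytest

from radialct.hic_io import BinTable, HicMatrix
from radialct.network_ensemble import (
    Layout3D,
    build_distance_matrix,
    build_graph,
    chromosome_com,
    fit_mve,
    fr_layout_3d,
    generate_ensemble,
    mve_volume,
    radial_distances,
)
from radialct.strong_contacts import StrongMatrix, threshold_strong


def _bins(spec):
    rows = []
    for chrom, n in spec:
        rows += [(chrom, i * 10, (i + 1) * 10) for i in range(n)]
    return BinTable(pd.DataFrame(rows, columns=["chrom", "start", "end"]))


def _strong(vals, bins):
    return StrongMatrix(np.asarray(vals, dtype=float), 0.0, 95.0, bins)


class TestBuildGraph:
    def test_edges_and_weights(self):
        bins = _bins([("chrA", 2), ("chrB", 2)])
        vals = np.zeros((4, 4))
        for (i, j), w in {(0, 1): 3.0, (0, 2): 5.0, (2, 3): 7.0}.items():
            vals[i, j] = vals[j, i] = w
        G = build_graph(_strong(vals, bins), bins)
        assert G.number_of_edges() == 3
        assert G[0][2]["weight"] == 5.0
        assert G.nodes[0]["chrom"] == "chrA"
        assert G.nodes[2]["chrom"] == "chrB"

    def test_self_loops_excluded(self):
        bins = _bins([("chrA", 2)])
        vals = np.array([[9.0, 1.0], [1.0, 9.0]])
        G = build_graph(_strong(vals, bins), bins)
        assert G.number_of_edges() == 1
        assert not list(True for n in G.nodes if G.has_edge(n, n))

    def test_empty_graph_raises(self):
        bins = _bins([("chrA", 2)])
        with pytest.raises(ValueError, match="empty"):
            build_graph(_strong(np.zeros((2, 2)), bins), bins)


class TestFrLayout:
    def _line_graph(self):
        bins = _bins([("chrA", 2)])
        vals = np.zeros((2, 2))
        vals[0, 1] = vals[1, 0] = 4.0
        return build_graph(_strong(vals, bins), bins)

    def test_two_nodes_bounded_distance(self):
        lay = fr_layout_3d(self._line_graph(), seed=0, iterations=100)
        d = np.linalg.norm(lay.coords[0] - lay.coords[1])
        assert 0 < d < np.sqrt(3) * 5  # stays near the unit-cube scale

    def test_seed_determinism(self):
        a = fr_layout_3d(self._line_graph(), seed=42, iterations=50)
        b = fr_layout_3d(self._line_graph(), seed=42, iterations=50)
        assert np.array_equal(a.coords, b.coords)

    def test_strongly_linked_chromosomes_lie_closer(self):
        """chrA-chrB share many strong edges, chrA-chrC few: over an
        ensemble, the A-B center-of-mass distance is smaller on average."""
        rng = np.random.default_rng(0)
        nb = 8
        bins = _bins([("chrA", nb), ("chrB", nb), ("chrC", nb)])
        m = 3 * nb
        vals = np.zeros((m, m))
        blocks = {"chrA": range(0, nb), "chrB": range(nb, 2 * nb),
                  "chrC": range(2 * nb, 3 * nb)}
        for blk in blocks.values():  # intra chains keep territories compact
            for i, j in zip(list(blk)[:-1], list(blk)[1:]):
                vals[i, j] = vals[j, i] = 10.0
        for i in blocks["chrA"]:
            for j in blocks["chrB"]:
                vals[i, j] = vals[j, i] = 5.0
        i, j = list(blocks["chrA"])[0], list(blocks["chrC"])[0]
        vals[i, j] = vals[j, i] = 1.0
        G = build_graph(_strong(vals, bins), bins)
        chroms = ["chrA", "chrB", "chrC"]
        d_ab, d_ac = [], []
        for seed in range(30):
            lay = fr_layout_3d(G, seed=seed, iterations=150)
            coms = chromosome_com(lay, chroms)
            d_ab.append(np.linalg.norm(coms[0] - coms[1]))
            d_ac.append(np.linalg.norm(coms[0] - coms[2]))
        assert np.mean(d_ab) < np.mean(d_ac)

    def test_ensemble_seeds_and_determinism(self):
        G = self._line_graph()
        ens = generate_ensemble(G, 3, base_seed=5, iterations=20)
        assert [l.seed for l in ens] == [5, 6, 7]
        ens2 = generate_ensemble(G, 3, base_seed=5, iterations=20)
        for a, b in zip(ens, ens2):
            assert np.array_equal(a.coords, b.coords)


class TestMve:
    def test_octahedron(self):
        r = 2.0
        pts = r * np.array([[1, 0, 0], [-1, 0, 0], [0, 1, 0],
                            [0, -1, 0], [0, 0, 1], [0, 0, -1]], dtype=float)
        fit = fit_mve(pts, epsilon=1e-9, max_iter=100000)
        assert np.allclose(fit.center, 0, atol=1e-6)
        assert np.allclose(fit.shape, np.eye(3) / r**2, atol=1e-6)

    @pytest.mark.parametrize("seed", [0, 1, 2, 3, 4])
    def test_all_points_enclosed(self, seed):
        pts = np.random.default_rng(seed).normal(size=(25, 3))
        fit = fit_mve(pts, epsilon=1e-3)
        q = np.einsum("ij,jk,ik->i", pts - fit.center, fit.shape, pts - fit.center)
        assert (q <= 1 + fit.tolerance).all()

    def test_volume_against_tight_oracle_and_rotation(self):
        pts = np.random.default_rng(7).normal(size=(20, 3))
        fit = fit_mve(pts, epsilon=1e-3)
        oracle = fit_mve(pts, epsilon=1e-8, max_iter=300000)
        assert mve_volume(fit) / mve_volume(oracle) == pytest.approx(1.0, abs=0.01)
        Q, _ = np.linalg.qr(np.random.default_rng(8).normal(size=(3, 3)))
        fit_rot = fit_mve(pts @ Q.T, epsilon=1e-3)
        assert mve_volume(fit_rot) == pytest.approx(mve_volume(fit), rel=1e-3)

    def test_too_few_points_raises(self):
        with pytest.raises(ValueError, match="at least"):
            fit_mve(np.zeros((3, 3)))


class TestRandomizedEnsembleInvariance:
    def test_no_residual_source_signal_after_randomization(self):
        """Radial-distance distributions from randomized matrices carry
        no cell-type signal: per-CT Kolmogorov-Smirnov distances between
        ensembles built from two different source maps are statistically
        indistinguishable from those between two randomizations of the
        same source (quenched-shuffle variability only)."""
        from scipy import stats

        from radialct.hic_io import filter_bins
        from radialct.network_ensemble import ensemble_distance_matrix
        from radialct.randomization import ShuffleSpec, simulate_random_ligation
        from radialct.strong_contacts import compute_hcut, threshold_strong
        from radialct.synthetic import CHROMS, HG19_LENGTHS, SyntheticSpec, make_dataset

        genome = [(c, HG19_LENGTHS[c] // 20) for c in CHROMS]

        def rand_D(org, seed, shuffle_seed):
            spec = SyntheticSpec(organization=org, seed=seed, genome=genome)
            H, *_ = make_dataset(spec)
            HR = simulate_random_ligation(filter_bins(H),
                                          ShuffleSpec(seed=shuffle_seed))
            S = threshold_strong(HR, compute_hcut(HR, 95))
            return ensemble_distance_matrix(S, 60, base_seed=shuffle_seed * 100,
                                            iterations=250)

        A1 = rand_D("gene_density", 1, 11)
        A2 = rand_D("gene_density", 1, 22)  # same source, new shuffle
        B1 = rand_D("length", 2, 33)        # different source

        def ks_per_ct(X, Y):
            return np.array([
                stats.ks_2samp(X.values[:, j], Y.values[:, j]).statistic
                for j in range(23)
            ])

        same, cross = ks_per_ct(A1, A2), ks_per_ct(A1, B1)
        assert np.median(cross) <= np.median(same) + 0.1
        # distributions are broad, not pinned
        assert A1.values.std(axis=0).mean() > 0.1


class TestDistances:
    def _layout(self, coords, chrom):
        return Layout3D(np.asarray(coords, float), np.arange(len(coords)),
                        np.asarray(chrom), seed=0)

    def _unit_fit(self, center=(0, 0, 0)):
        from radialct.network_ensemble import EllipsoidFit
        return EllipsoidFit(np.asarray(center, float), np.eye(3) / 100.0, 1e-3)

    def test_com_trivial_and_single_node(self):
        lay = self._layout([[0, 0, 0], [2, 0, 0], [5, 5, 5]],
                           ["chrA", "chrA", "chrB"])
        coms = chromosome_com(lay, ["chrA", "chrB"])
        assert np.allclose(coms[0], [1, 0, 0])
        assert np.allclose(coms[1], [5, 5, 5])

    def test_com_missing_chromosome_raises(self):
        lay = self._layout([[0, 0, 0]], ["chrA"])
        with pytest.raises(ValueError, match="chrB"):
            chromosome_com(lay, ["chrA", "chrB"])

    @pytest.mark.parametrize("seed", [0, 1])
    def test_com_matches_brute_force(self, seed):
        rng = np.random.default_rng(seed)
        coords = rng.normal(size=(30, 3))
        chrom = np.repeat(["chrA", "chrB", "chrC"], 10)
        lay = self._layout(coords, chrom)
        coms = chromosome_com(lay, ["chrA", "chrB", "chrC"])
        for k, c in enumerate(["chrA", "chrB", "chrC"]):
            assert np.allclose(coms[k], coords[chrom == c].mean(axis=0))

    def test_minmax_forced(self):
        # COMs at distances 2, 4, 6 from the center
        lay = self._layout([[2, 0, 0], [0, 4, 0], [0, 0, 6]],
                           ["chrA", "chrB", "chrC"])
        d = radial_distances(lay, self._unit_fit(), ["chrA", "chrB", "chrC"])
        assert np.allclose(d, [0, 0.5, 1.0])

    def test_central_ct_gets_zero(self):
        lay = self._layout([[0, 0, 0], [3, 0, 0]], ["chrA", "chrB"])
        d = radial_distances(lay, self._unit_fit(), ["chrA", "chrB"])
        assert d[0] == 0.0

    def test_equidistant_degenerate_warns(self):
        lay = self._layout([[1, 0, 0], [0, 1, 0]], ["chrA", "chrB"])
        with pytest.warns(UserWarning, match="equidistant"):
            d = radial_distances(lay, self._unit_fit(), ["chrA", "chrB"])
        assert np.allclose(d, 0.5)

    def test_distance_matrix_shape_and_rows(self):
        lay = self._layout([[2, 0, 0], [0, 4, 0]], ["chrA", "chrB"])
        fits = [self._unit_fit(), self._unit_fit()]
        D = build_distance_matrix([lay, lay], fits, ["chrA", "chrB"])
        assert D.values.shape == (2, 2)
        assert np.array_equal(D.values[0], D.values[1])
        assert D.values.min(axis=1).max() == 0.0
        assert D.values.max(axis=1).min() == 1.0

    def test_rotation_invariance(self):
        """Rigid rotation of a layout leaves radial distances unchanged
        (the MVE rotates with the points)."""
        rng = np.random.default_rng(3)
        coords = rng.normal(size=(40, 3)) * [2.0, 1.0, 0.7]
        chrom = np.repeat(["chrA", "chrB", "chrC", "chrD"], 10)
        lay = self._layout(coords, chrom)
        fit = fit_mve(coords)
        d0 = radial_distances(lay, fit, ["chrA", "chrB", "chrC", "chrD"])
        Q, _ = np.linalg.qr(rng.normal(size=(3, 3)))
        lay_r = self._layout(coords @ Q.T, chrom)
        fit_r = fit_mve(coords @ Q.T)
        d1 = radial_distances(lay_r, fit_r, ["chrA", "chrB", "chrC", "chrD"])
        assert np.allclose(d0, d1, atol=1e-4)
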