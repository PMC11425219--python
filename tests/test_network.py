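"""Construction of morphological similarity networks: smoothing, KDE, JSDs."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

import wm_morphnet as wm
from wm_morphnet.network import (
    DEFAULT_N_POINTS,
    discrete_frechet,
    silverman_bandwidth,
)
from wm_morphnet.types import DegenerateDensityError, RegionalDensity, VoxelMap


def _density(mass, grid=None):
    mass = np.asarray(mass, dtype=float)
    if grid is None:
        grid = np.arange(mass.size, dtype=float)
    return RegionalDensity(grid=grid, mass=mass)


# ---------------------------------------------------------------------------
# smoothing
# ---------------------------------------------------------------------------

class TestSmoothing:
    def test_zero_fwhm_is_identity(self):
        rng = np.random.default_rng(0)
        vmap = VoxelMap(rng.random((6, 7, 8)))
        out = wm.smooth_map(vmap, 0.0)
        np.testing.assert_array_equal(out.data, vmap.data)

    def test_negative_fwhm_rejected(self):
        with pytest.raises(ValueError):
            wm.smooth_map(VoxelMap(np.zeros((4, 4, 4))), -1.0)

    def test_impulse_matches_discrete_convolution_oracle(self):
        # FWHM = 2 sqrt(2 ln 2) mm on 1 mm voxels -> sigma = 1 voxel
        fwhm = 2.0 * np.sqrt(2.0 * np.log(2.0))
        data = np.zeros((17, 17, 17))
        data[8, 8, 8] = 1.0
        out = wm.smooth_map(VoxelMap(data), fwhm)
        # oracle: normalized discrete Gaussian kernel, truncated at 4 sigma
        i = np.arange(-4, 5)
        k1d = np.exp(-0.5 * i**2)
        k1d /= k1d.sum()
        peak = k1d[4] ** 3
        assert out.data[8, 8, 8] == pytest.approx(peak, rel=1e-10)

    def test_interior_mass_conserved(self):
        rng = np.random.default_rng(1)
        data = np.zeros((30, 30, 30))
        data[10:20, 10:20, 10:20] = rng.random((10, 10, 10))
        out = wm.smooth_map(VoxelMap(data), 4.0)
        assert out.data.sum() == pytest.approx(data.sum(), rel=1e-6)

    def test_shift_equivariance_on_interior(self):
        data = np.zeros((24, 24, 24))
        data[10, 10, 10] = 1.0
        shifted = np.roll(data, (2, 0, 0), axis=(0, 1, 2))
        a = wm.smooth_map(VoxelMap(data), 3.0).data
        b = wm.smooth_map(VoxelMap(shifted), 3.0).data
        np.testing.assert_allclose(np.roll(a, (2, 0, 0), axis=(0, 1, 2)), b, atol=1e-12)

    def test_anisotropic_voxels_scale_sigma(self):
        data = np.zeros((21, 21, 21))
        data[10, 10, 10] = 1.0
        iso = wm.smooth_map(VoxelMap(data, voxel_size=(1, 1, 1)), 4.0)
        coarse = wm.smooth_map(VoxelMap(data, voxel_size=(2, 2, 2)), 8.0)
        np.testing.assert_allclose(iso.data, coarse.data, atol=1e-12)


# ---------------------------------------------------------------------------
# density estimation
# ---------------------------------------------------------------------------

class TestEstimateDensity:
    def test_mass_sums_to_one(self):
        rng = np.random.default_rng(2)
        d = wm.estimate_density(rng.standard_normal(50))
        assert d.mass.sum() == pytest.approx(1.0, abs=1e-12)
        assert d.n_points == DEFAULT_N_POINTS

    def test_deterministic(self):
        vals = np.random.default_rng(3).standard_normal(40)
        a = wm.estimate_density(vals)
        b = wm.estimate_density(vals.copy())
        assert np.array_equal(a.grid, b.grid) and np.array_equal(a.mass, b.mass)

    def test_matches_kernel_sum_oracle(self):
        """Explicit double-loop Gaussian kernel sum reproduces the estimate."""
        vals = np.random.default_rng(4).standard_normal(100)
        d = wm.estimate_density(vals, n_points=64)
        n = vals.size
        bw = np.std(vals, ddof=1) * (3.0 * n / 4.0) ** (-0.2)
        raw = np.zeros(64)
        for gi, g in enumerate(d.grid):
            s = 0.0
            for x in vals:
                s += np.exp(-0.5 * ((g - x) / bw) ** 2)
            raw[gi] = s / (n * bw * np.sqrt(2 * np.pi))
        np.testing.assert_allclose(d.mass, raw / raw.sum(), atol=1e-10)

    def test_grid_spans_three_bandwidths(self):
        vals = np.random.default_rng(5).standard_normal(30)
        bw = silverman_bandwidth(vals)
        d = wm.estimate_density(vals)
        assert d.grid[0] == pytest.approx(vals.min() - 3 * bw)
        assert d.grid[-1] == pytest.approx(vals.max() + 3 * bw)

    @pytest.mark.parametrize(
        "values,err",
        [
            ([1.0], DegenerateDensityError),
            ([2.0, 2.0, 2.0], DegenerateDensityError),
        ],
    )
    def test_degenerate_inputs(self, values, err):
        with pytest.raises(err):
            wm.estimate_density(values)

    def test_too_few_grid_points(self):
        with pytest.raises(ValueError):
            wm.estimate_density([0.0, 1.0, 2.0], n_points=1)


# ---------------------------------------------------------------------------
# JSD / JSDs
# ---------------------------------------------------------------------------

class TestJSD:
    def test_identical_distributions(self):
        p = _density([0.25, 0.25, 0.5])
        assert wm.jsd(p, p) == 0.0
        assert wm.jsds(p, p) == 1.0

    def test_disjoint_support_maximal(self):
        p = _density([1.0, 0.0])
        q = _density([0.0, 1.0])
        assert wm.jsd(p, q) == pytest.approx(1.0)
        assert wm.jsds(p, q) == pytest.approx(0.0)

    def test_worked_value(self):
        """JSD((1/2,1/2) || (1,0)) by direct summation of the base-2 sums."""
        p = _density([0.5, 0.5])
        q = _density([1.0, 0.0])
        # M = (0.75, 0.25)
        expected = 0.5 * (
            0.5 * np.log2(0.5 / 0.75) + 0.5 * np.log2(0.5 / 0.25)
        ) + 0.5 * (1.0 * np.log2(1.0 / 0.75))
        assert expected == pytest.approx(0.311278, abs=1e-6)
        assert wm.jsd(p, q) == pytest.approx(expected, abs=1e-12)
        assert wm.jsds(p, q) == pytest.approx(1 - expected, abs=1e-12)

    def test_mismatched_grids_rejected(self):
        p = _density([0.5, 0.5], grid=np.array([0.0, 1.0]))
        q = _density([0.5, 0.5], grid=np.array([0.0, 2.0]))
        with pytest.raises(ValueError):
            wm.jsd(p, q)

    def test_symmetry_bounds_identity_on_random_pairs(self):
        """Symmetric, in [0,1], and 1 iff identical, over 1000 random pairs."""
        rng = np.random.default_rng(6)
        for _ in range(1000):
            n = rng.integers(2, 20)
            a = rng.random(n) + 1e-12
            b = rng.random(n) + 1e-12
            p = _density(a / a.sum(), grid=np.arange(n, dtype=float))
            q = _density(b / b.sum(), grid=np.arange(n, dtype=float))
            s_pq = wm.jsds(p, q)
            s_qp = wm.jsds(q, p)
            assert s_pq == pytest.approx(s_qp, abs=1e-12)
            assert 0.0 <= s_pq <= 1.0
            if not np.allclose(p.mass, q.mass):
                assert s_pq < 1.0

    @settings(deadline=None, max_examples=50, derandomize=True)
    @given(st.lists(st.floats(1e-6, 1.0), min_size=2, max_size=12))
    def test_self_similarity_always_one(self, weights):
        mass = np.array(weights) / np.sum(weights)
        p = _density(mass)
        assert wm.jsds(p, p) == 1.0


# ---------------------------------------------------------------------------
# build_network
# ---------------------------------------------------------------------------

class TestBuildNetwork:
    def test_edge_count_48_regions(self, full_atlas):
        maps = wm.simulate_subject_maps(full_atlas, 1, seed=0)
        net = wm.build_network(maps[0], full_atlas, n_points=32)
        assert net.n_regions == 48
        assert net.n_edges == 1128

    def test_duplicate_map_identical_networks(self, toy_atlas):
        maps = wm.simulate_subject_maps(toy_atlas, 1, seed=1)
        a = wm.build_network(maps[0], toy_atlas, n_points=64)
        b = wm.build_network(maps[0], toy_atlas, n_points=64)
        np.testing.assert_array_equal(a.matrix, b.matrix)

    def test_homotopic_exceeds_heterotopic(self, toy_atlas):
        """Mirrored-hemisphere generator: homotopic similarity dominates."""
        maps = wm.simulate_subject_maps(toy_atlas, 1, homotopic_coupling=0.8, seed=0)
        net = wm.build_network(maps[0], toy_atlas, n_points=64)
        idx = {rid: k for k, rid in enumerate(net.region_ids)}
        hom_pairs = {(idx[a], idx[b]) for a, b in toy_atlas.homotopic_pairs()}
        hom = [net.matrix[i, j] for i, j in hom_pairs]
        lateral = [idx[r.id] for r in toy_atlas.regions if r.hemisphere != "M"]
        het = [
            net.matrix[i, j]
            for ii, i in enumerate(lateral)
            for j in lateral[ii + 1 :]
            if (min(i, j), max(i, j)) not in hom_pairs
        ]
        assert np.mean(hom) > np.mean(het)

    def test_permutation_equivariance(self, toy_atlas):
        """Relabeling regions permutes similarity rows/columns identically."""
        from wm_morphnet.types import Atlas

        maps = wm.simulate_subject_maps(toy_atlas, 1, seed=2)
        net = wm.build_network(maps[0], toy_atlas, n_points=32)
        order = list(reversed(range(len(toy_atlas.regions))))
        shuffled = Atlas(
            labels=toy_atlas.labels,
            regions=[toy_atlas.regions[k] for k in order],
            voxel_size=toy_atlas.voxel_size,
        )
        net2 = wm.build_network(maps[0], shuffled, n_points=32)
        perm = np.array(order)
        np.testing.assert_allclose(
            net2.matrix, net.matrix[np.ix_(perm, perm)], atol=1e-12
        )

    def test_degenerate_region_lists_ids(self, toy_atlas):
        data = np.zeros(toy_atlas.labels.shape)
        bad_id = toy_atlas.region_ids[0]
        # every other region varies; region bad_id is constant
        rng = np.random.default_rng(3)
        for rid in toy_atlas.region_ids[1:]:
            sel = toy_atlas.labels == rid
            data[sel] = rng.standard_normal(int(sel.sum()))
        with pytest.raises(DegenerateDensityError, match=str(bad_id)):
            wm.build_network(VoxelMap(data), toy_atlas, n_points=32)


# ---------------------------------------------------------------------------
# Frechet diagnostic
# ---------------------------------------------------------------------------

def _frechet_bruteforce(a, b):
    """Exponential enumeration over all monotone couplings (tiny curves)."""
    import itertools

    na, nb = len(a), len(b)

    def dist(i, j):
        return float(np.linalg.norm(np.atleast_1d(a[i]) - np.atleast_1d(b[j])))

    best = np.inf
    # walks over the coupling lattice from (0,0) to (na-1, nb-1)
    frontier = {(0, 0): dist(0, 0)}
    while frontier:
        done = {}
        nxt = {}
        for (i, j), cost in frontier.items():
            if i == na - 1 and j == nb - 1:
                best = min(best, cost)
                continue
            for di, dj in ((1, 0), (0, 1), (1, 1)):
                ni, nj = i + di, j + dj
                if ni < na and nj < nb:
                    c = max(cost, dist(ni, nj))
                    if c < nxt.get((ni, nj), np.inf):
                        nxt[(ni, nj)] = c
        frontier = nxt
    return best


class TestFrechet:
    def test_identical_curves_zero(self):
        c = np.column_stack([np.arange(5.0), np.ones(5)])
        assert discrete_frechet(c, c) == 0.0

    def test_single_point_gap_matches_bruteforce(self):
        a = np.array([0.0, 0.0, 0.0, 0.0])
        b = np.array([0.0, 0.7, 0.0, 0.0])
        assert discrete_frechet(a, b) == pytest.approx(0.7)
        assert discrete_frechet(a, b) == pytest.approx(_frechet_bruteforce(a, b))

    def test_random_curves_match_bruteforce(self):
        rng = np.random.default_rng(8)
        for _ in range(20):
            a = rng.random((rng.integers(2, 6), 2))
            b = rng.random((rng.integers(2, 6), 2))
            assert discrete_frechet(a, b) == pytest.approx(
                _frechet_bruteforce(a, b), abs=1e-12
            )

    def test_distances_stabilize_with_more_points(self):
        """More sampling points -> more stable density curves on average."""
        vals = np.random.default_rng(9).standard_normal(400)
        d = wm.frechet_diagnostic(vals, [2**k for k in range(4, 11)])
        first, last = np.mean(d[:2]), np.mean(d[-2:])
        assert last < first

    def test_parameter_errors(self):
        with pytest.raises(ValueError):
            wm.frechet_diagnostic([0.0, 1.0, 2.0], [64])
        with pytest.raises(ValueError):
            wm.frechet_diagnostic([0.0, 1.0, 2.0], [64, 48])
        with pytest.raises(ValueError):
            wm.frechet_diagnostic([0.0, 1.0, 2.0], [60, 120])
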