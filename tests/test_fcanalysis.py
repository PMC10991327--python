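"""FC matrices, per-wave FC, superposition, spatial summaries, seeds, statistics."""

import numpy as np
import pandas as pd
import pytest

from conftest import make_component
from cortexwaves import fcanalysis, preprocess
from cortexwaves.fcanalysis import (
    FCError,
    FCMatrix,
    fc_matrix,
    fc_similarity_map,
    fc_superposition,
    group_fc_tests,
    hemispheric_difference_map,
    mean_fc_map,
    seed_fc,
    select_seeds,
    short_range_fc,
    wave_fc,
)
from cortexwaves.synthdata import simulate_waveform


def _matrix(values, rate=30.0, grid=None):
    values = np.asarray(values, float)
    n = values.shape[1]
    if grid is None:
        pix = np.stack([np.zeros(n, dtype=int), np.arange(n)], axis=1)
        grid_shape = (1, n)
    else:
        pix, grid_shape = grid
    return preprocess.TimeByPixelMatrix(
        values=values, pixel_index=pix, grid_shape=grid_shape, sampling_rate=rate,
    )


def _fc(values, labels=None):
    values = np.asarray(values, float)
    if labels is None:
        labels = np.arange(values.shape[0])
    return FCMatrix(values=values, node_index=np.asarray(labels))


class TestFcMatrix:
    def test_identical_and_negated_columns(self):
        x = np.random.default_rng(0).standard_normal(100)
        m = _matrix(np.stack([x, x, -x], axis=1))
        fc = fc_matrix(m)
        assert fc.values[0, 1] == pytest.approx(1.0)
        assert fc.values[0, 2] == pytest.approx(-1.0)

    def test_independent_noise_bound(self):
        vals = np.random.default_rng(1).standard_normal((10_000, 6))
        fc = fc_matrix(_matrix(vals))
        off = fc.upper_triangle()
        assert np.max(np.abs(off)) < 3 / np.sqrt(10_000)

    def test_zero_variance_rejected(self):
        vals = np.random.default_rng(0).standard_normal((50, 3))
        vals[:, 1] = 2.0
        with pytest.raises(FCError):
            fc_matrix(_matrix(vals))


class TestWaveFc:
    def test_standing_wave_all_ones(self):
        c = make_component(
            np.ones(8, complex), simulate_waveform(1.0, 0.1, 100, 30, seed=0)
        )
        fc = wave_fc(c)
        assert np.allclose(fc.values, 1.0, atol=1e-10)

    def test_cos_phase_difference_oracle(self):
        """For a long proper analytic score, C_Φ(j,k) ≈ cos(θ_j − θ_k)."""
        rng = np.random.default_rng(2)
        theta = rng.uniform(0, 2 * np.pi, 12)
        c = make_component(
            np.exp(1j * theta), simulate_waveform(1.0, 0.1, 100, 30, seed=3)
        )
        fc = wave_fc(c)
        oracle = np.cos(theta[:, None] - theta[None, :])
        assert np.max(np.abs(fc.values - oracle)) < 0.05

    def test_two_lobe_pi_offset_negative_across_lobes(self):
        theta = np.array([0.0] * 6 + [np.pi] * 6)
        c = make_component(
            np.exp(1j * theta), simulate_waveform(2.0, 0.1, 100, 30, seed=4)
        )
        fc = wave_fc(c)
        cross = fc.values[:6, 6:]
        within = fc.values[:6, :6]
        assert np.all(cross <= -0.9)
        assert np.all(within >= 0.9)

    def test_zero_amplitude_pixels_flagged_undefined(self):
        loading = np.array([1.0, 1.0, 0.0, 1.0], complex)
        c = make_component(loading, simulate_waveform(1.0, 0.1, 60, 30, seed=5))
        fc = wave_fc(c)
        assert fc.undefined is not None and fc.undefined[2]
        assert np.isnan(fc.values[2, 0]) and np.isnan(fc.values[0, 2])
        assert fc.values[2, 2] == 1.0


class TestSuperposition:
    def test_single_standing_dominated_first_term_nearly_constant(self, small_run):
        d = small_run["decomposition"]
        sup, _ = fc_superposition(d, 1)
        vals = sup.upper_triangle()
        assert vals.min() > 0.5  # near-constant, all-positive matrix

    def test_similarity_increases_with_waves(self, small_run):
        d = small_run["decomposition"]
        _, curve = fc_superposition(d, len(d), reference=small_run["fc"])
        assert curve[-1] > curve[0]
        assert curve[2] > 0.9  # three true waves capture the FC structure

    def test_bounds_checked(self, small_run):
        with pytest.raises(FCError):
            fc_superposition(small_run["decomposition"], 0)


class TestSpatialSummaries:
    def test_mean_fc_map_trivial_cases(self):
        ones = _fc(np.ones((4, 4)))
        assert np.allclose(mean_fc_map(ones), 1.0)
        block = np.block([[np.ones((3, 3)), -np.ones((3, 3))],
                          [-np.ones((3, 3)), np.ones((3, 3))]])
        fc = _fc(block)
        assert np.allclose(mean_fc_map(fc, absolute=True), 1.0)
        assert np.max(np.abs(mean_fc_map(fc, absolute=False))) < 0.3

    def test_mean_fc_tracks_dominant_amplitude(self, small_run):
        """The unsigned mean-FC map echoes the dominant standing wave's
        amplitude distribution."""
        fc = small_run["fc"]
        rho0 = small_run["decomposition"][0].rho
        dmap = mean_fc_map(fc, absolute=False)
        assert np.corrcoef(dmap, rho0)[0, 1] > 0.8

    def test_hemispheric_difference_uniform_coupling_is_zero(self):
        """When every pixel pair couples identically, homolateral and
        contralateral mean |FC| agree and the difference map vanishes."""
        n = 8
        vals = 0.4 * np.ones((n, n)) + 0.6 * np.eye(n)
        fc = _fc(vals)
        fc.node_index = np.stack([np.zeros(n, int), np.arange(n)], axis=1)
        dmap = hemispheric_difference_map(fc, midline_column=n // 2)
        assert np.allclose(dmap, 0.0, atol=1e-12)

    def test_hemisphere_specific_waves_positive_map(self):
        """Each hemisphere carrying its own wave couples pixels more strongly
        within than across the midline: homolateral − contralateral > 0."""
        x = np.real(simulate_waveform(1.0, 0.1, 100, 30, seed=6))
        y = np.real(simulate_waveform(3.0, 0.1, 100, 30, seed=16))
        rng = np.random.default_rng(7)
        n_side = 5
        vals = np.concatenate(
            [
                x[:, None] + 0.3 * rng.standard_normal((x.size, n_side)),
                y[:, None] + 0.3 * rng.standard_normal((y.size, n_side)),
            ],
            axis=1,
        )
        pix = np.stack([np.zeros(2 * n_side, int), np.arange(2 * n_side)], axis=1)
        fc = fc_matrix(_matrix(vals, grid=(pix, (1, 2 * n_side))))
        dmap = hemispheric_difference_map(fc, midline_column=n_side)
        assert np.all(dmap > 0)

    def test_single_hemisphere_errors(self):
        fc = _fc(np.eye(4))
        fc.node_index = np.stack([np.zeros(4, int), np.arange(4)], axis=1)
        with pytest.raises(FCError):
            hemispheric_difference_map(fc, midline_column=0)

    def test_fc_similarity_identity_affine_shuffle(self):
        rng = np.random.default_rng(8)
        a = np.corrcoef(rng.standard_normal((60, 10)).T)
        fa = _fc(a)
        assert np.allclose(fc_similarity_map(fa, fa), 1.0)
        b = 0.5 * a + 0.2
        np.fill_diagonal(b, 1.0)
        assert np.allclose(fc_similarity_map(fa, _fc(b)), 1.0, atol=1e-10)
        perm = rng.permutation(10)
        shuffled = a[perm][:, perm]
        sim = fc_similarity_map(fa, _fc(shuffled))
        assert abs(np.mean(sim)) < 0.4

    def test_similarity_requires_same_nodes(self):
        fa = _fc(np.eye(4))
        fb = _fc(np.eye(5))
        with pytest.raises(FCError):
            fc_similarity_map(fa, fb)


class TestSeeds:
    @staticmethod
    def _two_block_matrix(n_time=400, seed=0):
        rng = np.random.default_rng(seed)
        a = np.real(simulate_waveform(0.5, 0.1, n_time / 30, 30, seed))
        b = np.real(simulate_waveform(3.0, 0.1, n_time / 30, 30, seed + 1))
        vals = np.concatenate(
            [
                a[:, None] + 0.2 * rng.standard_normal((a.size, 5)),
                b[:, None] + 0.2 * rng.standard_normal((b.size, 5)),
            ],
            axis=1,
        )
        pix = np.stack([np.zeros(10, int), np.arange(10)], axis=1)
        return _matrix(vals, grid=(pix, (1, 10)))

    def test_two_block_fc_selects_k2_with_seed_per_block(self):
        m = self._two_block_matrix()
        fc = fc_matrix(m)
        ss = select_seeds(fc, k_range=range(2, 6), seed=0)
        assert ss.k == 2
        cols = sorted(c for _, (_, c) in ss.seeds)
        assert cols[0] < 5 <= cols[1]
        labels = ss.cluster_assignment
        assert len(set(labels[:5])) == 1 and len(set(labels[5:])) == 1

    def test_deterministic(self):
        fc = fc_matrix(self._two_block_matrix())
        s1 = select_seeds(fc, k_range=range(2, 6), seed=3)
        s2 = select_seeds(fc, k_range=range(2, 6), seed=3)
        assert s1.seeds == s2.seeds
        assert np.array_equal(s1.cluster_assignment, s2.cluster_assignment)

    def test_constant_fc_degenerate_warns(self):
        fc = _fc(np.ones((6, 6)))
        fc.node_index = np.stack([np.zeros(6, int), np.arange(6)], axis=1)
        with pytest.warns(UserWarning, match="degenerate"):
            ss = select_seeds(fc)
        assert ss.k == 2

    def test_seed_fc_and_maps(self):
        m = self._two_block_matrix()
        fc = fc_matrix(m)
        ss = select_seeds(fc, k_range=range(2, 6), seed=0)
        sfc, maps = seed_fc(m, ss)
        assert sfc.values.shape == (2, 2)
        assert np.allclose(np.diag(sfc.values), 1.0)
        assert maps.shape == (2, 10)
        # each seed map is high over its own block
        for j, (_, (_, col)) in enumerate(ss.seeds):
            own = maps[j, :5] if col < 5 else maps[j, 5:]
            assert own.mean() > 0.8

    def test_single_seed(self):
        m = self._two_block_matrix()
        ss = fcanalysis.SeedSet(
            seeds=[("s", (0, 0))], cluster_assignment=np.zeros(10, int), k=1
        )
        sfc, maps = seed_fc(m, ss)
        assert sfc.values.shape == (1, 1) and sfc.values[0, 0] == 1.0

    def test_seed_outside_mask_errors(self):
        m = self._two_block_matrix()
        ss = fcanalysis.SeedSet(
            seeds=[("bad", (5, 5))], cluster_assignment=np.zeros(10, int), k=1
        )
        with pytest.raises(FCError):
            seed_fc(m, ss)


class TestShortRange:
    @staticmethod
    def _grid_matrix(vals_fn, shape=(5, 5), n_time=500, seed=0):
        rng = np.random.default_rng(seed)
        mask = np.ones(shape, bool)
        movie = vals_fn(rng, n_time, shape)
        return preprocess.flatten_movie(movie, mask, 30.0)

    def test_constant_region_gives_one(self):
        x = np.random.default_rng(0).standard_normal(500)
        m = self._grid_matrix(lambda rng, n, s: np.tile(x[:, None, None], (1, *s)))
        ss = fcanalysis.SeedSet(
            seeds=[("c", (2, 2))], cluster_assignment=np.zeros(25, int), k=1
        )
        out = short_range_fc(m, ss)
        assert out.short_range_fc.iloc[0] == pytest.approx(1.0)
        assert out.n_neighbors.iloc[0] == 8

    def test_independent_noise_bounded(self):
        m = self._grid_matrix(
            lambda rng, n, s: rng.standard_normal((10_000, *s)), n_time=10_000
        )
        ss = fcanalysis.SeedSet(
            seeds=[("c", (2, 2))], cluster_assignment=np.zeros(25, int), k=1
        )
        val = short_range_fc(m, ss).short_range_fc.iloc[0]
        assert abs(val) < 3 / np.sqrt(10_000) * np.sqrt(8)

    def test_corner_seed_uses_in_mask_neighbors_only(self):
        m = self._grid_matrix(lambda rng, n, s: rng.standard_normal((200, *s)))
        ss = fcanalysis.SeedSet(
            seeds=[("corner", (0, 0))], cluster_assignment=np.zeros(25, int), k=1
        )
        out = short_range_fc(m, ss)
        assert out.n_neighbors.iloc[0] == 3

    def test_isolated_seed_flagged(self):
        mask = np.zeros((5, 5), bool)
        mask[0, 0] = mask[4, 4] = True
        movie = np.random.default_rng(0).standard_normal((100, 5, 5))
        m = preprocess.flatten_movie(movie, mask, 30.0)
        ss = fcanalysis.SeedSet(
            seeds=[("iso", (0, 0))], cluster_assignment=np.zeros(2, int), k=1
        )
        out = short_range_fc(m, ss)
        assert np.isnan(out.short_range_fc.iloc[0])
        assert out.flag.iloc[0] == "isolated seed"


class TestGroupTests:
    @staticmethod
    def _noise_fc(rng, n_time=120, n_nodes=8):
        vals = rng.standard_normal((n_time, n_nodes))
        return _fc(np.corrcoef(vals.T))

    def test_identical_matrices_all_significant_flagged(self):
        rng = np.random.default_rng(0)
        base = self._noise_fc(rng)
        table = group_fc_tests([base, base, base, base])
        assert table.significant.all()
        assert (table.flag == "zero-variance edge: infinite statistic").all()
        assert np.isinf(table.statistic).all()

    def test_null_false_positive_rate_controlled(self):
        rng = np.random.default_rng(1)
        fracs = []
        for _ in range(50):
            group = [self._noise_fc(rng) for _ in range(15)]
            fracs.append(group_fc_tests(group).significant.mean())
        assert np.mean(fracs) <= 0.05

    def test_two_group_difference_localized(self):
        """Two groups differing in one wave's strength show significant edges
        where that wave's correlation structure lives."""
        rng = np.random.default_rng(2)
        x = np.real(simulate_waveform(1.0, 0.1, 40, 30, seed=9))

        def group(strength, n=8):
            out = []
            for _ in range(n):
                noise = rng.standard_normal((x.size, 6))
                vals = noise.copy()
                vals[:, :3] += strength * x[:, None]  # wave covers nodes 0-2
                out.append(_fc(np.corrcoef(vals.T)))
            return out

        table = group_fc_tests(group(2.0), group(0.0))
        inside = table[(table.node_i < 3) & (table.node_j < 3)]
        outside = table[(table.node_i >= 3) & (table.node_j >= 3)]
        assert inside.significant.all()
        assert not outside.significant.any()

    def test_group_size_validated(self):
        rng = np.random.default_rng(0)
        with pytest.raises(FCError):
            group_fc_tests([self._noise_fc(rng)] * 2)
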