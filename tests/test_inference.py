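"""Voxelwise correlation, TFCE and permutation FWE inference."""

import numpy as np
import pytest
from scipy import ndimage, stats

import somasearch as ss
from somasearch.errors import AlignmentError, DegenerateCovariateError
from somasearch.inference import T_CAP, _tstats


def all_true_grid(n):
    return ss.VolumeGrid(shape=(n, n, n), mask=np.ones((n, n, n), dtype=bool))


class TestVoxelwiseCorrelation:
    def test_perfect_positive_capped(self):
        grid = all_true_grid(3)
        maps = [np.full(grid.shape, v) for v in (1.0, 2.0, 3.0)]
        t = ss.voxelwise_correlation(maps, np.array([2.0, 4.0, 6.0]), grid)
        assert np.all(t[grid.mask] == T_CAP)

    def test_perfect_negative_capped(self):
        grid = all_true_grid(3)
        maps = [np.full(grid.shape, v) for v in (1.0, 2.0, 3.0)]
        t = ss.voxelwise_correlation(maps, np.array([6.0, 4.0, 2.0]), grid)
        assert np.all(t[grid.mask] == -T_CAP)

    def test_matches_linregress(self):
        """The vectorised slope t equals scipy's per-voxel regression t."""
        grid = all_true_grid(4)
        rng = np.random.default_rng(0)
        maps = [rng.standard_normal(grid.shape) for _ in range(12)]
        trait = rng.normal(size=12)
        t = ss.voxelwise_correlation(maps, trait, grid)
        stack = np.stack([m for m in maps])
        for idx in [(0, 0, 0), (1, 2, 3), (3, 3, 3)]:
            y = stack[(slice(None), *idx)]
            lr = stats.linregress(trait - trait.mean(), y)
            t_ref = lr.slope / lr.stderr
            assert t[idx] == pytest.approx(t_ref, rel=1e-10)

    def test_null_r_spread(self):
        """With 70 subjects and no coupling, per-voxel r has sd ~ 1/sqrt(n-1)."""
        n = 70
        grid = all_true_grid(10)
        rng = np.random.default_rng(1)
        maps = [rng.standard_normal(grid.shape) for _ in range(n)]
        trait = rng.normal(size=n)
        t = ss.voxelwise_correlation(maps, trait, grid)[grid.mask]
        r = t / np.sqrt(n - 2 + t**2)
        assert abs(r.std() - 1 / np.sqrt(n - 1)) < 0.02
        assert abs(r.mean()) < 0.02

    def test_zero_variance_voxels_get_zero(self):
        grid = all_true_grid(3)
        maps = [np.zeros(grid.shape) for _ in range(5)]
        t = ss.voxelwise_correlation(maps, np.arange(5.0), grid)
        assert np.all(t[grid.mask] == 0.0)

    def test_constant_trait_rejected(self):
        grid = all_true_grid(3)
        maps = [np.zeros(grid.shape) for _ in range(5)]
        with pytest.raises(DegenerateCovariateError):
            ss.voxelwise_correlation(maps, np.ones(5), grid)


class TestTFCE:
    def test_all_zero_map(self):
        grid = all_true_grid(6)
        out = ss.tfce_enhance(np.zeros(grid.shape), ss.TFCEParams(), grid.mask)
        assert np.all(out == 0)

    def test_single_voxel_closed_form(self):
        """Isolated voxel of height v: TFCE -> v^3/3 (E=0.5, H=2)."""
        grid = all_true_grid(7)
        v = 2.0
        vol = np.zeros(grid.shape)
        vol[3, 3, 3] = v
        out = ss.tfce_enhance(vol, ss.TFCEParams(dh=v / 1000), grid.mask)
        assert out[3, 3, 3] == pytest.approx(v**3 / 3, rel=0.01)
        assert np.count_nonzero(out) == 1

    def test_two_voxel_closed_form(self):
        """Two adjacent voxels at height v: extent 2 throughout, so each
        gets sqrt(2)·v^3/3."""
        grid = all_true_grid(7)
        v = 1.5
        vol = np.zeros(grid.shape)
        vol[3, 3, 3] = v
        vol[3, 3, 4] = v
        out = ss.tfce_enhance(vol, ss.TFCEParams(dh=v / 1000), grid.mask)
        expect = np.sqrt(2) * v**3 / 3
        assert out[3, 3, 3] == pytest.approx(expect, rel=0.01)
        assert out[3, 3, 4] == pytest.approx(expect, rel=0.01)

    def test_negative_values_not_enhanced(self):
        grid = all_true_grid(5)
        vol = -np.ones(grid.shape)
        out = ss.tfce_enhance(vol, ss.TFCEParams(), grid.mask)
        assert np.all(out == 0)

    def test_monotonicity(self):
        """Pointwise-increasing a statistic map never decreases TFCE."""
        grid = all_true_grid(8)
        rng = np.random.default_rng(2)
        params = ss.TFCEParams(dh=0.05)
        for _ in range(100):
            a = rng.standard_normal(grid.shape)
            b = a + rng.uniform(0, 0.5, grid.shape)  # b >= a pointwise
            ta = ss.tfce_enhance(a, params, grid.mask)
            tb = ss.tfce_enhance(b, params, grid.mask)
            assert np.all(tb >= ta - 1e-12)

    def test_step_halving_convergence(self):
        """TFCE at dh and dh/2 agree to O(dh) on a smooth map."""
        grid = all_true_grid(10)
        ii, jj, kk = np.meshgrid(*[np.arange(10)] * 3, indexing="ij")
        smooth = np.exp(-((ii - 5) ** 2 + (jj - 5) ** 2 + (kk - 5) ** 2) / 18.0)
        t1 = ss.tfce_enhance(smooth, ss.TFCEParams(dh=0.02), grid.mask)
        t2 = ss.tfce_enhance(smooth, ss.TFCEParams(dh=0.01), grid.mask)
        denom = np.maximum(t2.max(), 1e-12)
        assert np.max(np.abs(t1 - t2)) / denom < 0.05

    def test_connectivity_matters(self):
        """Diagonal neighbours join a component under 26- but not
        6-connectivity."""
        grid = all_true_grid(5)
        vol = np.zeros(grid.shape)
        vol[2, 2, 2] = 1.0
        vol[3, 3, 3] = 1.0
        t26 = ss.tfce_enhance(vol, ss.TFCEParams(dh=0.001, connectivity=26), grid.mask)
        t6 = ss.tfce_enhance(vol, ss.TFCEParams(dh=0.001, connectivity=6), grid.mask)
        assert t26[2, 2, 2] > t6[2, 2, 2]


class TestPermutationFWE:
    def _noise_setup(self, n_sub=8, n=6, seed=3):
        grid = all_true_grid(n)
        rng = np.random.default_rng(seed)
        maps = [rng.standard_normal(grid.shape) for _ in range(n_sub)]
        trait = rng.normal(size=n_sub)
        return grid, maps, trait

    def test_inv_p_bounded_by_plus_one_convention(self):
        grid, maps, trait = self._noise_setup()
        res = ss.permutation_fwe(maps, trait, grid, n_perm=99, seed=4)
        v = res.fwe_inv_p[grid.mask]
        assert np.nanmax(v) <= 99 / 100 + 1e-12
        assert np.nanmin(v) >= 0

    def test_subject_relabeling_invariance(self):
        """Consistently reordering subjects in maps and trait leaves the
        p-value maps unchanged."""
        grid, maps, trait = self._noise_setup()
        res = ss.permutation_fwe(maps, trait, grid, n_perm=64, seed=5)
        order = np.random.default_rng(6).permutation(len(trait))
        res2 = ss.permutation_fwe(
            [maps[i] for i in order], trait[order], grid, n_perm=64, seed=5
        )
        assert np.allclose(
            res.fwe_inv_p[grid.mask], res2.fwe_inv_p[grid.mask], equal_nan=True
        )

    def test_seed_determinism(self):
        grid, maps, trait = self._noise_setup()
        a = ss.permutation_fwe(maps, trait, grid, n_perm=50, seed=7)
        b = ss.permutation_fwe(maps, trait, grid, n_perm=50, seed=7)
        c = ss.permutation_fwe(maps, trait, grid, n_perm=50, seed=8)
        assert np.array_equal(a.fwe_inv_p, b.fwe_inv_p, equal_nan=True)
        assert not np.array_equal(a.fwe_inv_p, c.fwe_inv_p, equal_nan=True)

    def test_exhaustive_matches_fisher_pitman_oracle(self):
        """With n_perm >= n!, the permutation p equals an independently
        coded exact Fisher-Pitman enumeration."""
        from itertools import permutations

        n_sub = 5
        grid = all_true_grid(4)
        rng = np.random.default_rng(9)
        maps = [rng.standard_normal(grid.shape) for _ in range(n_sub)]
        trait = rng.normal(size=n_sub)
        params = ss.TFCEParams(dh=0.1)
        with pytest.warns(UserWarning, match="enumerating"):
            res = ss.permutation_fwe(maps, trait, grid, params=params, n_perm=200, seed=0)
        assert res.n_perm == 120

        # independent oracle: per-voxel regression t via scipy, TFCE via a
        # direct reimplementation, exact tail over all 120 permutations
        stack = np.stack(maps)
        x0 = trait - trait.mean()

        def tmap(x):
            out = np.zeros(grid.shape)
            for idx in np.ndindex(grid.shape):
                y = stack[(slice(None), *idx)]
                if np.ptp(y) == 0:
                    continue
                lr = stats.linregress(x, y)
                out[idx] = lr.slope / lr.stderr
            return np.clip(out, -T_CAP, T_CAP)

        def tfce(vol):
            pos = np.clip(vol, 0, None)
            out = np.zeros_like(pos)
            h = 0.1
            struct = ndimage.generate_binary_structure(3, 3)
            while h <= pos.max():
                lab, nlab = ndimage.label(pos >= h, structure=struct)
                for l in range(1, nlab + 1):
                    sel = lab == l
                    out[sel] += np.sqrt(sel.sum()) * h * h * 0.1
                h += 0.1
            return out

        obs = tfce(tmap(x0))
        maxima = [tfce(tmap(np.asarray(p))).max() for p in permutations(x0)]
        p_oracle = np.array([
            np.mean([m >= obs[idx] for m in maxima]) for idx in np.ndindex(grid.shape)
        ]).reshape(grid.shape)
        assert np.allclose(1.0 - res.fwe_inv_p, p_oracle, atol=1e-10)

    def test_observed_signal_found_and_negative_null(self):
        """A map component proportional to the trait is flagged by the
        positive direction and not by the negative one."""
        grid = all_true_grid(8)
        rng = np.random.default_rng(10)
        n_sub = 14
        trait = rng.normal(size=n_sub)
        maps = []
        for i in range(n_sub):
            vol = 0.3 * rng.standard_normal(grid.shape)
            vol[3:6, 3:6, 3:6] += trait[i]  # strong positive coupling
            maps.append(vol)
        pos = ss.permutation_fwe(maps, trait, grid, n_perm=199, seed=11, direction="positive")
        neg = ss.permutation_fwe(maps, trait, grid, n_perm=199, seed=11, direction="negative")
        assert pos.fwe_inv_p[4, 4, 4] > 0.95
        assert np.nanmax(neg.fwe_inv_p[grid.mask]) <= 0.95


class TestRunEmpathyCorrelations:
    def _tiny_dissim(self, n_sub=6, seed=12):
        grid = all_true_grid(5)
        rng = np.random.default_rng(seed)
        traits = ss.generate_traits(n_sub, seed=seed)
        dissim = {
            contrast: [
                ss.DissimilarityMap(sid, contrast, rng.uniform(0, 2, grid.shape), grid)
                for sid in traits.subject_ids
            ]
            for contrast in ss.CONTRASTS
        }
        return grid, dissim, traits

    def test_24_results(self):
        grid, dissim, traits = self._tiny_dissim()
        res = ss.run_empathy_correlations(dissim, traits, grid, n_perm=20, seed=13)
        assert len(res) == 24
        assert sum(1 for k in res if k[2] == "positive") == 12
        for key, r in res.items():
            assert r.contrast == key[0] and r.subscale == key[1] and r.direction == key[2]

    def test_alignment_error(self):
        grid, dissim, traits = self._tiny_dissim()
        other = ss.generate_traits(6, seed=99)
        renamed = other.table.assign(subject_id=[f"x{i}" for i in range(6)])
        with pytest.raises(AlignmentError):
            ss.run_empathy_correlations(
                dissim, ss.TraitScores(renamed), grid, n_perm=5, seed=0
            )

    def test_constant_traits_rejected(self):
        grid, dissim, traits = self._tiny_dissim()
        const = traits.table.copy()
        for s in ss.SUBSCALES:
            const[s] = 10.0
        with pytest.raises(DegenerateCovariateError):
            ss.run_empathy_correlations(dissim, ss.TraitScores(const), grid, n_perm=5, seed=0)
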