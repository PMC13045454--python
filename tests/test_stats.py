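import numpy as np
import pytest
from scipy import sparse
from scipy.sparse.csgraph import connected_components

from pulseflow.stats import (
    directional_reversal_map,
    paired_permutation_test,
    power_delta_regression,
    spatial_correlation,
    tfce_enhance,
)


def brute_force_tfce(stat, h_power, e_power, dh):
    """Independent TFCE: cluster membership via sparse-graph connected
    components (26-neighbourhood) at every threshold."""
    shape = stat.shape
    n = stat.size
    idx = np.arange(n).reshape(shape)
    edges = []
    for dx in (-1, 0, 1):
        for dy in (-1, 0, 1):
            for dz in (-1, 0, 1):
                if (dx, dy, dz) <= (0, 0, 0):
                    continue
                src = idx[
                    max(0, -dx) : shape[0] - max(0, dx),
                    max(0, -dy) : shape[1] - max(0, dy),
                    max(0, -dz) : shape[2] - max(0, dz),
                ].ravel()
                dst = idx[
                    max(0, dx) :shape[0] - max(0, -dx),
                    max(0, dy) :shape[1] - max(0, -dy),
                    max(0, dz) :shape[2] - max(0, -dz),
                ].ravel()
                edges.append((src, dst))
    src = np.concatenate([e[0] for e in edges])
    dst = np.concatenate([e[1] for e in edges])

    flat = stat.ravel()
    out = np.zeros(n)
    h = dh
    while h <= flat.max() + 1e-12:
        above = flat >= h
        keep = above[src] & above[dst]
        graph = sparse.coo_matrix(
            (np.ones(keep.sum()), (src[keep], dst[keep])), shape=(n, n)
        )
        n_comp, labels = connected_components(graph, directed=False)
        sizes = np.bincount(labels, weights=above.astype(float))
        # clusters containing no supra-threshold voxel are irrelevant
        contrib = np.where(above, sizes[labels] ** e_power * h**h_power * dh, 0.0)
        out += contrib
        h += dh
    return out.reshape(shape)


class TestTfce:
    def test_zero_map_maps_to_zero(self):
        assert np.all(tfce_enhance(np.zeros((5, 5, 5))) == 0)

    def test_extent_rewards_cluster_membership(self):
        stat = np.zeros((8, 8, 8))
        stat[1:3, 1:6, 1] = 1.0  # 10-voxel plateau
        stat[6, 6, 6] = 1.0  # isolated voxel of the same height
        out = tfce_enhance(stat, dh=0.1)
        assert out[1, 1, 1] > out[6, 6, 6]

    def test_uniform_cluster_closed_form(self):
        stat = np.zeros((8, 8, 8))
        stat[2:4, 2:4, 2:4] = 2.0  # k = 8 voxels at height 2
        h_power, e_power, dh = 2.0, 0.5, 0.002
        out = tfce_enhance(stat, h_power, e_power, dh)
        expected = 8**e_power * 2.0 ** (h_power + 1) / (h_power + 1)
        assert out[2, 2, 2] == pytest.approx(expected, rel=0.01)

    def test_matches_bruteforce_oracle(self, rng):
        stat = np.clip(rng.normal(0.5, 0.5, size=(12, 12, 12)), 0, None)
        ours = tfce_enhance(stat, dh=stat.max() / 40)
        oracle = brute_force_tfce(stat, 2.0, 0.5, stat.max() / 40)
        assert np.allclose(ours, oracle, rtol=1e-9, atol=1e-12)

    def test_monotone_in_voxel_height(self, rng):
        stat = np.clip(rng.normal(0.5, 0.3, size=(8, 8, 8)), 0, None)
        base = tfce_enhance(stat, dh=0.02)
        bumped = stat.copy()
        bumped[4, 4, 4] += 0.5
        out = tfce_enhance(bumped, dh=0.02)
        assert np.all(out >= base - 1e-9)

    def test_rejects_negative_input_and_dh(self):
        with pytest.raises(ValueError, match="non-negative"):
            tfce_enhance(np.array([[[-1.0]]]))
        with pytest.raises(ValueError, match="dh"):
            tfce_enhance(np.ones((3, 3, 3)), dh=-0.1)


class TestPairedPermutation:
    def test_identical_conditions_never_significant(self, rng):
        a = rng.normal(size=(8, 6, 6, 6))
        res = paired_permutation_test(a, a.copy(), n_perm=200, seed=0, use_tfce=False)
        assert not res.sig_mask.any()

    def test_detects_strong_focal_effect_without_false_positives(self, rng):
        n = 12
        shape = (10, 10, 10)
        roi = np.zeros(shape, bool)
        roi[2:7, 2:6, 2:7] = True  # 100 voxels
        noise_a = rng.normal(size=(n,) + shape)
        noise_b = rng.normal(size=(n,) + shape)
        b = noise_b + 3.0 * roi  # effect = 3 x noise SD
        res = paired_permutation_test(
            b, noise_a, n_perm=1000, alpha=0.05, use_tfce=True, seed=1
        )
        assert res.sig_mask[roi].mean() >= 0.9
        # cluster enhancement may bleed one voxel across the ROI edge;
        # beyond that, no false positives
        from scipy import ndimage

        near = ndimage.binary_dilation(roi, ndimage.generate_binary_structure(3, 3))
        assert res.sig_mask[~near].sum() == 0

    def test_exhaustive_enumeration_when_feasible(self, rng):
        a = rng.normal(size=(6, 4, 4, 4))
        b = rng.normal(size=(6, 4, 4, 4))
        res = paired_permutation_test(a, b, n_perm=100, seed=0, use_tfce=False)
        assert res.exhaustive and res.n_permutations == 64

    def test_swap_symmetry(self, rng):
        a = rng.normal(size=(7, 5, 5, 5))
        b = rng.normal(size=(7, 5, 5, 5))
        r1 = paired_permutation_test(a, b, n_perm=64, seed=3, use_tfce=False)
        r2 = paired_permutation_test(b, a, n_perm=64, seed=3, use_tfce=False)
        assert np.allclose(r1.stat_map, -r2.stat_map)
        assert np.allclose(r1.p_corr_map, r2.p_corr_map)

    def test_input_validation(self, rng):
        a = rng.normal(size=(6, 4, 4, 4))
        with pytest.raises(ValueError, match="unpaired"):
            paired_permutation_test(a, a[:, :3])
        with pytest.raises(ValueError, match=">= 5"):
            paired_permutation_test(a[:3], a[:3])


class TestReversal:
    def _unit_field(self, rng, n, shape, axis=0):
        d = np.zeros((n,) + shape + (3,))
        d[..., axis] = 1.0
        return d + 0.02 * rng.normal(size=d.shape)

    def test_full_reversal_flagged_everywhere(self, rng):
        shape = (6, 6, 6)
        a = self._unit_field(rng, 8, shape)
        rev = directional_reversal_map(a, -a, n_perm=256, seed=0, use_tfce=False)
        assert rev.reversal.mean() > 0.95

    def test_identical_directions_empty(self, rng):
        a = self._unit_field(rng, 8, (6, 6, 6))
        rev = directional_reversal_map(a, a.copy(), n_perm=256, seed=0, use_tfce=False)
        assert not rev.reversal.any()

    def test_reversal_confined_to_flipped_region(self, rng):
        shape = (10, 10, 10)
        roi = np.zeros(shape, bool)
        roi[3:7, 3:7, 3:7] = True
        a = self._unit_field(rng, 10, shape, axis=0)
        b = a.copy()
        b[..., 0] = np.where(roi, -a[..., 0], a[..., 0])
        rev = directional_reversal_map(a, b, n_perm=500, seed=2, use_tfce=False)
        assert rev.reversal[roi].mean() > 0.9
        from scipy import ndimage

        near_roi = ndimage.binary_dilation(roi, iterations=1)
        assert rev.reversal[~near_roi].sum() == 0
        # the flip was along x only
        assert rev.per_component[0].any()
        assert not rev.per_component[1].any()


class TestCorrelations:
    def test_self_correlation(self, rng):
        m = rng.normal(size=(8, 8, 8))
        assert spatial_correlation(m, m) == pytest.approx(1.0)
        assert spatial_correlation(m, -m) == pytest.approx(-1.0)

    def test_constructed_correlation_recovered(self, rng):
        z = rng.normal(size=(22, 22, 22))
        eps = rng.normal(size=z.shape)
        b = 0.35 * z + np.sqrt(1 - 0.35**2) * eps
        assert spatial_correlation(z, b) == pytest.approx(0.35, abs=0.03)

    def test_zero_variance_rejected(self):
        with pytest.raises(ValueError, match="variance"):
            spatial_correlation(np.ones((4, 4, 4)), np.random.rand(4, 4, 4))

    def test_mask_restriction(self, rng):
        a = rng.normal(size=(6, 6, 6))
        b = a.copy()
        b[0] = -a[0]  # corrupt voxels outside the mask
        mask = np.ones((6, 6, 6), bool)
        mask[0] = False
        assert spatial_correlation(a, b, mask) == pytest.approx(1.0)


class TestPowerDeltaRegression:
    def test_collinear_points(self):
        x = np.linspace(0, 1, 10)
        r, slope, excluded = power_delta_regression(2 * x + 1, x)
        assert r == pytest.approx(1.0)
        assert slope == pytest.approx(2.0)
        assert excluded == []

    def test_five_sigma_outlier_excluded(self, rng):
        x = rng.normal(size=40)
        y = 0.5 * x + 0.1 * rng.normal(size=40)
        x[7] = x.std() * 8  # ends up > 4 sigma from the mean
        r, slope, excluded = power_delta_regression(y, x, sigma_threshold=4.0)
        assert 7 in excluded

    def test_requires_four_subjects(self):
        with pytest.raises(ValueError):
            power_delta_regression(np.ones(3), np.ones(3))

    def test_recovers_coupling_signs(self):
        from pulseflow.synthetic import draw_power_covariates

        rng = np.random.default_rng(11)
        cov = draw_power_covariates(22, {"vasomotor": 0.5, "cardiac": -0.5}, rng)
        r_v, _, _ = power_delta_regression(cov["vasomotor"], cov["log_delta"])
        r_c, _, _ = power_delta_regression(cov["cardiac"], cov["log_delta"])
        assert r_v > 0 and r_c < 0
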