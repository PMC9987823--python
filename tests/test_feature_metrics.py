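"""Metric-suite oracles: Dice, thresholding, sparsities, entropies,
connected components."""

import numpy as np
import pytest
from scipy import ndimage

from voxsparse.feature_metrics import (
    DEFAULT_OFFSETS, connected_components, dice, feature_sparsity,
    shannon_entropy, spatial_entropy, threshold_feature, weight_sparsity,
)


def _random_masks(rng, n=200, size=60):
    for _ in range(n):
        a = rng.random(size) < rng.uniform(0.1, 0.9)
        b = rng.random(size) < rng.uniform(0.1, 0.9)
        if a.any() or b.any():
            yield a, b


class TestDice:
    def test_hand_counted_formula_on_random_pairs(self):
        rng = np.random.default_rng(42)
        for a, b in _random_masks(rng):
            expected = 2 * np.sum(a & b) / (np.sum(a) + np.sum(b))
            assert dice(a, b) == pytest.approx(expected)

    def test_symmetry(self):
        rng = np.random.default_rng(7)
        for a, b in _random_masks(rng):
            assert dice(a, b) == pytest.approx(dice(b, a))

    @pytest.mark.parametrize("a,b,expected", [
        ([1, 1, 0], [1, 1, 0], 1.0),                      # identical
        ([1, 1, 0, 0], [0, 0, 1, 1], 0.0),                # disjoint
        ([1, 1, 1, 0, 0, 0, 0, 0],
         [0, 1, 1, 1, 1, 1, 0, 0], 0.5),                  # |A|=3 |B|=5 |∩|=2
    ])
    def test_reference_values(self, a, b, expected):
        assert dice(np.array(a, bool), np.array(b, bool)) == \
            pytest.approx(expected)

    def test_both_empty_is_undefined(self):
        z = np.zeros(5, dtype=bool)
        with pytest.raises(ValueError, match="empty"):
            dice(z, z)


def _best_1d_two_means_split(f):
    """Oracle: globally optimal 1-D 2-means by enumerating sorted splits."""
    order = np.argsort(f)
    fs = f[order]
    best_cost, best_cut = np.inf, 1
    for cut in range(1, len(fs)):
        lo, hi = fs[:cut], fs[cut:]
        cost = ((lo - lo.mean()) ** 2).sum() + ((hi - hi.mean()) ** 2).sum()
        if cost < best_cost:
            best_cost, best_cut = cost, cut
    mask_lo = np.zeros(len(f), dtype=bool)
    mask_lo[order[:best_cut]] = True
    return mask_lo


class TestThresholdFeature:
    def test_matches_enumeration_oracle(self):
        rng = np.random.default_rng(3)
        for _ in range(20):
            f = np.concatenate([rng.normal(0, 1, 40), rng.normal(6, 1, 15)])
            rng.shuffle(f)
            lo, hi = threshold_feature(f, seed=0)
            oracle_lo = _best_1d_two_means_split(f)
            assert np.array_equal(lo, oracle_lo)
            assert np.array_equal(hi, ~oracle_lo)

    def test_simple_split(self):
        lo, hi = threshold_feature(np.array([0., 0., 0., 10., 10.]), seed=0)
        assert np.array_equal(lo, [True, True, True, False, False])
        assert np.array_equal(hi, [False, False, False, True, True])

    def test_masks_partition(self):
        rng = np.random.default_rng(5)
        f = rng.normal(size=100)
        lo, hi = threshold_feature(f, seed=0)
        assert np.array_equal(lo, ~hi)

    def test_scale_equivariance(self):
        rng = np.random.default_rng(11)
        f = rng.normal(size=80)
        lo1, _ = threshold_feature(f, seed=0)
        lo3, _ = threshold_feature(3.0 * f, seed=0)
        assert np.array_equal(lo1, lo3)

    def test_constant_raises(self):
        with pytest.raises(ValueError, match="constant"):
            threshold_feature(np.ones(10))


class TestSparsities:
    def test_feature_sparsity_direct_counts(self):
        assert feature_sparsity(np.array([0., 0., 0., 0., 8.])) == 5.0
        one_hot = np.zeros(33); one_hot[4] = 1.0
        assert feature_sparsity(one_hot) == 33.0

    def test_weight_sparsity_direct_counts(self):
        assert weight_sparsity(np.array([1., 1., 1., 9.])) == 4.0
        one_hot = np.zeros(17); one_hot[0] = 1.0
        assert weight_sparsity(one_hot) == 17.0

    def test_all_equal_raises(self):
        with pytest.raises(ValueError, match="sparsity undefined"):
            weight_sparsity(np.full(6, 2.5))

    def test_uniform_random_near_two(self):
        # half the mass lies above the mean of a symmetric distribution
        vals = [feature_sparsity(np.random.default_rng(s).random(1000))
                for s in range(20)]
        assert 1.8 <= np.mean(vals) <= 2.2

    def test_at_least_one_and_equals_length_iff_single_active(self):
        rng = np.random.default_rng(2)
        for _ in range(50):
            v = rng.normal(size=rng.integers(3, 40))
            if v.max() == v.min():
                continue
            s = feature_sparsity(v)
            assert s >= 1.0
            n_active = int((v > v.mean()).sum())
            assert (s == len(v)) == (n_active == 1)


class TestShannonEntropy:
    def test_constant_is_zero(self):
        assert shannon_entropy(np.full(40, 3.3)) == 0.0

    def test_two_equiprobable_symbols(self):
        f = np.array([0.0] * 50 + [1.0] * 50)
        assert shannon_entropy(f, n_bins=2) == pytest.approx(np.log(2))

    def test_bounded_by_log_bins(self):
        rng = np.random.default_rng(9)
        for n_bins in (2, 8, 64):
            f = rng.normal(size=500)
            assert shannon_entropy(f, n_bins) <= np.log(n_bins) + 1e-12

    def test_affine_invariance(self):
        rng = np.random.default_rng(13)
        f = rng.normal(size=300)
        h = shannon_entropy(f, 32)
        assert shannon_entropy(2.5 * f - 7.0, 32) == pytest.approx(h)


class TestSpatialEntropy:
    def test_constant_volume_is_zero(self):
        assert spatial_entropy(np.full((6, 6, 6), 2.0)) == 0.0

    def test_checkerboard_single_offset(self):
        idx = np.indices((8, 8, 8)).sum(axis=0)
        board = (idx % 2).astype(float)
        h = spatial_entropy(board, n_levels=2, offsets=((1, 0, 0),))
        assert h == pytest.approx(np.log(2))

    def test_shuffled_volume_not_less_entropic(self):
        # spatial structure lowers co-occurrence entropy
        vol = np.zeros((12, 12, 12))
        vol[3:9, 3:9, 3:9] = 1.0
        base = spatial_entropy(vol, n_levels=4)
        rng_master = np.random.default_rng(0)
        for _ in range(20):
            flat = vol.ravel().copy()
            rng_master.shuffle(flat)
            shuffled = flat.reshape(vol.shape)
            assert spatial_entropy(shuffled, n_levels=4) >= base - 1e-12

    def test_affine_invariance(self):
        rng = np.random.default_rng(21)
        vol = rng.normal(size=(7, 7, 7))
        h = spatial_entropy(vol, n_levels=8)
        assert spatial_entropy(0.1 * vol + 5, n_levels=8) == pytest.approx(h)

    def test_empty_cooccurrence_raises(self):
        vol = np.zeros((3, 3, 3)); vol[1, 1, 1] = 1.0
        mask = np.zeros((3, 3, 3), bool); mask[1, 1, 1] = True
        with pytest.raises(ValueError, match="no co-occurring"):
            spatial_entropy(vol, n_levels=2, offsets=((1, 0, 0),), mask=mask)


def _multi_blob_volume(rng, shape=(14, 14, 14), max_blobs=4):
    """Random solid blocks separated by >= 2 voxels from each other."""
    vol = np.zeros(shape)
    placed = []
    for _ in range(rng.integers(1, max_blobs + 1)):
        for _attempt in range(50):
            size = rng.integers(2, 4)
            lo = rng.integers(1, np.array(shape) - size - 1)
            box = (slice(lo[0], lo[0] + size), slice(lo[1], lo[1] + size),
                   slice(lo[2], lo[2] + size))
            # enforce >= 2-voxel separation: some axis must separate the
            # dilated bounding boxes
            ok = True
            for plo, psize in placed:
                if not any(lo[i] + size + 2 <= plo[i] or
                           plo[i] + psize + 2 <= lo[i] for i in range(3)):
                    ok = False
                    break
            if ok:
                vol[box] = 1.0
                placed.append((lo, size))
                break
    return vol


class TestConnectedComponents:
    def test_single_block(self):
        vol = np.zeros((9, 9, 9)); vol[3:6, 3:6, 3:6] = 1.0
        assert connected_components(vol, threshold=0.5) == 1

    def test_two_separated_blocks(self):
        vol = np.zeros((12, 12, 12))
        vol[1:4, 1:4, 1:4] = 1.0
        vol[7:10, 7:10, 7:10] = 1.0
        assert connected_components(vol, threshold=0.5) == 2

    def test_all_background_warns_and_returns_zero(self):
        with pytest.warns(UserWarning, match="no isosurface"):
            assert connected_components(np.zeros((5, 5, 5)), 0.5) == 0

    def test_agrees_with_floodfill_oracle(self):
        # 26-connectivity voxel flood fill is the independent oracle
        rng = np.random.default_rng(17)
        structure = np.ones((3, 3, 3), dtype=int)
        for _ in range(50):
            vol = _multi_blob_volume(rng)
            if vol.max() == 0:
                continue
            _, n_true = ndimage.label(vol > 0.5, structure=structure)
            assert connected_components(vol, threshold=0.5) == n_true
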