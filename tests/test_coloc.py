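import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from focimix import (
    AnalysisConfig,
    NucleusSpec,
    ThresholdSet,
    coloc_mask,
    coloc_report,
    coloc_volume,
    find_max_coloc_roi,
    generate_nucleus,
    manders,
    pearson,
)

VOX = (0.34, 0.8, 0.8)
T0 = ThresholdSet({"green": 0.0, "red": 0.0}, rule="manual")


def pearson_oracle(a, b):
    """Closed-form sample correlation via explicit sums."""
    a = np.asarray(a, float).ravel()
    b = np.asarray(b, float).ravel()
    n = a.size
    num = n * (a * b).sum() - a.sum() * b.sum()
    den = np.sqrt(n * (a**2).sum() - a.sum() ** 2) * np.sqrt(
        n * (b**2).sum() - b.sum() ** 2
    )
    return num / den


class TestPearson:
    def test_self_correlation_is_one(self, rng):
        img = rng.random((4, 4, 4))
        assert pearson(img, img) == pytest.approx(1.0)

    def test_complementary_masks_give_minus_one(self, rng):
        a = (rng.random((4, 4, 4)) > 0.5).astype(float)
        b = 1.0 - a
        assert pearson(a, b) == pytest.approx(-1.0)

    @pytest.mark.parametrize(
        "a,b",
        [
            ((0, 0, 1, 1, 2, 2, 3, 3), (3, 3, 2, 2, 1, 1, 0, 0)),
            ((0, 1, 2, 3, 0, 1, 2, 3), (0, 1, 2, 3, 3, 2, 1, 0)),
        ],
    )
    def test_eight_voxel_examples_match_closed_form(self, a, b):
        a3 = np.array(a, float).reshape(2, 2, 2)
        b3 = np.array(b, float).reshape(2, 2, 2)
        assert pearson(a3, b3) == pytest.approx(pearson_oracle(a, b))

    def test_zero_variance_is_nan_with_warning(self):
        flat = np.ones((3, 3, 3))
        with pytest.warns(UserWarning, match="zero variance"):
            assert np.isnan(pearson(flat, np.random.rand(3, 3, 3)))


class TestManders:
    def test_identical_channels_complete_colocalization(self, rng):
        img = rng.integers(1, 200, size=(4, 4, 4)).astype(float)
        t = ThresholdSet({"green": 50.0, "red": 50.0}, rule="manual")
        mg, mr = manders(img, img, t)
        assert 0 < mg < 1 and 0 < mr < 1  # total-denominator convention
        mg, mr = manders(img, img, t, denominator="thresholded")
        assert (mg, mr) == (1.0, 1.0)

    def test_disjoint_supports_give_zero(self):
        a = np.zeros((2, 2, 2))
        b = np.zeros((2, 2, 2))
        a[0] = 10.0
        b[1] = 10.0
        assert manders(a, b, T0) == (0.0, 0.0)

    def test_four_voxel_toy_direct_sum(self):
        a = np.array([10.0, 10.0, 0.0, 0.0]).reshape(1, 2, 2)
        b = np.array([0.0, 10.0, 10.0, 0.0]).reshape(1, 2, 2)
        mg, mr = manders(a, b, T0)
        assert mg == pytest.approx(0.5)
        assert mr == pytest.approx(0.5)

    def test_zero_denominator_warns_and_returns_zero(self):
        empty = np.zeros((2, 2, 2))
        with pytest.warns(UserWarning, match="denominator"):
            mg, mr = manders(empty, empty, T0)
        assert (mg, mr) == (0.0, 0.0)


class TestColocMaskAndVolume:
    def test_disjoint_empty_and_identical_support(self):
        a = np.zeros((2, 2, 2))
        b = np.zeros((2, 2, 2))
        a[0] = 5.0
        b[1] = 5.0
        assert coloc_mask(a, b, T0).sum() == 0
        assert coloc_mask(a, a, T0).sum() == 4

    def test_toy_pair_single_voxel(self):
        a = np.array([10.0, 10.0, 0.0, 0.0]).reshape(1, 2, 2)
        b = np.array([0.0, 10.0, 10.0, 0.0]).reshape(1, 2, 2)
        mask = coloc_mask(a, b, T0)
        assert mask.sum() == 1 and mask[0, 0, 1]

    def test_volume_is_count_times_voxel_volume(self):
        mask = np.zeros((10, 10, 10), dtype=bool)
        mask.ravel()[:100] = True
        assert coloc_volume(mask, (0.34, 0.8, 0.8)) == pytest.approx(100 * 0.2176)
        assert coloc_volume(np.zeros((2, 2, 2), bool), VOX) == 0.0
        assert coloc_volume(np.ones((10, 10, 10), bool), (1, 1, 1)) == 1000.0

    def test_volume_conservation(self, rng):
        mask = rng.random((6, 6, 6)) > 0.4
        total = coloc_volume(np.ones_like(mask), VOX)
        assert coloc_volume(mask, VOX) + coloc_volume(~mask, VOX) == pytest.approx(total)


class TestMaxColocRoi:
    def test_empty_mask_origin_box(self):
        roi = find_max_coloc_roi(np.zeros((20, 20, 20), bool), (1, 1, 1), 64.0)
        assert roi.origin == (0, 0, 0)
        assert roi.coloc_voxels == 0
        assert roi.volume_um3 == pytest.approx(64.0)

    def test_single_cluster_is_captured(self):
        mask = np.zeros((20, 20, 20), dtype=bool)
        mask[10:13, 11:14, 12:15] = True
        roi = find_max_coloc_roi(mask, (1, 1, 1), 64.0)
        assert roi.coloc_voxels == 27
        sl = roi.slices()
        assert mask[sl].sum() == 27

    def test_larger_of_two_clusters_wins(self):
        mask = np.zeros((30, 30, 30), dtype=bool)
        mask[2:4, 2:4, 2:4] = True  # 8 voxels
        mask[20:23, 20:23, 20:23] = True  # 27 voxels
        roi = find_max_coloc_roi(mask, (1, 1, 1), 64.0)
        assert roi.coloc_voxels == 27
        assert all(o >= 17 for o in roi.origin)

    def test_physical_cube_shape(self):
        roi = find_max_coloc_roi(np.zeros((40, 40, 40), bool), (0.34, 0.8, 0.8), 65.0)
        side = 65.0 ** (1 / 3)
        assert roi.size == (round(side / 0.34), round(side / 0.8), round(side / 0.8))
        assert roi.volume_um3 == pytest.approx(
            roi.size[0] * 0.34 * roi.size[1] * 0.8 * roi.size[2] * 0.8
        )

    def test_oversized_roi_rejected(self):
        with pytest.raises(ValueError, match="exceeds"):
            find_max_coloc_roi(np.zeros((4, 4, 4), bool), (1, 1, 1), 1000.0)


class TestColocReport:
    def test_channel_swap_symmetry(self, default_nucleus):
        """Swapping channels preserves PC and volumes, swaps the Mander pair."""
        stack, _ = default_nucleus
        normal = coloc_report(stack, AnalysisConfig(channels=("green", "red")))
        swapped = coloc_report(stack, AnalysisConfig(channels=("red", "green")))
        for a, b in zip(normal, swapped):
            assert a.pearson == pytest.approx(b.pearson)
            assert a.vol_coloc_um3 == pytest.approx(b.vol_coloc_um3)
            assert a.m_green == pytest.approx(b.m_red)
            assert a.m_red == pytest.approx(b.m_green)

    def test_rows_and_bounds(self, default_nucleus):
        stack, _ = default_nucleus
        rows = coloc_report(stack)
        assert [r.region for r in rows] == ["nucleus", "roi"]
        for r in rows:
            assert -1.0 <= r.pearson <= 1.0
            assert 0.0 <= r.m_green <= 1.0 and 0.0 <= r.m_red <= 1.0
            assert 0.0 <= r.pct_coloc <= min(r.pct_green, r.pct_red) + 1e-9
            assert r.pct_occupied == pytest.approx(r.pct_green + r.pct_red)
            assert r.pct_occupied_union <= r.pct_occupied + 1e-9
        assert rows[1].roi is not None
        assert rows[1].vol_coloc_um3 <= rows[0].vol_coloc_um3 + 1e-9

    def test_segregated_nucleus_has_negative_whole_nucleus_pc(self):
        """Spatially segregated territories anticorrelate the two channels."""
        pcs = []
        for seed in (21, 22, 23):
            stack, _ = generate_nucleus(NucleusSpec(seed=seed, f_mix=0.0))
            pcs.append(coloc_report(stack)[0].pearson)
        assert all(pc < 0 for pc in pcs)


# --- brute-force oracle ----------------------------------------------------


def naive_metrics(a, b, t_a, t_b, voxel):
    """Triple-loop reference for every voxel-level metric."""
    nz, ny, nx = a.shape
    sum_a = sum_b = sum_ab = sum_a2 = sum_b2 = 0.0
    n = 0
    coloc = 0
    num_g = den_g = num_r = den_r = 0.0
    for z in range(nz):
        for y in range(ny):
            for x in range(nx):
                va, vb = float(a[z, y, x]), float(b[z, y, x])
                n += 1
                sum_a += va
                sum_b += vb
                sum_ab += va * vb
                sum_a2 += va * va
                sum_b2 += vb * vb
                above_a = va > t_a
                above_b = vb > t_b
                if above_a and above_b:
                    coloc += 1
                if above_b:
                    num_g += va
                den_g += va
                if above_a:
                    num_r += vb
                den_r += vb
    num = n * sum_ab - sum_a * sum_b
    den = np.sqrt(n * sum_a2 - sum_a**2) * np.sqrt(n * sum_b2 - sum_b**2)
    pc = num / den if den > 0 else np.nan
    mg = num_g / den_g if den_g else 0.0
    mr = num_r / den_r if den_r else 0.0
    return pc, mg, mr, coloc, coloc * voxel[0] * voxel[1] * voxel[2]


def test_metrics_match_naive_oracle_on_random_images(rng):
    """PC, Mander pair, coloc count and volume agree with a naive
    triple-loop implementation to 1e-10 relative on random small images."""
    for _ in range(60):
        shape = tuple(rng.integers(2, 9, size=3))
        a = rng.integers(0, 256, size=shape).astype(float)
        b = rng.integers(0, 256, size=shape).astype(float)
        t_a, t_b = rng.uniform(0, 200, size=2)
        ts = ThresholdSet({"green": t_a, "red": t_b}, rule="manual")
        pc_o, mg_o, mr_o, n_o, vol_o = naive_metrics(a, b, t_a, t_b, VOX)
        assert pearson(a, b) == pytest.approx(pc_o, rel=1e-10)
        mg, mr = manders(a, b, ts)
        assert mg == pytest.approx(mg_o, rel=1e-10)
        assert mr == pytest.approx(mr_o, rel=1e-10)
        mask = coloc_mask(a, b, ts)
        assert int(mask.sum()) == n_o
        assert coloc_volume(mask, VOX) == pytest.approx(vol_o, rel=1e-10)


@settings(max_examples=200, deadline=None, derandomize=True)
@given(st.integers(0, 2**31 - 1))
def test_coefficient_bounds_property(seed):
    """PC stays in [-1, 1] and Mander values in [0, 1] on random images."""
    rng = np.random.default_rng(seed)
    shape = tuple(rng.integers(2, 7, size=3))
    a = rng.integers(0, 256, size=shape).astype(float)
    b = rng.integers(0, 256, size=shape).astype(float)
    ts = ThresholdSet(
        {"green": float(rng.uniform(0, 255)), "red": float(rng.uniform(0, 255))},
        rule="manual",
    )
    pc = pearson(a, b)
    if not np.isnan(pc):
        assert -1.0 - 1e-12 <= pc <= 1.0 + 1e-12
    mg, mr = manders(a, b, ts)
    assert 0.0 <= mg <= 1.0 and 0.0 <= mr <= 1.0
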