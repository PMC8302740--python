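"""Image-quality metrics vs independent voxel-loop oracles."""

import numpy as np
import pytest

from qcbct import evaluate as ev


def _rand_pair(rng, n=16):
    ref = rng.normal(200, 150, (n, n))
    test = ref + rng.normal(0, 60, (n, n))
    mask = rng.random((n, n)) > 0.3
    return ref, test, mask


# --- explicit voxel-loop oracles -------------------------------------------

def oracle_stats(ref, test, mask):
    xs, ys = [], []
    for i in range(ref.shape[0]):
        for j in range(ref.shape[1]):
            if mask[i, j]:
                xs.append(ref[i, j])
                ys.append(test[i, j])
    n = len(xs)
    mx = sum(xs) / n
    my = sum(ys) / n
    vx = sum((x - mx) ** 2 for x in xs) / n
    vy = sum((y - my) ** 2 for y in ys) / n
    cov = sum((x - mx) * (y - my) for x, y in zip(xs, ys)) / n
    return xs, ys, n, mx, my, vx, vy, cov


class TestMetricOracles:
    def test_all_metrics_match_voxel_loop(self, rng):
        for _ in range(5):
            ref, test, mask = _rand_pair(rng)
            xs, ys, n, mx, my, vx, vy, cov = oracle_stats(ref, test, mask)
            o_mad = sum(abs(x - y) for x, y in zip(xs, ys)) / n
            mse = sum((x - y) ** 2 for x, y in zip(xs, ys)) / n
            o_psnr = 20 * np.log10(4000.0 / np.sqrt(mse))
            c1, c2 = (0.01 * 4000) ** 2, (0.03 * 4000) ** 2
            o_ssim = ((2 * mx * my + c1) * (2 * cov + c2)) / (
                (mx**2 + my**2 + c1) * (vx + vy + c2)
            )
            o_ncc = cov / np.sqrt(vx * vy)
            o_slope = cov / vx
            o_bias = my - mx
            assert ev.mad(ref, test, mask) == pytest.approx(o_mad, rel=1e-12)
            assert ev.psnr(ref, test, mask) == pytest.approx(o_psnr, rel=1e-12)
            assert ev.ssim(ref, test, mask) == pytest.approx(o_ssim, rel=1e-12)
            assert ev.ncc(ref, test, mask) == pytest.approx(o_ncc, rel=1e-12)
            assert ev.linearity_slope(ref, test, mask)[0] == pytest.approx(o_slope, rel=1e-10)
            ba = ev.bland_altman(ref, test, mask)
            assert ba.bias == pytest.approx(o_bias, rel=1e-10, abs=1e-10)

    def test_identity_values(self, rng):
        ref = rng.normal(100, 50, (8, 8))
        mask = np.ones((8, 8), bool)
        assert ev.mad(ref, ref, mask) == 0.0
        assert ev.psnr(ref, ref, mask) == np.inf
        assert ev.ssim(ref, ref, mask) == pytest.approx(1.0, abs=1e-9)
        assert ev.ncc(ref, ref, mask) == pytest.approx(1.0, abs=1e-12)
        assert ev.linearity_slope(ref, ref, mask)[0] == pytest.approx(1.0, abs=1e-12)
        ba = ev.bland_altman(ref, ref, mask)
        assert (ba.bias, ba.loa_low, ba.loa_high) == (0.0, 0.0, 0.0)

    def test_swap_invariance_mad_ncc(self, rng):
        ref, test, mask = _rand_pair(rng)
        assert ev.mad(ref, test, mask) == ev.mad(test, ref, mask)
        assert ev.ncc(ref, test, mask) == pytest.approx(ev.ncc(test, ref, mask), rel=1e-12)

    def test_simple_values(self):
        assert ev.mad(np.array([[0.0, 2.0]]), np.array([[1.0, 1.0]])) == 1.0
        # MAX=100, MSE=100 -> 20 dB
        ref = np.zeros((1, 4))
        test = np.full((1, 4), 10.0)
        assert ev.psnr(ref, test, max_intensity=100.0) == pytest.approx(20.0)
        # anti-correlated
        x = np.array([[1.0, 2.0, 3.0]])
        assert ev.ncc(x, -x) == pytest.approx(-1.0)

    def test_errors(self, rng):
        ref, test, mask = _rand_pair(rng)
        with pytest.raises(ValueError, match="empty"):
            ev.mad(ref, test, np.zeros_like(mask))
        with pytest.raises(ValueError):
            ev.ncc(np.ones((4, 4)), rng.normal(size=(4, 4)))
        with pytest.raises(ValueError):
            ev.linearity_slope(np.ones((4, 4)), rng.normal(size=(4, 4)))


class TestSnu:
    def test_constant_rois_zero(self):
        vol = np.full((4, 16, 16), 100.0)
        rois = [(0, 4, 0, 4, 0, 4), (0, 4, 8, 12, 8, 12)]
        assert ev.snu(vol, rois) == 0.0

    def test_known_roi_means(self):
        vol = np.zeros((1, 10, 10))
        vol[0, 0:2, 0:2] = 30.0
        vol[0, 4:6, 4:6] = 50.0
        vol[0, 8:10, 8:10] = 80.0
        rois = [(0, 1, 0, 2, 0, 2), (0, 1, 4, 6, 4, 6), (0, 1, 8, 10, 8, 10)]
        assert ev.snu(vol, rois) == pytest.approx(50.0)

    def test_random_rois_vs_oracle(self, rng):
        vol = rng.normal(100, 30, (3, 12, 12))
        rois = [(0, 3, 1, 5, 2, 6), (0, 3, 6, 10, 7, 11), (1, 2, 0, 12, 0, 12)]
        means = [vol[r[0]:r[1], r[2]:r[3], r[4]:r[5]].mean() for r in rois]
        assert ev.snu(vol, rois) == pytest.approx(max(means) - min(means), rel=1e-12)

    def test_needs_two_rois(self):
        with pytest.raises(ValueError):
            ev.snu(np.zeros((1, 4, 4)), [(0, 1, 0, 2, 0, 2)])


class TestBlandAltman:
    def test_constant_offset(self, rng):
        ref = rng.normal(size=(6, 6))
        ba = ev.bland_altman(ref, ref + 5.0)
        assert ba.bias == pytest.approx(5.0)
        assert ba.loa_low == pytest.approx(5.0)
        assert ba.loa_high == pytest.approx(5.0)

    def test_loa_formula(self, rng):
        ref, test, mask = _rand_pair(rng)
        ba = ev.bland_altman(ref, test, mask)
        d = (test - ref)[mask]
        assert ba.loa_high == pytest.approx(d.mean() + 1.96 * d.std(), rel=1e-12)


class TestArchProfile:
    def test_identical_r1(self, rng):
        sl = rng.normal(100, 30, (32, 32))
        poly = np.array([[8, 8], [16, 24], [24, 8]], float)
        prof = ev.arch_profile_correlation(sl, sl, poly)
        assert prof.pearson_r == pytest.approx(1.0)

    def test_affine_invariance(self, rng):
        sl = rng.normal(100, 30, (32, 32))
        poly = np.array([[8, 8], [16, 24], [24, 8]], float)
        prof = ev.arch_profile_correlation(sl, 3.0 * sl + 7.0, poly)
        assert prof.pearson_r == pytest.approx(1.0)

    def test_sampling_matches_manual_oracle(self, rng):
        sl_a = rng.normal(size=(16, 16))
        sl_b = rng.normal(size=(16, 16))
        poly = np.array([[2.0, 2.0], [2.0, 12.0]])  # horizontal segment
        prof = ev.arch_profile_correlation(sl_a, sl_b, poly, n_samples=11)
        # equal arc-length samples land on integer columns 2..12 of row 2
        assert np.allclose(prof.ref_values, sl_a[2, 2:13], atol=1e-12)
        r = np.corrcoef(sl_a[2, 2:13], sl_b[2, 2:13])[0, 1]
        assert prof.pearson_r == pytest.approx(r, rel=1e-12)

    def test_degenerate_polyline_rejected(self, rng):
        sl = rng.normal(size=(8, 8))
        with pytest.raises(ValueError):
            ev.arch_profile_correlation(sl, sl, np.array([[2.0, 2.0], [2.0, 2.0]]))


class TestPercentImprovement:
    @pytest.mark.parametrize(
        "q,o,direction,expected",
        [
            (203.45, 328.91, "lower_better", 38.14),
            (23.87, 19.94, "higher_better", 19.71),
            (15.60, 79.04, "lower_better", 80.26),
            (0.85, 0.42, "higher_better", 102.38),
            (15.60, 13.39, "lower_better", -16.50),
        ],
    )
    def test_reference_examples(self, q, o, direction, expected):
        from qcbct.benchmark import round_half_up

        assert round_half_up(ev.percent_improvement(q, o, direction)) == pytest.approx(expected)

    def test_equal_values_zero(self):
        assert ev.percent_improvement(3.3, 3.3, "lower_better") == 0.0
        assert ev.percent_improvement(3.3, 3.3, "higher_better") == 0.0

    def test_zero_denominator(self):
        with pytest.raises(ValueError):
            ev.percent_improvement(1.0, 0.0, "lower_better")


class TestPairedTtest:
    def test_symmetric_differences_t0(self):
        a = np.array([1.0, 2.0, 3.0, 4.0])
        b = a + np.array([0.5, -0.5, 1.0, -1.0])
        t, p = ev.paired_ttest(a, b)
        assert t == pytest.approx(0.0, abs=1e-12)
        assert p == pytest.approx(1.0)

    def test_closed_form_oracle(self):
        # differences (1,2,3): mean 2, sd 1, t = 2/(1/sqrt(3)) = 2*sqrt(3) = 3.4641
        a = np.array([1.0, 2.0, 3.0])
        b = a + np.array([1.0, 2.0, 3.0])
        t, p = ev.paired_ttest(b, a)
        assert t == pytest.approx(2 * np.sqrt(3.0), rel=1e-9)
        from scipy import stats

        assert p == pytest.approx(2 * stats.t.sf(2 * np.sqrt(3.0), df=2), rel=1e-9)
        assert p == pytest.approx(0.0742, abs=2e-4)

    def test_zero_variance_rejected(self):
        with pytest.raises(ValueError):
            ev.paired_ttest([1.0, 2.0], [2.0, 3.0])


class TestCompareReports:
    def test_paired_tests_between_methods(self, rng):
        ref = rng.normal(300, 150, (6, 16, 16))
        good = ref + rng.normal(0, 20, ref.shape)
        bad = ref + rng.normal(0, 120, ref.shape)
        ra = ev.metric_report(ref, good)
        rb = ev.metric_report(ref, bad)
        comp = ev.compare_reports(ra, rb)
        t, p = comp["mad"]
        assert t < 0  # the better method has lower per-slice MAD
        assert 0 <= p <= 1
        mads_a = [r["mad"] for r in ra["per_slice"]]
        mads_b = [r["mad"] for r in rb["per_slice"]]
        t_oracle, p_oracle = ev.paired_ttest(mads_a, mads_b)
        assert (t, p) == (pytest.approx(t_oracle), pytest.approx(p_oracle))


class TestRegionAggregate:
    def test_constant_values_zero_sd(self):
        out = ev.region_aggregate([5.0] * 10, ["maxilla"] * 4 + ["mandible"] * 6)
        assert out["maxilla"] == (5.0, 0.0)
        assert out["mandible"] == (5.0, 0.0)

    def test_two_region_split_hand_computed(self):
        vals = [1.0, 3.0, 10.0, 14.0]
        out = ev.region_aggregate(vals, ["maxilla", "maxilla", "mandible", "mandible"])
        assert out["maxilla"] == (pytest.approx(2.0), pytest.approx(1.0))
        assert out["mandible"] == (pytest.approx(12.0), pytest.approx(2.0))

    def test_single_region_is_global_mean(self, rng):
        vals = rng.normal(size=20)
        out = ev.region_aggregate(vals, ["all"] * 20)
        assert out["all"][0] == pytest.approx(vals.mean())

    def test_default_split_follows_81_of_200(self):
        vals = list(range(200))
        out = ev.region_aggregate(vals)
        assert out["maxilla"][0] == pytest.approx(np.mean(range(81)))
        assert out["mandible"][0] == pytest.approx(np.mean(range(81, 200)))
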