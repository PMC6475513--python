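import numpy as np
import pytest
from scipy import ndimage

from tubemorph.detect import (
    DegenerateHistogramError,
    DetectParams,
    IntensityHistogram,
    apply_threshold,
    binarize,
    compute_histogram,
    fill_holes,
    frangi_vesselness,
    refine_mask,
    remove_small_regions,
    threshold_adaptive,
    threshold_kittler,
    threshold_multiotsu,
    threshold_otsu,
)
from tubemorph.image_io import GrayImage

from conftest import random_histogram


def hist_from_counts(counts):
    counts = np.asarray(counts, dtype=np.int64)
    return IntensityHistogram(counts, int(counts.sum()))


def spike_hist(**bins):
    counts = np.zeros(256, dtype=np.int64)
    for b, n in bins.items():
        counts[int(b[1:])] = n
    return hist_from_counts(counts)


# ---------------------------------------------------------------------------
# brute-force criterion oracles (independent of the implementation path)

def otsu_oracle(counts):
    """Minimise within-class weighted variance by explicit loop."""
    best, best_t = np.inf, None
    idx = np.arange(256, dtype=float)
    for t in range(255):
        c0, c1 = counts[: t + 1], counts[t + 1 :]
        w0, w1 = c0.sum(), c1.sum()
        if w0 == 0 or w1 == 0:
            continue
        mu0 = (c0 * idx[: t + 1]).sum() / w0
        mu1 = (c1 * idx[t + 1 :]).sum() / w1
        var0 = (c0 * (idx[: t + 1] - mu0) ** 2).sum() / w0
        var1 = (c1 * (idx[t + 1 :] - mu1) ** 2).sum() / w1
        within = (w0 * var0 + w1 * var1) / (w0 + w1)
        if within < best - 1e-12:
            best, best_t = within, t
    return best_t


def multiotsu_oracle(counts, n_classes):
    """Maximise between-class variance over all cut tuples by explicit loops."""
    from itertools import combinations

    idx = np.arange(256, dtype=float)
    total = counts.sum()
    best, best_cuts = -np.inf, None
    for cuts in combinations(range(1, 256), n_classes - 1):
        bounds = (0, *cuts, 256)
        val = 0.0
        ok = True
        for a, b in zip(bounds[:-1], bounds[1:]):
            w = counts[a:b].sum()
            if w == 0:
                continue
            mu = (counts[a:b] * idx[a:b]).sum() / w
            val += w * mu * mu
        if best_cuts is None or val > best * (1 + 1e-12) + 1e-9:
            best, best_cuts = val, cuts
    return [c - 1 for c in best_cuts]


def kittler_oracle(counts):
    """Scan the minimum-error criterion over every candidate threshold."""
    idx = np.arange(256, dtype=float)
    total = counts.sum()
    best, best_t = np.inf, None
    for t in range(255):
        c0, c1 = counts[: t + 1], counts[t + 1 :]
        w0, w1 = c0.sum(), c1.sum()
        if w0 == 0 or w1 == 0:
            continue
        mu0 = (c0 * idx[: t + 1]).sum() / w0
        mu1 = (c1 * idx[t + 1 :]).sum() / w1
        var0 = max((c0 * (idx[: t + 1] - mu0) ** 2).sum() / w0, 1.0)
        var1 = max((c1 * (idx[t + 1 :] - mu1) ** 2).sum() / w1, 1.0)
        p0, p1 = w0 / total, w1 / total
        j = 1.0 + p0 * np.log(var0) + p1 * np.log(var1) \
            - 2.0 * (p0 * np.log(p0) + p1 * np.log(p1))
        if j < best - 1e-12:
            best, best_t = j, t
    return best_t


# ---------------------------------------------------------------------------

class TestHistogram:
    def test_four_pixel_extremes(self):
        img = GrayImage(np.tile([[0.0, 0.0], [1.0, 1.0]], (4, 4)))
        h = compute_histogram(img)
        assert h.counts[0] == 32 and h.counts[255] == 32

    def test_total_equals_pixel_count(self):
        rng = np.random.default_rng(0)
        img = GrayImage(rng.random((37, 53)))
        h = compute_histogram(img)
        assert h.counts.sum() == 37 * 53

    def test_half_intensity_bin(self):
        h = compute_histogram(GrayImage(np.full((16, 16), 0.5)))
        assert h.counts[127] == 256


class TestOtsu:
    def test_bimodal_spikes(self):
        h = spike_hist(b50=100, b200=100)
        t = threshold_otsu(h)
        assert 50 <= t <= 199
        assert t == otsu_oracle(h.counts)

    def test_adjacent_bins_forced_separator(self):
        assert threshold_otsu(spike_hist(b100=5, b101=7)) == 100

    def test_three_equal_spikes(self):
        h = spike_hist(b0=100, b128=100, b255=100)
        assert threshold_otsu(h) == otsu_oracle(h.counts)

    def test_degenerate_single_bin(self):
        with pytest.raises(DegenerateHistogramError):
            threshold_otsu(spike_hist(b42=100))

    @pytest.mark.parametrize("seed", range(25))
    def test_matches_brute_force_on_random_histograms(self, seed):
        h = random_histogram(np.random.default_rng(seed))
        assert threshold_otsu(h) == otsu_oracle(h.counts)


class TestMultiOtsu:
    def test_two_classes_reduce_to_otsu(self):
        for seed in range(10):
            h = random_histogram(np.random.default_rng(100 + seed))
            assert threshold_multiotsu(h, 2) == [threshold_otsu(h)]

    def test_trimodal_matches_exhaustive_search(self):
        h = spike_hist(b30=500, b130=400, b230=300)
        got = threshold_multiotsu(h, 3)
        assert got == multiotsu_oracle(h.counts, 3)
        t1, t2 = got
        assert 30 <= t1 < 130 <= t2 < 230 or (30 <= t1 and t2 >= 130)

    def test_three_classes_on_bimodal_histogram(self):
        rng = np.random.default_rng(44)
        sample = np.concatenate([
            rng.normal(40, 6, 5000), rng.normal(210, 8, 4000)
        ])
        counts = np.bincount(
            np.clip(np.round(sample), 0, 255).astype(int), minlength=256
        )
        h = hist_from_counts(counts)
        got = threshold_multiotsu(h, 3)
        assert len(got) == 2
        assert got == multiotsu_oracle(h.counts, 3)

    @pytest.mark.parametrize("seed", range(10))
    def test_matches_brute_force_on_random_histograms(self, seed):
        h = random_histogram(np.random.default_rng(200 + seed))
        assert threshold_multiotsu(h, 3) == multiotsu_oracle(h.counts, 3)

    def test_agrees_with_skimage_on_smooth_histogram(self):
        from skimage.filters import threshold_multiotsu as sk_multiotsu

        rng = np.random.default_rng(5)
        px = np.clip(
            np.concatenate([
                rng.normal(0.2, 0.05, 4000),
                rng.normal(0.5, 0.05, 3000),
                rng.normal(0.8, 0.04, 2000),
            ]),
            0,
            1,
        ).reshape(90, 100)
        img = GrayImage(px)
        ours = threshold_multiotsu(compute_histogram(img), 3)
        theirs = sk_multiotsu(px, classes=3, nbins=256) * 255
        assert np.all(np.abs(np.asarray(ours) - theirs) <= 2)


class TestKittler:
    def test_two_gaussian_sample(self):
        rng = np.random.default_rng(42)
        sample = np.concatenate([
            rng.normal(60, 8, 80_000),
            rng.normal(200, 12, 20_000),
        ])
        counts = np.bincount(
            np.clip(np.round(sample), 0, 255).astype(int), minlength=256
        )
        h = hist_from_counts(counts)
        assert threshold_kittler(h) == kittler_oracle(h.counts)

    def test_symmetric_equal_gaussians(self):
        rng = np.random.default_rng(7)
        sample = np.concatenate([
            rng.normal(100, 9, 50_000),
            rng.normal(150, 9, 50_000),
        ])
        counts = np.bincount(
            np.clip(np.round(sample), 0, 255).astype(int), minlength=256
        )
        h = hist_from_counts(counts)
        t = threshold_kittler(h)
        assert abs(t - 125) <= 2
        assert t == kittler_oracle(h.counts)

    def test_weak_mode_threshold_below_otsu(self):
        rng = np.random.default_rng(8)
        sample = np.concatenate([
            rng.normal(70, 10, 98_000),
            rng.normal(170, 25, 2_000),
        ])
        counts = np.bincount(
            np.clip(np.round(sample), 0, 255).astype(int), minlength=256
        )
        h = hist_from_counts(counts)
        assert threshold_kittler(h) < threshold_otsu(h)

    @pytest.mark.parametrize("seed", range(25))
    def test_matches_brute_force_on_random_histograms(self, seed):
        h = random_histogram(np.random.default_rng(300 + seed))
        assert threshold_kittler(h) == kittler_oracle(h.counts)


class TestAdaptive:
    def test_constant_with_positive_offset_empty(self):
        img = GrayImage(np.full((40, 40), 0.5))
        assert not threshold_adaptive(img, 15, offset=0.01).any()

    def test_negative_offset_full(self):
        img = GrayImage(np.full((40, 40), 0.5))
        assert threshold_adaptive(img, 15, offset=-1.0).all()

    def test_recovers_line_on_ramp_where_global_otsu_fails(self):
        H = W = 128
        ramp = np.tile(np.linspace(0.0, 0.8, W), (H, 1))
        line = np.zeros((H, W), bool)
        line[:, 16:19] = True
        px = np.clip(ramp + 0.18 * line, 0, 1)
        img = GrayImage(px)
        local = threshold_adaptive(img, 31, offset=0.05)
        t = threshold_otsu(compute_histogram(img))
        global_mask = apply_threshold(img, t)
        local_recall = (local & line).sum() / line.sum()
        global_recall = (global_mask & line).sum() / line.sum()
        assert local_recall > 0.9
        assert local_recall > global_recall


class TestFrangi:
    def test_constant_image_zero_response(self):
        out = frangi_vesselness(GrayImage(np.full((64, 64), 0.4)))
        assert np.allclose(out.pixels, 0.0)

    def test_ridge_response_concentrates_on_centerline(self):
        H = W = 128
        yy = np.mgrid[0:H, 0:W][0].astype(float)
        px = 0.8 * np.exp(-((yy - 64) ** 2) / (2 * 3.0**2))
        resp = frangi_vesselness(GrayImage(px), scales=(2.0, 3.0, 4.0)).pixels
        center = resp[63:66, 20:-20].mean()
        far = resp[np.abs(np.arange(H) - 64) > 15][:, 20:-20].mean()
        assert center >= 5 * max(far, 1e-9)

    def test_blob_suppressed_relative_to_ridge(self):
        # equal-contrast ridge (through row 96) and isotropic blob (at
        # (32, 64)) in one image: the blob centre responds strictly less
        H = W = 128
        yy, xx = np.mgrid[0:H, 0:W].astype(float)
        ridge = 0.8 * np.exp(-((yy - 96) ** 2) / (2 * 3.0**2))
        blob = 0.8 * np.exp(-(((yy - 32) ** 2) + (xx - 64) ** 2) / (2 * 3.0**2))
        combo = GrayImage(np.clip(np.maximum(ridge, blob), 0, 1))
        resp = frangi_vesselness(combo, scales=(2, 3, 4)).pixels
        assert resp[96, 20] > resp[32, 64]

    def test_weak_ridge_recovered_only_with_vesselness(self):
        # a faint vessel next to a strongly stained one: global Otsu
        # separates background from the bright vessel and misses the faint
        # one entirely; shape-normalised vesselness recovers it
        rng = np.random.default_rng(9)
        H = W = 128
        yy = np.mgrid[0:H, 0:W][0].astype(float)
        truth = np.abs(yy - 96) <= 2
        px = np.clip(
            0.1
            + 0.55 * np.exp(-((yy - 32) ** 2) / (2 * 3.0**2))
            + 0.13 * np.exp(-((yy - 96) ** 2) / (2 * 3.0**2))
            + rng.normal(0, 0.02, (H, W)),
            0,
            1,
        )
        img = GrayImage(px)
        direct, _ = binarize(img, DetectParams(threshold_method="otsu"))
        enhanced, _ = binarize(
            img,
            DetectParams(use_vesselness=True, threshold_method="otsu",
                         frangi_scales=(2.0, 3.0, 4.0), frangi_c=0.002),
        )
        recall_direct = (direct & truth).sum() / truth.sum()
        recall_enh = (enhanced & truth).sum() / truth.sum()
        assert recall_enh >= 0.9
        assert recall_direct < 0.5


class TestBinarize:
    def test_otsu_method_equals_manual_threshold(self):
        rng = np.random.default_rng(10)
        px = np.clip(
            np.where(rng.random((64, 64)) < 0.3,
                     rng.normal(0.8, 0.05, (64, 64)),
                     rng.normal(0.2, 0.05, (64, 64))),
            0, 1,
        )
        img = GrayImage(px)
        mask, t = binarize(img, DetectParams(threshold_method="otsu"))
        assert np.array_equal(mask, apply_threshold(img, int(t)))

    def test_adaptive_dispatch(self):
        rng = np.random.default_rng(11)
        img = GrayImage(rng.random((64, 64)))
        params = DetectParams(threshold_method="adaptive",
                              adaptive_block=15, adaptive_offset=0.02)
        mask, t = binarize(img, params)
        assert np.isnan(t)
        assert np.array_equal(mask, threshold_adaptive(img, 15, 0.02))

    def test_adaptive_complement_symmetry(self):
        rng = np.random.default_rng(12)
        img = GrayImage(rng.random((40, 40)))
        fg = threshold_adaptive(img, 15, offset=0.0)
        inv = threshold_adaptive(GrayImage(1.0 - img.pixels), 15, offset=0.0)
        # strict > means ties flip; exclude exact-tie pixels
        local_mean = ndimage.uniform_filter(img.pixels, 15, mode="reflect")
        ties = np.isclose(img.pixels, local_mean)
        assert np.array_equal(fg[~ties], ~inv[~ties])


class TestRefinement:
    def test_small_region_removal_against_counts(self):
        mask = np.zeros((100, 100), bool)
        mask[5:10, 5:15] = True           # 50 px -> removed at 1% (100 px)
        mask[50:60, 50:65] = True         # 150 px -> kept
        out = remove_small_regions(mask, 0.01)
        assert out.sum() == 150
        assert out[50:60, 50:65].all()

    def test_zero_fraction_is_identity(self):
        rng = np.random.default_rng(13)
        mask = rng.random((50, 50)) < 0.3
        assert np.array_equal(remove_small_regions(mask, 0.0), mask)

    def test_component_exactly_at_cutoff_is_kept(self):
        mask = np.zeros((100, 100), bool)
        mask[10:20, 10:20] = True         # exactly 100 px at 1% cutoff
        assert remove_small_regions(mask, 0.01).sum() == 100

    def test_hole_filling(self, ring):
        filled = fill_holes(ring)
        assert filled[20, 20]             # interior filled
        assert filled.sum() > ring.sum()

    def test_border_touching_background_untouched(self):
        mask = np.zeros((30, 30), bool)
        mask[0:2, :] = True
        mask[:, 0:2] = True
        out = fill_holes(mask)
        assert np.array_equal(out, mask)

    def test_idempotence_and_monotonicity(self):
        rng = np.random.default_rng(14)
        mask = ndimage.binary_dilation(rng.random((60, 60)) < 0.08)
        small = remove_small_regions(mask, 0.005)
        assert np.array_equal(remove_small_regions(small, 0.005), small)
        assert not (small & ~mask).any()   # removal only shrinks
        filled = fill_holes(mask)
        assert np.array_equal(fill_holes(filled), filled)
        assert not (mask & ~filled).any()  # filling only grows

    def test_refine_order_small_regions_before_fill(self):
        params = DetectParams(min_region_fraction=0.02, fill_holes=True)
        mask = np.zeros((50, 50), bool)
        mask[20:30, 20:30] = True
        mask[23:27, 23:27] = False        # hole
        mask[5, 5] = True                 # speck below cutoff
        out = refine_mask(mask, params)
        assert out[24, 24]                # hole filled
        assert not out[5, 5]              # speck removed first
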