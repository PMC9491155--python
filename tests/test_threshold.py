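import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as hst
from skimage import filters as skfilters

from rhizopore import threshold as th
from rhizopore.volio import GrayVolume


def bimodal_histogram(mu0=20, mu1=180, sd=8.0, w0=0.6, n=100_000, seed=0):
    rng = np.random.default_rng(seed)
    samples = np.concatenate([
        rng.normal(mu0, sd, int(n * w0)),
        rng.normal(mu1, sd, n - int(n * w0)),
    ])
    samples = np.clip(np.rint(samples), 0, 255).astype(np.uint8)
    return np.bincount(samples, minlength=256), samples


class TestMethods:
    def test_delta_peaks_all_between(self):
        h = np.zeros(256)
        h[20] = 500
        h[180] = 500
        for name, t in th.auto_thresholds(h):
            assert 20 < t < 180, f"{name} returned {t}"

    def test_bimodal_all_between_peaks(self):
        h, _ = bimodal_histogram()
        for name, t in th.auto_thresholds(h):
            assert 20 < t < 180, f"{name} returned {t}"

    def test_otsu_symmetric_equal_mass(self):
        # analytic symmetric histogram: threshold must sit at the midpoint
        g = np.arange(256.0)
        h = np.rint(1e4 * (np.exp(-((g - 50) ** 2) / 200) + np.exp(-((g - 150) ** 2) / 200)))
        assert abs(th.otsu(h) - 100) <= 1

    def test_otsu_attains_exhaustive_scan_maximum(self):
        # the between-class variance at the returned threshold equals the
        # exhaustive-scan maximum (the arg may sit anywhere on a flat valley)
        h, _ = bimodal_histogram(seed=3)
        p = h / h.sum()
        g = np.arange(256.0)

        def sigma_b(t):
            w0 = p[: t + 1].sum()
            w1 = 1 - w0
            if w0 == 0 or w1 == 0:
                return -1.0
            mu0 = (p[: t + 1] * g[: t + 1]).sum() / w0
            mu1 = (p[t + 1 :] * g[t + 1 :]).sum() / w1
            return w0 * w1 * (mu0 - mu1) ** 2

        best = max(sigma_b(t) for t in range(255))
        assert sigma_b(th.otsu(h)) == pytest.approx(best, rel=1e-9)

    def test_isodata_is_fixed_point(self):
        h, _ = bimodal_histogram(seed=4)
        t = th.isodata(h)
        g = np.arange(256.0)
        mb = (h[: t + 1] * g[: t + 1]).sum() / h[: t + 1].sum()
        ma = (h[t + 1 :] * g[t + 1 :]).sum() / h[t + 1 :].sum()
        assert t == int(np.floor((mb + ma) / 2.0))

    @pytest.mark.parametrize(
        "mine,theirs",
        [
            (th.otsu, skfilters.threshold_otsu),
            (th.isodata, skfilters.threshold_isodata),
            (th.yen, skfilters.threshold_yen),
            (th.triangle, skfilters.threshold_triangle),
            (th.li, skfilters.threshold_li),
        ],
    )
    def test_against_independent_implementations(self, mine, theirs):
        # overlapping modes populate the valley so the criterion optimum is
        # unique and the two implementations must agree closely
        h, samples = bimodal_histogram(sd=25.0, seed=5)
        ours = mine(h)
        ref = theirs(samples)
        assert abs(ours - float(ref)) <= 2.0

    def test_degenerate_histogram(self):
        h = np.zeros(256)
        h[42] = 100
        with pytest.raises(th.DegenerateHistogramError):
            th.auto_thresholds(h)

    def test_unknown_method_name(self):
        h, _ = bimodal_histogram()
        with pytest.raises(ValueError):
            th.auto_thresholds(h, methods=["NotAMethod"])


class TestEnsemble:
    def test_outlier_removed_hand_example(self):
        rep = th.ensemble_threshold([100, 102, 98, 101, 99, 150])
        assert rep.ensemble == 100.0
        assert len(rep.retained) == 5
        assert all(v != 150 for _, v in rep.retained)

    def test_all_identical(self):
        rep = th.ensemble_threshold([120, 120, 120])
        assert rep.ensemble == 120.0

    def test_exactly_one_sd_is_retained(self):
        rep = th.ensemble_threshold([50, 150])
        assert len(rep.retained) == 2
        assert rep.ensemble == 100.0

    def test_empty_rejected(self):
        with pytest.raises(ValueError):
            th.ensemble_threshold([])

    @settings(max_examples=50, deadline=None)
    @given(hst.lists(hst.integers(0, 255), min_size=2, max_size=12),
           hst.randoms(use_true_random=False))
    def test_permutation_invariant_and_bounded(self, values, rnd):
        rep_a = th.ensemble_threshold(values)
        shuffled = list(values)
        rnd.shuffle(shuffled)
        rep_b = th.ensemble_threshold(shuffled)
        assert rep_a.ensemble == pytest.approx(rep_b.ensemble)
        assert min(values) <= rep_a.ensemble <= max(values)


class TestBinaries:
    def _volume(self):
        data = np.zeros((6, 6, 6), np.uint8)
        data[0] = 20
        data[1] = 90
        data[2:] = 180
        return GrayVolume(data, 0.04)

    def test_pore_binary_covers_dark_bands(self):
        vol = self._volume()
        mask = th.pore_binary(vol, 120)
        assert mask[0].all() and mask[1].all() and not mask[2:].any()

    def test_pore_binary_all_true_at_255(self):
        assert th.pore_binary(self._volume(), 255).all()

    def test_organic_band_arithmetic(self):
        # T = 120, fraction 2.4 -> band (50, 120]: selects the 90-gray
        # voxels, excludes 20-gray air
        vol = self._volume()
        mask = th.organic_binary(vol, 120, 2.4)
        assert mask[1].all()
        assert not mask[0].any() and not mask[2:].any()

    def test_large_fraction_limit_equals_pore_binary(self):
        vol = self._volume()
        np.testing.assert_array_equal(
            th.organic_binary(vol, 120, 1e9), th.pore_binary(vol, 120) & (vol.voxels > 0)
        )

    def test_organic_subset_of_pore(self):
        rng = np.random.default_rng(0)
        vol = GrayVolume(rng.integers(0, 256, (8, 8, 8), dtype=np.uint8), 0.04)
        for T in (40, 120, 200):
            organic = th.organic_binary(vol, T)
            pore = th.pore_binary(vol, T)
            assert not (organic & ~pore).any()

    def test_noise_free_two_material_exact(self):
        # with flat grays any threshold strictly between the materials
        # reproduces the planted binary exactly
        rng = np.random.default_rng(1)
        truth = rng.random((16, 16, 16)) < 0.3
        vol = GrayVolume(np.where(truth, 20, 180).astype(np.uint8), 0.04)
        for T in (21, 100, 179):
            assert np.array_equal(th.pore_binary(vol, T), truth)


class TestReportOnVolume:
    def test_threshold_report_roundtrip(self, tmp_path):
        rng = np.random.default_rng(2)
        data = np.where(rng.random((24, 24, 24)) < 0.3, 20, 180)
        data = np.clip(data + rng.normal(0, 8, data.shape), 0, 255).astype(np.uint8)
        vol = GrayVolume(data, 0.04)
        rep = th.threshold_report(vol)
        assert 20 < rep.ensemble < 180
        text = rep.to_json(tmp_path / "report.json")
        assert "ensemble" in text
        lows = [v for _, v in rep.per_method]
        assert min(lows) <= rep.ensemble <= max(lows)
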