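import numpy as np
import pytest
from scipy import ndimage as ndi

from rhizopore import morpho as mo


def inscribed_sphere_oracle(mask):
    """Exhaustive maximum-inscribed-sphere search (independent of the fast
    per-radius covering implementation): paint every candidate sphere."""
    D2 = np.rint(ndi.distance_transform_edt(mask) ** 2).astype(np.int64)
    out = np.zeros(mask.shape)
    for c in np.argwhere(mask):
        r2 = D2[tuple(c)]
        r = np.sqrt(r2)
        lo = np.maximum((c - np.ceil(r)).astype(int), 0)
        hi = np.minimum((c + np.ceil(r)).astype(int) + 1, mask.shape)
        zz, yy, xx = np.ogrid[lo[0]:hi[0], lo[1]:hi[1], lo[2]:hi[2]]
        ball = (zz - c[0]) ** 2 + (yy - c[1]) ** 2 + (xx - c[2]) ** 2 <= r2
        sub = out[lo[0]:hi[0], lo[1]:hi[1], lo[2]:hi[2]]
        np.maximum(sub, np.where(ball, 2 * r, 0), out=sub)
    out[~mask] = 0
    return out


def random_blob_mask(seed, shape=(24, 24, 24), fill=0.25):
    rng = np.random.default_rng(seed)
    field = ndi.gaussian_filter(rng.standard_normal(shape), 2.5)
    return field < np.quantile(field, fill)


class TestLocalThickness:
    def test_solid_sphere_uniform(self):
        zz, yy, xx = np.indices((24, 24, 24))
        sph = (zz - 12) ** 2 + (yy - 12) ** 2 + (xx - 12) ** 2 <= 4.5**2
        tm = mo.local_thickness(sph, 1.0)
        vals = tm.values[sph]
        assert abs(vals.min() - 9) <= 1 and abs(vals.max() - 9) <= 1

    def test_cylinder_mean_thickness(self):
        zz, yy, xx = np.indices((32, 32, 32))
        cyl = (yy - 16) ** 2 + (xx - 16) ** 2 <= 16
        tm = mo.local_thickness(cyl, 1.0)
        assert abs(tm.values[cyl].mean() - 8) <= 1

    def test_two_touching_spheres_bimodal(self):
        zz, yy, xx = np.indices((32, 32, 32))
        small = (zz - 7) ** 2 + (yy - 16) ** 2 + (xx - 16) ** 2 <= 2.5**2
        big = (zz - 15) ** 2 + (yy - 16) ** 2 + (xx - 16) ** 2 <= 5.5**2
        tm = mo.local_thickness(small | big, 1.0)
        assert abs(tm.values[big].max() - 11) <= 1
        tip = small & (zz <= 5)
        assert tip.any()
        assert abs(tm.values[tip].max() - 5) <= 1.5

    @pytest.mark.parametrize("seed", range(4))
    def test_matches_exhaustive_oracle(self, seed):
        mask = random_blob_mask(seed)
        fast = mo.local_thickness(mask, 1.0, exact=True).values
        oracle = inscribed_sphere_oracle(mask)
        np.testing.assert_allclose(fast[mask], oracle[mask], atol=1e-5)

    def test_quantized_mode_close_to_exact(self):
        # quantisation rounds sphere radii down by at most half a voxel;
        # only thin boundary shells may drop to the next covering sphere
        mask = random_blob_mask(7, shape=(28, 28, 28))
        exact = mo.local_thickness(mask, 1.0, exact=True).values
        quant = mo.local_thickness(mask, 1.0, exact=False).values
        err = exact[mask] - quant[mask]
        assert (err >= -1e-6).all()  # never overestimates
        assert np.quantile(err, 0.95) <= 2.0 + 1e-6
        assert err.mean() <= 1.0

    def test_dilation_monotone(self):
        mask = random_blob_mask(2)
        grown = ndi.binary_dilation(mask, np.ones((3, 3, 3), bool))
        a = mo.local_thickness(mask, 1.0, exact=True).values
        b = mo.local_thickness(grown, 1.0, exact=True).values
        assert (b[mask] >= a[mask] - 1e-6).all()

    def test_empty_mask(self):
        tm = mo.local_thickness(np.zeros((8, 8, 8), bool), 0.04)
        assert not tm.mask.any()


class TestSizeDistribution:
    def test_single_cylinder_one_class(self):
        zz, yy, xx = np.indices((40, 24, 24))
        cyl = (yy - 12) ** 2 + (xx - 12) ** 2 <= 3.75**2  # O 0.3 mm at 0.04 mm
        tm = mo.local_thickness(cyl, 0.04)
        sd = mo.size_distribution(tm)
        frame = sd.to_frame()
        target = frame.loc[frame["class"] == "0.2-0.5 mm", "volume_mm3"].iloc[0]
        assert target == pytest.approx(sd.total_volume_mm3, rel=1e-6)

    def test_conservation_exact(self):
        for seed in range(3):
            mask = random_blob_mask(seed)
            tm = mo.local_thickness(mask, 0.04)
            with np.errstate(all="ignore"):
                sd = mo.size_distribution(tm)
            assert sd.volume_mm3.sum() + sd.sub_resolution_mm3 == pytest.approx(
                sd.total_volume_mm3, abs=1e-9
            )
            assert sd.total_volume_mm3 == pytest.approx(mask.sum() * 0.04**3)

    def test_empty_map(self):
        tm = mo.local_thickness(np.zeros((8, 8, 8), bool), 0.04)
        sd = mo.size_distribution(tm)
        assert sd.volume_mm3.sum() == 0 and sd.mean_diameter_mm == 0

    def test_bad_edges(self):
        tm = mo.local_thickness(np.zeros((8, 8, 8), bool), 0.04)
        with pytest.raises(ValueError):
            mo.size_distribution(tm, edges_mm=(0.5, 0.2))


class TestPorosity:
    def test_full_and_empty(self):
        core = np.ones((10, 10, 10), bool)
        assert mo.porosity(core, core) == 100.0
        assert mo.porosity(np.zeros_like(core), core) == 0.0

    def test_fraction(self):
        mask = np.zeros((10, 10, 10), bool)
        mask[:3] = True
        assert mo.porosity(mask) == pytest.approx(30.0)

    def test_empty_core_rejected(self):
        with pytest.raises(ValueError):
            mo.porosity(np.zeros((4, 4, 4), bool), np.zeros((4, 4, 4), bool))


class TestRootLength:
    def test_straight_cylinder_within_5pct(self):
        zz, yy, xx = np.indices((40, 24, 24))
        cyl = (yy - 12) ** 2 + (xx - 12) ** 2 <= 9
        L = mo.skeleton_length_mm(cyl, 1.0)
        assert 0.95 * 40 <= L <= 1.05 * 40

    def test_two_disjoint_tubes_additive(self):
        zz, yy, xx = np.indices((64, 40, 40))
        a = (yy - 10) ** 2 + (xx - 10) ** 2 <= 9
        b = ((yy - 30) ** 2 + (xx - 30) ** 2 <= 9) & (zz < 40)
        L = mo.skeleton_length_mm(a | b, 1.0)
        assert 0.95 * 104 <= L <= 1.05 * 104

    def test_empty_mask_zero(self):
        assert mo.skeleton_length_mm(np.zeros((8, 8, 8), bool), 0.04) == 0.0

    def test_length_by_class_assignment(self):
        zz, yy, xx = np.indices((40, 32, 32))
        thin = (yy - 8) ** 2 + (xx - 8) ** 2 <= (3.75 / 2) ** 2   # O 0.15 mm
        thick = (yy - 22) ** 2 + (xx - 22) ** 2 <= (7.5 / 2) ** 2  # O 0.3 mm
        mask = thin | thick
        tm = mo.local_thickness(mask, 0.04)
        df = mo.root_length_by_class(mask, tm, voxel_size=0.04)
        by = df.set_index("class")["length_cm"]
        # each tube lands in its own diameter class; both ~40 voxels = 0.16 cm
        assert by["0.036-0.2 mm"] == pytest.approx(0.16, rel=0.15)
        assert by["0.2-0.5 mm"] == pytest.approx(0.16, rel=0.15)
        assert df["length_density_cm_cm3"].sum() == pytest.approx(
            df["length_cm"].sum() / (40 * 32 * 32 * 0.004**3)
        )

    def test_empty_root_mask(self):
        tm = mo.local_thickness(np.zeros((8, 8, 8), bool), 0.04)
        df = mo.root_length_by_class(np.zeros((8, 8, 8), bool), tm, voxel_size=0.04)
        assert (df["length_cm"] == 0).all()
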