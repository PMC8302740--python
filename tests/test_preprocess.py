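"""Rigid registration, resampling, crop/resize and anatomy masking."""

import numpy as np
import pytest
from scipy.spatial.transform import Rotation

from qcbct.preprocess import (
    LANDMARK_NAMES,
    LandmarkSet,
    MaskVolume,
    RigidTransform,
    crop_resize,
    default_landmarks,
    fit_rigid_from_landmarks,
    make_mask,
    mask_pair,
    resample,
)
from qcbct.volume import BACKGROUND_SENTINEL, VolumeImage


def _rmsd(a: LandmarkSet, b: LandmarkSet) -> float:
    d = a.as_array() - b.as_array()
    return float(np.sqrt(np.mean(np.sum(d**2, axis=1))))


class TestRigidFit:
    def test_identity(self):
        lm = default_landmarks()
        xf = fit_rigid_from_landmarks(lm, lm)
        assert np.allclose(xf.rotation, np.eye(3), atol=1e-12)
        assert np.allclose(xf.translation, 0, atol=1e-12)

    def test_pure_translation(self):
        lm = default_landmarks()
        moved = LandmarkSet.from_array(lm.as_array() + [5.0, 0.0, 0.0])
        xf = fit_rigid_from_landmarks(lm, moved)
        assert np.allclose(xf.rotation, np.eye(3), atol=1e-12)
        assert np.allclose(xf.translation, [5.0, 0.0, 0.0], atol=1e-12)

    def test_known_30deg_rotation_recovered(self):
        lm = default_landmarks()
        R = Rotation.from_euler("z", 30, degrees=True).as_matrix()
        true = RigidTransform(R, np.array([1.0, -2.0, 3.0]))
        fixed = lm.transformed(true)
        xf = fit_rigid_from_landmarks(lm, fixed)
        assert np.abs(xf.rotation - R).max() <= 1e-9
        assert _rmsd(lm.transformed(xf), fixed) <= 1e-9

    def test_random_rigid_recovery_many(self, rng):
        lm = default_landmarks()
        for _ in range(100):
            R = Rotation.random(random_state=int(rng.integers(2**31))).as_matrix()
            t = rng.normal(0, 20, 3)
            true = RigidTransform(R, t)
            fixed = lm.transformed(true)
            xf = fit_rigid_from_landmarks(lm, fixed)
            assert _rmsd(lm.transformed(xf), fixed) <= 1e-9

    def test_collinear_rejected(self):
        pts = {n: (float(i), 2.0 * i, 0.0) for i, n in enumerate(LANDMARK_NAMES)}
        lm = LandmarkSet(pts)
        with pytest.raises(ValueError, match="collinear"):
            fit_rigid_from_landmarks(lm, lm)

    def test_requires_exact_names(self):
        with pytest.raises(ValueError):
            LandmarkSet({"a": (0.0, 0.0, 0.0)})


class TestResample:
    def test_identity_same_grid(self, rng):
        vol = VolumeImage(rng.normal(0, 100, (6, 10, 12)))
        out = resample(vol, RigidTransform.identity())
        assert np.allclose(out.data, vol.data, atol=1e-12)

    def test_integer_translation_shifts(self):
        data = np.zeros((4, 8, 8))
        data[1, 3, 4] = 100.0
        vol = VolumeImage(data, spacing_mm=(1, 1, 1))
        xf = RigidTransform(np.eye(3), np.array([1.0, 0.0, 0.0]))
        out = resample(vol, xf, fill_value=0.0)
        assert out.data[2, 3, 4] == pytest.approx(100.0)
        assert out.data[1, 3, 4] == pytest.approx(0.0)

    def test_small_rotation_matches_trilinear_oracle(self, rng):
        vol = VolumeImage(rng.normal(0, 50, (6, 8, 8)), spacing_mm=(1, 1, 1))
        R = Rotation.from_euler("x", 4, degrees=True).as_matrix()
        xf = RigidTransform(R, np.array([0.2, -0.1, 0.3]))
        out = resample(vol, xf, fill_value=0.0)
        inv = xf.inverse()

        def trilerp(p):
            z, y, x = p
            if not (0 <= z <= 5 and 0 <= y <= 7 and 0 <= x <= 7):
                return None
            z0, y0, x0 = int(np.floor(z)), int(np.floor(y)), int(np.floor(x))
            z0, y0, x0 = min(z0, 4), min(y0, 6), min(x0, 6)
            fz, fy, fx = z - z0, y - y0, x - x0
            acc = 0.0
            for dz in (0, 1):
                for dy in (0, 1):
                    for dx in (0, 1):
                        w = ((fz if dz else 1 - fz) * (fy if dy else 1 - fy) * (fx if dx else 1 - fx))
                        acc += w * vol.data[z0 + dz, y0 + dy, x0 + dx]
            return acc

        checked = 0
        for z in range(6):
            for y in range(8):
                for x in range(8):
                    src = inv.apply(np.array([z, y, x], dtype=float))
                    expect = trilerp(src)
                    if expect is not None:
                        assert abs(out.data[z, y, x] - expect) <= 1e-6
                        checked += 1
        assert checked > 100


class TestCropResize:
    def test_identity_sizes_unchanged(self, rng):
        vol = VolumeImage(rng.normal(size=(4, 16, 16)))
        out = crop_resize(vol, crop_to=(4, 16, 16), resize_to=(4, 16, 16))
        assert np.array_equal(out.data, vol.data)

    def test_constant_volume_constant_output(self):
        vol = VolumeImage(np.full((4, 20, 20), 7.0))
        out = crop_resize(vol, crop_to=(4, 16, 16), resize_to=(4, 8, 8))
        assert out.shape == (4, 8, 8)
        assert np.allclose(out.data, 7.0)

    def test_linear_ramp_preserved_by_bilinear_resize(self):
        # a plane a*r + b*c + d stays a plane under bilinear interpolation
        r, c = np.mgrid[0:16, 0:16].astype(float)
        sl = 2.0 * r + 3.0 * c + 5.0
        vol = VolumeImage(np.broadcast_to(sl, (2, 16, 16)).copy())
        out = crop_resize(vol, crop_to=(2, 16, 16), resize_to=(2, 8, 8))
        rr, cc = np.mgrid[0:8, 0:8].astype(float)
        # skimage resize maps output px centers to input coords (x+0.5)*scale-0.5
        exp = 2.0 * ((rr + 0.5) * 2 - 0.5) + 3.0 * ((cc + 0.5) * 2 - 0.5) + 5.0
        assert np.allclose(out.data[0], exp, atol=1e-9)

    def test_crop_larger_than_volume_rejected(self):
        vol = VolumeImage(np.zeros((2, 8, 8)))
        with pytest.raises(ValueError, match="larger"):
            crop_resize(vol, crop_to=(2, 16, 16), resize_to=(2, 8, 8))

    def test_slice_count_must_be_preserved(self):
        vol = VolumeImage(np.zeros((4, 8, 8)))
        with pytest.raises(ValueError):
            crop_resize(vol, crop_to=(4, 8, 8), resize_to=(2, 8, 8))


class TestMakeMask:
    def test_uniform_slice_empty(self):
        m = make_mask(VolumeImage(np.zeros((2, 16, 16))))
        assert m.data.sum() == 0

    def test_noisy_disk_dice(self, rng):
        n = 64
        rr, cc = np.mgrid[0:n, 0:n]
        disk = (rr - 32) ** 2 + (cc - 32) ** 2 <= 20**2
        sl = np.where(disk, 1000.0, 0.0) + rng.normal(0, 20, (n, n))
        md = make_mask(VolumeImage(sl[None])).data[0].astype(bool)
        dice = 2 * np.sum(md & disk) / (md.sum() + disk.sum())
        assert dice >= 0.95

    def test_small_blob_removed_by_opening(self):
        n = 48
        rr, cc = np.mgrid[0:n, 0:n]
        big = (rr - 16) ** 2 + (cc - 16) ** 2 <= 12**2
        tiny = (rr - 38) ** 2 + (cc - 38) ** 2 <= 1.0
        sl = np.where(big | tiny, 800.0, 0.0)
        md = make_mask(VolumeImage(sl[None]), opening_radius=3).data[0].astype(bool)
        assert not md[32:46, 32:46].any()  # tiny blob gone
        assert md[16, 16]  # big disk kept
        no_open = make_mask(VolumeImage(sl[None]), opening_radius=0).data[0].astype(bool)
        assert no_open[32:46, 32:46].any()  # kept without opening

    def test_even_window_rejected(self):
        with pytest.raises(ValueError, match="odd"):
            make_mask(VolumeImage(np.zeros((1, 8, 8))), range_window=4)


class TestMaskPair:
    def test_full_masks_unchanged(self, rng):
        a = VolumeImage(rng.normal(size=(2, 8, 8)))
        b = VolumeImage(rng.normal(size=(2, 8, 8)))
        full = MaskVolume(np.ones((2, 8, 8), dtype=np.uint8))
        ao, bo, inter = mask_pair(a, b, full, full)
        assert np.array_equal(ao.data, a.data)
        assert np.array_equal(bo.data, b.data)
        assert inter.data.all()

    def test_disjoint_masks_all_sentinel(self, rng):
        a = VolumeImage(rng.normal(size=(1, 4, 4)))
        b = VolumeImage(rng.normal(size=(1, 4, 4)))
        m1 = np.zeros((1, 4, 4), dtype=np.uint8)
        m1[0, :2] = 1
        m2 = 1 - m1
        ao, bo, inter = mask_pair(a, b, MaskVolume(m1), MaskVolume(m2))
        assert np.all(ao.data == BACKGROUND_SENTINEL)
        assert inter.data.sum() == 0

    def test_outside_set_is_complement_of_intersection(self, rng):
        a = VolumeImage(rng.normal(10, 1, size=(3, 8, 8)))
        b = VolumeImage(rng.normal(10, 1, size=(3, 8, 8)))
        m1 = MaskVolume((rng.random((3, 8, 8)) > 0.5).astype(np.uint8))
        m2 = MaskVolume((rng.random((3, 8, 8)) > 0.5).astype(np.uint8))
        ao, bo, inter = mask_pair(a, b, m1, m2)
        expected = (m1.data & m2.data).astype(bool)
        assert np.array_equal(ao.data == BACKGROUND_SENTINEL, ~expected)
        assert np.array_equal(bo.data == BACKGROUND_SENTINEL, ~expected)
        assert np.array_equal(ao.data[expected], a.data[expected])

    def test_idempotent(self, rng):
        a = VolumeImage(rng.normal(10, 1, size=(2, 6, 6)))
        b = VolumeImage(rng.normal(10, 1, size=(2, 6, 6)))
        m = MaskVolume((rng.random((2, 6, 6)) > 0.4).astype(np.uint8))
        a1, b1, i1 = mask_pair(a, b, m, m)
        a2, b2, i2 = mask_pair(a1, b1, i1, i1)
        assert np.array_equal(a1.data, a2.data)
        assert np.array_equal(b1.data, b2.data)

    def test_shape_mismatch_rejected(self, rng):
        a = VolumeImage(np.zeros((2, 4, 4)))
        b = VolumeImage(np.zeros((2, 4, 5)))
        m = MaskVolume(np.ones((2, 4, 4), dtype=np.uint8))
        with pytest.raises(ValueError):
            mask_pair(a, b, m, m)


def test_landmarks_json_csv_roundtrip(tmp_path):
    lm = default_landmarks()
    lm.save_json(tmp_path / "lm.json")
    lm2 = LandmarkSet.load(tmp_path / "lm.json")
    assert np.allclose(lm.as_array(), lm2.as_array())
    with open(tmp_path / "lm.csv", "w") as fh:
        fh.write("name,z,y,x\n")
        for n, p in lm.points.items():
            fh.write(f"{n},{p[0]},{p[1]},{p[2]}\n")
    lm3 = LandmarkSet.load(tmp_path / "lm.csv")
    assert np.allclose(lm.as_array(), lm3.as_array())
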