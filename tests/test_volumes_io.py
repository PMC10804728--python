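"""DICOM ingestion, geometric resampling, contour rasterization, cropping."""

import numpy as np
import pytest

from dosiofuse.dicom_io import (
    crop_to_roi, rasterize_contours, read_ct_series, read_rtdose,
    read_rtstruct, resample_to_reference,
)
from dosiofuse.grids import ContourSet, ROIMask, VolumeGrid, load_sidecar, save_sidecar
from dosiofuse.phantom import make_phantom_pair, write_dicom_fixture


@pytest.fixture(scope="module")
def dicom_fixture(tmp_path_factory):
    ct, dose, gtv = make_phantom_pair((16, 20, 20), tumor_radius_mm=6.0,
                                      texture_mode="uniform", seed=7)
    # square GTV contours, 10x10 mm at z-slices 6..9; half-integer vertices
    # keep voxel centers strictly inside/outside (no boundary ambiguity)
    contours = []
    for k in (6, 7, 8, 9):
        z = k * 1.0
        contours.append(np.array([
            [3.5, 3.5, z], [13.5, 3.5, z], [13.5, 13.5, z], [3.5, 13.5, z],
        ]))
    out = tmp_path_factory.mktemp("dicom")
    paths = write_dicom_fixture(out, ct, dose=dose, gtv_contours=contours)
    return ct, dose, paths


class TestReadCTSeries:
    def test_rescale_to_hu(self, dicom_fixture):
        ct, _, paths = dicom_fixture
        vol = read_ct_series(paths["ct_dir"])
        # stored = round(HU + 1024); reading must give stored - 1024
        assert vol.modality_tag == "CT"
        np.testing.assert_allclose(vol.data, np.round(ct.data), atol=1e-9)
        assert vol.data.min() == pytest.approx(np.round(ct.data).min())

    def test_file_order_invariance(self, dicom_fixture, tmp_path):
        _, _, paths = dicom_fixture
        ref = read_ct_series(paths["ct_dir"])
        shuffled = tmp_path / "shuffled"
        shuffled.mkdir()
        files = sorted(paths["ct_dir"].iterdir())
        rng = np.random.default_rng(1)
        for f, tag in zip(files, rng.permutation(len(files))):
            (shuffled / f"zz_{tag:03d}.dcm").write_bytes(f.read_bytes())
        vol = read_ct_series(shuffled)
        np.testing.assert_array_equal(vol.data, ref.data)

    def test_missing_slice_reports_position(self, dicom_fixture, tmp_path):
        _, _, paths = dicom_fixture
        broken = tmp_path / "broken"
        broken.mkdir()
        for f in sorted(paths["ct_dir"].iterdir()):
            if not f.name.endswith("005.dcm"):
                (broken / f.name).write_bytes(f.read_bytes())
        with pytest.raises(ValueError, match="missing CT slice"):
            read_ct_series(broken)


class TestReadRTDose:
    def test_roundtrip_values_in_gy(self, dicom_fixture):
        _, dose, paths = dicom_fixture
        vol = read_rtdose(paths["dose"])
        assert vol.modality_tag == "DOSE"
        # written as round(dose/scaling) * scaling on read
        assert np.abs(vol.data - dose.data).max() < dose.data.max() / 30000.0

    def test_scaling_applied(self, tmp_path):
        import pydicom

        _, dose, gtv = make_phantom_pair((16, 16, 16), 5.0, "uniform", seed=0)
        paths = write_dicom_fixture(tmp_path, dose.with_data(np.zeros(dose.shape)),
                                    dose=dose)
        ds = pydicom.dcmread(str(paths["dose"]))
        stored = ds.pixel_array.astype(float)
        vol = read_rtdose(paths["dose"])
        np.testing.assert_allclose(vol.data, stored * float(ds.DoseGridScaling),
                                   rtol=0, atol=1e-12)

    def test_all_zero_grid(self, tmp_path):
        ct, _, _ = make_phantom_pair((16, 16, 16), 5.0, "uniform", seed=0)
        zero = VolumeGrid(np.zeros((16, 16, 16)), spacing=(1, 1, 1),
                          modality_tag="DOSE")
        paths = write_dicom_fixture(tmp_path, ct, dose=zero)
        vol = read_rtdose(paths["dose"])
        assert np.all(vol.data == 0)


class TestResample:
    def test_identity_on_matching_geometry(self, phantom_pair):
        ct, _, _ = phantom_pair
        out = resample_to_reference(ct, ct, interpolation="trilinear")
        np.testing.assert_allclose(out.data, ct.data, rtol=1e-6)
        out_nn = resample_to_reference(ct, ct, interpolation="nearest")
        np.testing.assert_array_equal(out_nn.data, ct.data)

    def test_constant_moving_grid(self):
        const = VolumeGrid(np.full((10, 10, 10), 3.5), spacing=(1, 1, 1))
        ref = VolumeGrid(np.zeros((8, 8, 8)), spacing=(1, 1, 1),
                         origin=(1.0, 1.0, 1.0))
        out = resample_to_reference(const, ref)
        np.testing.assert_allclose(out.data, 3.5)

    def test_integer_shift_equals_index_shift(self, rng):
        data = rng.random((10, 10, 10))
        moving = VolumeGrid(data, spacing=(1, 1, 1), origin=(1.0, 0.0, 0.0))
        ref = VolumeGrid(np.zeros_like(data), spacing=(1, 1, 1), origin=(0, 0, 0))
        out = resample_to_reference(moving, ref)
        # moving origin shifted +1 in x: ref voxel (k,j,i) samples moving (k,j,i-1)
        np.testing.assert_allclose(out.data[:, :, 1:], data[:, :, :-1], atol=1e-12)

    def test_degenerate_orientation_rejected(self, rng):
        bad = VolumeGrid(rng.random((4, 4, 4)), spacing=(1, 1, 1),
                         orientation=np.zeros((3, 3)))
        ref = VolumeGrid(np.zeros((4, 4, 4)), spacing=(1, 1, 1))
        with pytest.raises(ValueError, match="degenerate"):
            resample_to_reference(bad, ref)


class TestRasterize:
    def _ref(self, shape=(6, 20, 20), spacing=(1.0, 1.0, 1.0)):
        return VolumeGrid(np.zeros(shape), spacing=spacing)

    def test_square_contour_voxel_count(self):
        ref = self._ref()
        # 10x10 mm square; voxel centers 3..12 inclusive lie strictly inside
        poly = np.array([[2.5, 2.5, 2.0], [12.5, 2.5, 2.0],
                         [12.5, 12.5, 2.0], [2.5, 12.5, 2.0]])
        cs = ContourSet({"GTV": [poly]})
        mask = rasterize_contours(cs, "GTV", ref)
        assert mask.data[2].sum() == 100
        assert mask.n_voxels == 100

    def test_missing_roi_lists_names(self):
        ref = self._ref()
        poly = np.array([[0, 0, 0], [5, 0, 0], [5, 5, 0]], dtype=float)
        cs = ContourSet({"PTV": [poly]})
        with pytest.raises(ValueError, match="PTV"):
            rasterize_contours(cs, "GTV", ref)
        with pytest.raises(ValueError):
            rasterize_contours(ContourSet(), "GTV", ref)

    def test_two_disjoint_squares_union(self):
        ref = self._ref()
        sq1 = np.array([[0.5, 0.5, 1.0], [4.5, 0.5, 1.0],
                        [4.5, 4.5, 1.0], [0.5, 4.5, 1.0]])
        sq2 = np.array([[10.5, 10.5, 1.0], [14.5, 10.5, 1.0],
                        [14.5, 14.5, 1.0], [10.5, 14.5, 1.0]])
        m1 = rasterize_contours(ContourSet({"GTV": [sq1]}), "GTV", ref)
        m2 = rasterize_contours(ContourSet({"GTV": [sq2]}), "GTV", ref)
        both = rasterize_contours(ContourSet({"GTV": [sq1, sq2]}), "GTV", ref)
        assert both.n_voxels == m1.n_voxels + m2.n_voxels

    def test_mask_volume_converges_with_spacing(self):
        # 10.5 x 10.5 mm square (area 110.25 mm^2) deliberately off-lattice:
        # voxel-count x voxel-area must approach the area as spacing shrinks
        poly = np.array([[2.3, 2.3, 0.0], [12.8, 2.3, 0.0],
                         [12.8, 12.8, 0.0], [2.3, 12.8, 0.0]])
        errors = []
        for sp in (1.0, 0.25):
            n = int(20 / sp)
            ref = VolumeGrid(np.zeros((2, n, n)), spacing=(sp, sp, 1.0))
            mask = rasterize_contours(ContourSet({"GTV": [poly]}), "GTV", ref)
            errors.append(abs(mask.n_voxels * sp * sp - 110.25))
        assert errors[1] < errors[0]
        assert errors[1] < 5.0

    def test_rtstruct_roundtrip(self, dicom_fixture):
        ct, _, paths = dicom_fixture
        cs = read_rtstruct(paths["struct"])
        assert cs.roi_names == ["GTV"]
        ref = VolumeGrid(np.zeros((16, 20, 20)), spacing=(1, 1, 1))
        mask = rasterize_contours(cs, "GTV", ref)
        # 10x10 mm squares on 4 slices; centers 4..13 inclusive inside
        assert mask.n_voxels == 4 * 10 * 10


class TestCrop:
    def test_single_voxel_margin_zero(self):
        vol = VolumeGrid(np.arange(27.0).reshape(3, 3, 3), spacing=(1, 1, 1))
        m = np.zeros((3, 3, 3), bool)
        m[1, 1, 1] = True
        cv, cm = crop_to_roi(vol, ROIMask.from_grid(vol, m), 0)
        assert cv.shape == (1, 1, 1)
        assert cv.data[0, 0, 0] == vol.data[1, 1, 1]

    def test_full_mask_is_identity(self, phantom_pair):
        ct, _, _ = phantom_pair
        full = ROIMask.from_grid(ct, np.ones(ct.shape, bool))
        cv, cm = crop_to_roi(ct, full, 0)
        np.testing.assert_array_equal(cv.data, ct.data)

    def test_centered_mask_with_margin(self):
        vol = VolumeGrid(np.zeros((20, 20, 20)), spacing=(1, 1, 1))
        m = np.zeros((20, 20, 20), bool)
        m[8:13, 8:13, 8:13] = True  # 5x5x5 centered
        cv, cm = crop_to_roi(vol, ROIMask.from_grid(vol, m), 2)
        assert cv.shape == (9, 9, 9)
        assert cm.data.sum() == 125

    def test_patient_coordinates_preserved(self, phantom_pair):
        ct, _, gtv = phantom_pair
        cv, cm = crop_to_roi(ct, gtv, 1)
        pts_before = gtv.index_to_patient(np.argwhere(gtv.data).astype(float))
        pts_after = cm.index_to_patient(np.argwhere(cm.data).astype(float))
        np.testing.assert_allclose(np.sort(pts_before, axis=0),
                                   np.sort(pts_after, axis=0), atol=1e-9)

    def test_empty_mask_rejected(self, phantom_pair):
        ct, _, _ = phantom_pair
        empty = ROIMask.from_grid(ct, np.zeros(ct.shape, bool))
        with pytest.raises(ValueError, match="empty"):
            crop_to_roi(ct, empty, 0)


def test_sidecar_roundtrip(tmp_path, phantom_pair):
    ct, _, gtv = phantom_pair
    save_sidecar(tmp_path / "v", ct)
    save_sidecar(tmp_path / "m", gtv)
    ct2 = load_sidecar(tmp_path / "v")
    gtv2 = load_sidecar(tmp_path / "m")
    np.testing.assert_array_equal(ct2.data, ct.data)
    assert ct2.modality_tag == "CT"
    np.testing.assert_array_equal(gtv2.data, gtv.data)
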