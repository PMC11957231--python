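"""File I/O round trips, intrinsics resampling, and DICOM handling."""

import json

import numpy as np
import pytest
from pydicom.dataset import Dataset, FileMetaDataset
from pydicom.uid import ExplicitVRLittleEndian, generate_uid

from fluoropose.geometry import (
    Intrinsics,
    RadiologicParams,
    pose_from_radiologic,
    radiologic_from_pose,
)
from fluoropose.interface import (
    pose_from_dicom_angles,
    read_fiducials,
    read_pose,
    read_volume,
    read_xray,
    resample_to_intrinsics,
    write_fiducials,
    write_pose,
    write_volume,
    write_xray,
)
from fluoropose.phantom import PhantomSpec, make_phantom
from fluoropose.rendering import Volume3D, XRay2D


class TestVolumeRoundTrip:
    def test_phantom_nifti_round_trip(self, tmp_path):
        vol, _, _ = make_phantom(PhantomSpec(shape=(24,) * 3, seed=1))
        p = tmp_path / "vol.nii.gz"
        write_volume(vol, p)
        back = read_volume(str(p), convert=False)
        assert np.array_equal(back.voxels, vol.voxels)
        assert np.allclose(back.spacing, vol.spacing, atol=1e-6)
        assert np.allclose(back.origin, vol.origin, atol=1e-6)
        assert np.allclose(back.orientation, vol.orientation, atol=1e-6)

    def test_oblique_orientation_preserved(self, tmp_path):
        from scipy.spatial.transform import Rotation

        R = Rotation.from_euler("zyx", [20, -10, 35], degrees=True).as_matrix()
        vol = Volume3D(np.random.default_rng(0).uniform(0, 0.05, (10, 12, 14)),
                       [1.0, 1.5, 2.0], [5.0, -3.0, 8.0], R)
        p = tmp_path / "oblique.nii.gz"
        write_volume(vol, p)
        back = read_volume(str(p), convert=False)
        assert np.allclose(back.orientation, R, atol=1e-6)
        assert np.allclose(back.spacing, vol.spacing, atol=1e-6)
        # same world position of an arbitrary voxel
        assert np.allclose(back.index_to_world([3, 4, 5]),
                           vol.index_to_world([3, 4, 5]), atol=1e-6)

    def test_ct_modality_converts_hounsfield(self, tmp_path):
        vol = Volume3D.centered(np.full((8, 8, 8), 0.0), 1.0, units="mu")
        p = tmp_path / "ct.nii.gz"
        write_volume(vol, p)
        mu = read_volume(str(p), modality="ct", mu_water=0.02)
        assert np.allclose(mu.voxels, 0.02)  # 0 HU = water
        assert mu.units == "mu"


def _dicom_ct_slice(z, rows=8, cols=8, spacing=(1.0, 1.0)):
    ds = Dataset()
    ds.file_meta = FileMetaDataset()
    ds.file_meta.TransferSyntaxUID = ExplicitVRLittleEndian
    ds.file_meta.MediaStorageSOPClassUID = "1.2.840.10008.5.1.4.1.1.2"
    ds.file_meta.MediaStorageSOPInstanceUID = generate_uid()
    ds.SOPClassUID = ds.file_meta.MediaStorageSOPClassUID
    ds.SOPInstanceUID = ds.file_meta.MediaStorageSOPInstanceUID
    ds.Modality = "CT"
    ds.Rows, ds.Columns = rows, cols
    ds.PixelSpacing = list(spacing)
    ds.ImageOrientationPatient = [1, 0, 0, 0, 1, 0]
    ds.ImagePositionPatient = [0.0, 0.0, float(z)]
    ds.RescaleSlope = 1.0
    ds.RescaleIntercept = -1024.0
    ds.BitsAllocated = 16
    ds.BitsStored = 16
    ds.HighBit = 15
    ds.PixelRepresentation = 0
    ds.SamplesPerPixel = 1
    ds.PhotometricInterpretation = "MONOCHROME2"
    arr = np.full((rows, cols), 1024, dtype=np.uint16)
    ds.PixelData = arr.tobytes()
    return ds


class TestDicomSeries:
    def test_uniform_series_reads(self, tmp_path):
        d = tmp_path / "series"
        d.mkdir()
        for i, z in enumerate([0.0, 2.0, 4.0, 6.0]):
            _dicom_ct_slice(z).save_as(d / f"s{i}.dcm", enforce_file_format=True)
        vol = read_volume(str(d), modality="ct", convert=False)
        assert vol.units == "hu"
        assert np.allclose(vol.voxels, 0.0)  # 1024 raw - 1024 intercept
        assert vol.voxels.shape[-1] == 4
        assert vol.spacing[2] == pytest.approx(2.0)

    def test_non_uniform_spacing_rejected(self, tmp_path):
        d = tmp_path / "bad"
        d.mkdir()
        for i, z in enumerate([0.0, 2.0, 7.0]):
            _dicom_ct_slice(z).save_as(d / f"s{i}.dcm", enforce_file_format=True)
        with pytest.raises(ValueError, match="non-uniform"):
            read_volume(str(d), convert=False)


class TestXrayIO:
    @staticmethod
    def _xray(seed=0, n=24):
        rng = np.random.default_rng(seed)
        K = Intrinsics(sdd=1000.0, height=n, width=n, delx=2.0, dely=2.0,
                       x0=1.0, y0=-2.0)
        x = XRay2D(rng.uniform(0, 4, (n, n)), K,
                   true_pose=pose_from_radiologic(RadiologicParams(alpha=7), 700.0))
        x.meta["nominal_sid"] = 700.0
        return x

    def test_tiff_sidecar_round_trip(self, tmp_path):
        x = self._xray()
        p = tmp_path / "xray.tif"
        write_xray(x, p)
        back = read_xray(str(p))
        assert np.allclose(back.pixels, x.pixels, atol=1e-6)  # float32 storage
        assert back.intrinsics == x.intrinsics
        assert back.true_pose.isclose(x.true_pose, atol=1e-9)

    def test_png_windowed_round_trip(self, tmp_path):
        x = self._xray()
        p = tmp_path / "xray.png"
        write_xray(x, p)
        back = read_xray(str(p))
        dyn = x.pixels.max() - x.pixels.min()
        assert np.abs(back.pixels - x.pixels).max() < dyn / 65000
        assert back.intrinsics == x.intrinsics

    def test_missing_sidecar_raises(self, tmp_path):
        import imageio.v3 as iio

        p = tmp_path / "naked.png"
        iio.imwrite(p, np.zeros((8, 8), dtype=np.uint16))
        with pytest.raises(ValueError, match="intrinsics"):
            read_xray(str(p))

    def test_multiframe_dicom_frame_policies(self, tmp_path):
        ds = Dataset()
        ds.file_meta = FileMetaDataset()
        ds.file_meta.TransferSyntaxUID = ExplicitVRLittleEndian
        ds.file_meta.MediaStorageSOPClassUID = "1.2.840.10008.5.1.4.1.1.12.1"
        ds.file_meta.MediaStorageSOPInstanceUID = generate_uid()
        ds.SOPClassUID = ds.file_meta.MediaStorageSOPClassUID
        ds.SOPInstanceUID = ds.file_meta.MediaStorageSOPInstanceUID
        ds.Modality = "XA"
        ds.Rows = ds.Columns = 8
        ds.NumberOfFrames = 4
        ds.ImagerPixelSpacing = [1.5, 1.5]
        ds.DistanceSourceToDetector = 1100.0
        ds.DistanceSourceToPatient = 750.0
        ds.PositionerPrimaryAngle = 25.0
        ds.PositionerSecondaryAngle = -10.0
        ds.BitsAllocated = 16
        ds.BitsStored = 16
        ds.HighBit = 15
        ds.PixelRepresentation = 0
        ds.SamplesPerPixel = 1
        ds.PhotometricInterpretation = "MONOCHROME2"
        frames = np.stack([np.full((8, 8), 100 * (k + 1), dtype=np.uint16)
                           for k in range(4)])
        frames[2, :, :] = 5  # the min-intensity frame
        ds.PixelData = frames.tobytes()
        p = tmp_path / "run.dcm"
        ds.save_as(p, enforce_file_format=True)

        first = read_xray(str(p), frame="first")
        assert first.pixels.mean() == pytest.approx(100.0)
        by_index = read_xray(str(p), frame=1)
        assert by_index.pixels.mean() == pytest.approx(200.0)
        lowest = read_xray(str(p), frame="min-intensity")
        assert lowest.pixels.mean() == pytest.approx(5.0)
        assert first.intrinsics.sdd == 1100.0
        assert first.meta["PositionerPrimaryAngle"] == 25.0


class TestResampling:
    @staticmethod
    def _source(seed=0):
        rng = np.random.default_rng(seed)
        K = Intrinsics(sdd=1000.0, height=32, width=32, delx=4.0, dely=4.0)
        base = rng.uniform(0, 1, (8, 8))
        # smooth source image so interpolation round trips are accurate
        from scipy.ndimage import zoom

        return XRay2D(zoom(base, 4, order=3), K)

    def test_identity_resampling_is_noop(self):
        x = self._source()
        out = resample_to_intrinsics(x, x.intrinsics)
        assert np.allclose(out.pixels, x.pixels, atol=1e-12)

    def test_upsample_then_downsample_recovers(self):
        x = self._source()
        fine = Intrinsics(sdd=1000.0, height=64, width=64, delx=2.0, dely=2.0)
        up = resample_to_intrinsics(x, fine)
        assert up.pixels.shape == (64, 64)
        back = resample_to_intrinsics(up, x.intrinsics)
        interior = back.pixels[2:-2, 2:-2]
        assert np.abs(interior - x.pixels[2:-2, 2:-2]).max() < 0.05

    def test_subextent_equals_crop(self):
        x = self._source()
        # same pixel pitch, central 16x16 window => exact pixel alignment
        target = Intrinsics(sdd=1000.0, height=16, width=16, delx=4.0, dely=4.0)
        out = resample_to_intrinsics(x, target)
        assert np.allclose(out.pixels, x.pixels[8:24, 8:24], atol=1e-12)

    def test_outside_region_zero_filled_and_masked(self):
        x = self._source()
        wide = Intrinsics(sdd=1000.0, height=48, width=48, delx=4.0, dely=4.0)
        out = resample_to_intrinsics(x, wide)
        assert np.all(out.pixels[0, :] == 0.0)
        assert not out.meta["resample_mask"][0, 0]
        assert out.meta["resample_mask"][24, 24]

    def test_sdd_mismatch_rejected(self):
        x = self._source()
        target = Intrinsics(sdd=900.0, height=32, width=32, delx=4.0, dely=4.0)
        with pytest.raises(ValueError, match="re-render"):
            resample_to_intrinsics(x, target)


class TestDicomAngles:
    def test_zero_angles_give_frontal_pose(self):
        pose, K = pose_from_dicom_angles(0.0, 0.0, 750.0, 1200.0)
        frontal = pose_from_radiologic(RadiologicParams(), 750.0)
        assert pose.isclose(frontal, atol=1e-9)
        assert K.sdd == 1200.0

    def test_primary_angle_maps_to_alpha(self):
        pose, _ = pose_from_dicom_angles(30.0, 0.0, 750.0, 1200.0)
        expected = pose_from_radiologic(RadiologicParams(alpha=30.0), 750.0)
        assert pose.isclose(expected, atol=1e-9)

    def test_angles_recoverable_through_inverse_chart(self):
        pose, _ = pose_from_dicom_angles(25.0, -15.0, 800.0, 1100.0)
        p = radiologic_from_pose(pose, 800.0)
        assert p.alpha == pytest.approx(25.0, abs=1e-9)
        assert p.beta == pytest.approx(-15.0, abs=1e-9)


class TestPoseFiducialFiles:
    def test_pose_file_round_trip(self, tmp_path):
        T = pose_from_radiologic(RadiologicParams(12, -7, 2, 3, 4, -5), 700.0)
        p = tmp_path / "pose.json"
        write_pose(T, 700.0, p)
        back, sid = read_pose(p)
        assert sid == 700.0
        assert back.isclose(T, atol=1e-12)
        doc = json.loads(p.read_text())
        assert "matrix" in doc and "radiologic" in doc

    def test_fiducial_file_round_trip(self, tmp_path):
        pts = np.random.default_rng(0).uniform(-50, 50, (8, 3))
        p = tmp_path / "fids.json"
        write_fiducials(pts, p)
        assert np.allclose(read_fiducials(p), pts)
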