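import numpy as np
import pytest

from radfilm.plane_io import (
    PlaneFormatError,
    RegistrationSpec,
    read_plan_plane,
    register_film_to_plan,
    resample_plane,
    write_plane,
)
from radfilm.planes import DosePlane, centered_plane


def _ramp_plane(shape=(21, 31), spacing=1.0):
    """dose(x, y) = 5 + 0.1 x + 0.05 y: bilinear interpolation is exact."""
    plane = centered_plane(np.zeros(shape), spacing, provenance="plan")
    xx, yy = np.meshgrid(plane.x_coords(), plane.y_coords())
    plane.dose_gy = 5.0 + 0.1 * xx + 0.05 * yy
    return plane


class TestTextAndBinaryRoundTrip:
    @pytest.mark.parametrize("fmt,tol", [("text", 1e-6), ("binary", 0.0)])
    def test_dose_round_trip(self, tmp_path, rng, fmt, tol):
        plane = centered_plane(rng.uniform(0, 20, (13, 17)), (0.5, 0.7), provenance="plan")
        suffix = ".txt" if fmt == "text" else ".raw"
        path = write_plane(plane, tmp_path / f"p{suffix}", fmt)
        back = read_plan_plane(path)
        np.testing.assert_allclose(back.dose_gy, plane.dose_gy, atol=tol)
        assert back.pixel_spacing_mm == pytest.approx(plane.pixel_spacing_mm)
        assert back.origin_mm == pytest.approx(plane.origin_mm)

    def test_netod_unit_tag_round_trip(self, tmp_path, rng):
        plane = centered_plane(rng.uniform(0, 0.6, (5, 5)), 0.17, unit="netOD")
        back = read_plan_plane(write_plane(plane, tmp_path / "n.txt", "text"))
        assert back.unit == "netOD"
        np.testing.assert_allclose(back.dose_gy, plane.dose_gy, atol=1e-9)

    def test_tps_export_geometry(self, tmp_path):
        """A 512-pixel plane at 0.39 mm pitch covers 199.68 mm."""
        plane = centered_plane(np.zeros((512, 512)), 0.39, provenance="plan")
        back = read_plan_plane(write_plane(plane, tmp_path / "tps.txt", "text"))
        assert back.shape == (512, 512)
        span_mm = back.shape[1] * back.pixel_spacing_mm[0]
        assert span_mm == pytest.approx(199.68)

    def test_missing_header_rejected(self, tmp_path):
        (tmp_path / "bad.txt").write_text("1 2\n3 4\n")
        with pytest.raises(PlaneFormatError, match="spacing"):
            read_plan_plane(tmp_path / "bad.txt")

    def test_missing_sidecar_rejected(self, tmp_path):
        (tmp_path / "p.raw").write_bytes(b"\0" * 32)
        with pytest.raises(PlaneFormatError, match="sidecar"):
            read_plan_plane(tmp_path / "p.raw")


class TestDicom:
    def _write_rtdose(self, path, stored, scaling, spacing=(0.39, 0.39)):
        import pydicom
        from pydicom.dataset import FileDataset, FileMetaDataset

        meta = FileMetaDataset()
        meta.MediaStorageSOPClassUID = pydicom.uid.RTDoseStorage
        meta.MediaStorageSOPInstanceUID = pydicom.uid.generate_uid()
        meta.TransferSyntaxUID = pydicom.uid.ExplicitVRLittleEndian
        ds = FileDataset(str(path), {}, file_meta=meta, preamble=b"\0" * 128)
        ds.SOPClassUID = pydicom.uid.RTDoseStorage
        ds.Modality = "RTDOSE"
        ds.DoseGridScaling = scaling
        ds.PixelSpacing = [spacing[1], spacing[0]]
        ds.Rows, ds.Columns = stored.shape
        ds.BitsAllocated = 16
        ds.BitsStored = 16
        ds.HighBit = 15
        ds.PixelRepresentation = 0
        ds.SamplesPerPixel = 1
        ds.PhotometricInterpretation = "MONOCHROME2"
        ds.PixelData = stored.astype("<u2").tobytes()
        ds.save_as(path, enforce_file_format=True)

    def test_dose_grid_scaling_applied(self, tmp_path):
        stored = np.full((8, 8), 5000, dtype=np.uint16)
        path = tmp_path / "dose.dcm"
        self._write_rtdose(path, stored, 0.001)
        plane = read_plan_plane(path)
        np.testing.assert_allclose(plane.dose_gy, 5.0)
        assert plane.provenance == "plan"
        assert plane.pixel_spacing_mm == pytest.approx((0.39, 0.39))

    def test_missing_scaling_rejected(self, tmp_path):
        import pydicom
        from pydicom.dataset import FileDataset, FileMetaDataset

        meta = FileMetaDataset()
        meta.MediaStorageSOPClassUID = pydicom.uid.RTDoseStorage
        meta.MediaStorageSOPInstanceUID = pydicom.uid.generate_uid()
        meta.TransferSyntaxUID = pydicom.uid.ExplicitVRLittleEndian
        ds = FileDataset("x", {}, file_meta=meta, preamble=b"\0" * 128)
        ds.save_as(tmp_path / "bad.dcm", enforce_file_format=True)
        with pytest.raises(PlaneFormatError, match="DoseGridScaling"):
            read_plan_plane(tmp_path / "bad.dcm")


class TestResample:
    def test_identity_grid(self):
        plane = _ramp_plane()
        out = resample_plane(plane, target=plane)
        np.testing.assert_allclose(out.dose_gy, plane.dose_gy, atol=1e-12)

    def test_constant_any_spacing(self):
        plane = centered_plane(np.full((11, 11), 7.0), 1.0)
        out = resample_plane(plane, 0.37)
        vals = out.dose_gy[np.isfinite(out.dose_gy)]
        np.testing.assert_allclose(vals, 7.0)

    def test_affine_ramp_exact(self):
        plane = _ramp_plane()
        out = resample_plane(plane, 0.3)
        xx, yy = np.meshgrid(out.x_coords(), out.y_coords())
        expected = 5.0 + 0.1 * xx + 0.05 * yy
        valid = np.isfinite(out.dose_gy)
        assert valid.sum() > 0.9 * out.dose_gy.size
        np.testing.assert_allclose(out.dose_gy[valid], expected[valid], atol=1e-9)

    def test_outside_marked_invalid(self):
        small = centered_plane(np.ones((5, 5)), 1.0)
        big = centered_plane(np.ones((15, 15)), 1.0)
        out = resample_plane(small, target=big)
        assert np.isnan(out.dose_gy[0, 0])
        assert np.isfinite(out.dose_gy[7, 7])

    def test_nearest_method(self):
        plane = centered_plane(np.arange(9.0).reshape(3, 3), 1.0)
        out = resample_plane(plane, target=plane, method="nearest")
        np.testing.assert_array_equal(out.dose_gy, plane.dose_gy)

    def test_bad_spacing(self):
        with pytest.raises(ValueError):
            resample_plane(_ramp_plane(), -1.0)


class TestRegistration:
    def test_identity_spec_equals_resample(self):
        film = _ramp_plane((21, 21), 0.8)
        plan = _ramp_plane((15, 15), 1.0)
        spec = RegistrationSpec(film_center_px=((21 - 1) / 2, (21 - 1) / 2))
        registered, _ = register_film_to_plan(film, plan, spec)
        resampled = resample_plane(film, target=plan)
        both = np.isfinite(registered.dose_gy) & np.isfinite(resampled.dose_gy)
        np.testing.assert_allclose(registered.dose_gy[both], resampled.dose_gy[both], atol=1e-9)

    def test_translation_restores_shifted_film(self):
        plan = _ramp_plane((21, 21), 1.0)
        film = plan.copy()
        xx, yy = np.meshgrid(film.x_coords(), film.y_coords())
        film.dose_gy = 5.0 + 0.1 * (xx - 5.0) + 0.05 * yy  # pattern shifted +5 mm in x
        # fiducial mark compensates: the pattern center sits 5 px to the right
        spec = RegistrationSpec(film_center_px=(10.0, 10.0 + 5.0))
        registered, _ = register_film_to_plan(film, plan, spec)
        both = np.isfinite(registered.dose_gy)
        assert both.sum() > 0.5 * registered.dose_gy.size
        np.testing.assert_allclose(registered.dose_gy[both], plan.dose_gy[both], atol=1e-9)

    def test_90_degree_rotation_restores_axes(self):
        # anisotropic field: wide in x, narrow in y
        base = centered_plane(np.zeros((41, 41)), 1.0, provenance="plan")
        xx, yy = np.meshgrid(base.x_coords(), base.y_coords())
        base.dose_gy = np.where((np.abs(xx) <= 15) & (np.abs(yy) <= 5), 10.0, 0.0)
        # the film recorded the field rotated by 90 degrees (wide in y)
        film = centered_plane(np.where((np.abs(xx) <= 5) & (np.abs(yy) <= 15), 10.0, 0.0), 1.0)
        spec = RegistrationSpec(film_center_px=(20.0, 20.0), rotation_deg=90.0)
        registered, _ = register_film_to_plan(film, base, spec)
        both = np.isfinite(registered.dose_gy)
        np.testing.assert_allclose(registered.dose_gy[both], base.dose_gy[both], atol=1e-9)

    def test_flip_lr(self):
        plan = centered_plane(np.zeros((11, 21)), 1.0, provenance="plan")
        xx, _ = np.meshgrid(plan.x_coords(), plan.y_coords())
        plan.dose_gy = np.clip(xx, 0, None)  # asymmetric in x
        film = plan.copy()
        film.dose_gy = film.dose_gy[:, ::-1].copy()  # mirrored film
        spec = RegistrationSpec(film_center_px=(5.0, 10.0), flip_lr=True)
        registered, _ = register_film_to_plan(film, plan, spec)
        both = np.isfinite(registered.dose_gy)
        np.testing.assert_allclose(registered.dose_gy[both], plan.dose_gy[both], atol=1e-9)

    def test_low_overlap_warns_in_meta(self):
        plan = _ramp_plane((31, 31), 1.0)
        film = centered_plane(np.ones((5, 5)), 1.0)
        spec = RegistrationSpec(film_center_px=(2.0, 2.0))
        registered, _ = register_film_to_plan(film, plan, spec)
        assert "registration_warning" in registered.meta

    def test_rotation_range_enforced(self):
        with pytest.raises(ValueError):
            RegistrationSpec(film_center_px=(0, 0), rotation_deg=270.0)


class TestDosePlaneType:
    def test_rejects_empty_or_bad_spacing(self):
        with pytest.raises(ValueError):
            DosePlane(np.zeros((0, 3)), (1, 1), (0, 0))
        with pytest.raises(ValueError):
            DosePlane(np.zeros((3, 3)), (0, 1), (0, 0))

    def test_coordinate_convention(self):
        plane = DosePlane(np.zeros((3, 5)), (2.0, 1.0), (-4.0, 1.0))
        assert plane.x_coords().tolist() == [-4.0, -2.0, 0.0, 2.0, 4.0]
        assert plane.y_coords().tolist() == [1.0, 0.0, -1.0]  # row 0 on top
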