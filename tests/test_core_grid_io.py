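"""Grid calculus and volume I/O."""

import struct

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from cmflv import (
    BinaryMask,
    GridError,
    LabelField,
    VectorField,
    Volume,
    divergence,
    gradient,
    read_volume,
    write_volume,
)
from cmflv.core_grid_io import FormatError


def brute_force_gradient(a, spacing):
    """Forward differences with zero last face, coded voxel by voxel."""
    out = [np.zeros_like(a) for _ in range(3)]
    nx, ny, nz = a.shape
    for i in range(nx):
        for j in range(ny):
            for k in range(nz):
                if i + 1 < nx:
                    out[0][i, j, k] = (a[i + 1, j, k] - a[i, j, k]) / spacing[0]
                if j + 1 < ny:
                    out[1][i, j, k] = (a[i, j + 1, k] - a[i, j, k]) / spacing[1]
                if k + 1 < nz:
                    out[2][i, j, k] = (a[i, j, k + 1] - a[i, j, k]) / spacing[2]
    return out


class TestGradientDivergence:
    def test_constant_field_has_zero_gradient(self):
        g = gradient(LabelField(np.full((4, 5, 6), 0.7), (1.0, 2.0, 0.5)))
        assert np.all(g.px == 0) and np.all(g.py == 0) and np.all(g.pz == 0)

    def test_linear_ramp_unit_slope(self):
        lam = np.arange(8)[:, None, None] / 7.0 * 7.0  # x-index plane
        lam = np.clip(lam / lam.max(), 0, 1)
        g = gradient(LabelField(lam, (1.0, 1.0, 1.0)))
        assert np.allclose(g.px[:-1], lam[1, 0, 0] - lam[0, 0, 0])
        assert np.all(g.px[-1] == 0)

    def test_matches_brute_force_stencil(self, rng):
        a = rng.random((5, 5, 5))
        sp = (0.8, 1.1, 2.3)
        g = gradient(LabelField(a, sp))
        ox, oy, oz = brute_force_gradient(a, sp)
        np.testing.assert_allclose(g.px, ox, atol=1e-14)
        np.testing.assert_allclose(g.py, oy, atol=1e-14)
        np.testing.assert_allclose(g.pz, oz, atol=1e-14)

    def test_zero_field_zero_divergence(self):
        p = VectorField.zeros((4, 4, 4))
        assert np.all(divergence(p) == 0)

    def test_constant_flow_divergence_boundary_terms(self):
        # div of constant p is zero in the interior; boundary terms carry
        # +p/h on the first slice and -p/h on the last (adjoint convention)
        p = VectorField(np.full((4, 4, 4), 2.0), np.zeros((4, 4, 4)),
                        np.zeros((4, 4, 4)), (0.5, 1.0, 1.0))
        d = divergence(p)
        assert np.allclose(d[1:-1], 0)
        assert np.allclose(d[0], 2.0 / 0.5)
        assert np.allclose(d[-1], -2.0 / 0.5)

    @given(seed=st.integers(0, 2**16),
           nx=st.integers(2, 7), ny=st.integers(1, 7), nz=st.integers(1, 7))
    @settings(max_examples=25, derandomize=True, deadline=None)
    def test_adjointness(self, seed, nx, ny, nz):
        # <grad u, p> + <u, div p> = 0 on arbitrary grids and spacings,
        # including singleton axes
        rng = np.random.default_rng(seed)
        sp = tuple(rng.uniform(0.5, 3.0, 3))
        u = rng.random((nx, ny, nz))
        p = VectorField(*rng.standard_normal((3, nx, ny, nz)), sp)
        g = gradient(LabelField(u, sp))
        forward = np.sum(g.px * p.px + g.py * p.py + g.pz * p.pz)
        adjoint = np.sum(u * divergence(p))
        assert abs(forward + adjoint) < 1e-10 * (1 + abs(forward))

    def test_dimension_mismatch_raises(self):
        with pytest.raises(GridError):
            VectorField(np.zeros((3, 3, 3)), np.zeros((3, 3, 3)),
                        np.zeros((3, 3, 4)))


class TestDomainTypes:
    def test_volume_invariants(self):
        with pytest.raises(GridError):
            Volume(np.zeros((4, 4, 4)), spacing=(1, -1, 1))
        with pytest.raises(GridError):
            Volume(np.full((4, 4, 4), np.nan))

    def test_label_field_range_enforced(self):
        with pytest.raises(GridError):
            LabelField(np.full((3, 3, 3), 1.5))

    def test_binary_mask_values(self):
        with pytest.raises(GridError):
            BinaryMask(np.full((3, 3, 3), 2))
        m = BinaryMask(np.eye(3)[None].repeat(3, 0))
        assert set(np.unique(m.mask)) <= {0, 1}


class TestVolumeIO:
    def test_interfile_round_trip_bit_identical(self, tmp_path, rng):
        vol = Volume(rng.random((8, 8, 8)).astype(np.float32),
                     (4.8, 4.8, 4.8), (1.0, -2.0, 3.0))
        p = str(tmp_path / "vol.hdr")
        write_volume(vol, p, format="interfile")
        back = read_volume(p, format="interfile")
        np.testing.assert_array_equal(back.data.astype(np.float32),
                                      vol.data.astype(np.float32))
        assert back.spacing == vol.spacing
        assert back.origin == vol.origin

    def test_interfile_write_is_deterministic(self, tmp_path, rng):
        vol = Volume(rng.random((4, 4, 4)).astype(np.float32))
        pa, pb = str(tmp_path / "a.hdr"), str(tmp_path / "b.hdr")
        write_volume(vol, pa, format="interfile")
        write_volume(vol, pb, format="interfile")
        assert (tmp_path / "a.img").read_bytes() == (tmp_path / "b.img").read_bytes()

    def test_minimal_interfile_fixture(self, tmp_path):
        # authored independently of write_volume: header text + packed bytes
        hdr = tmp_path / "mini.hdr"
        hdr.write_text(
            "!INTERFILE :=\n"
            "name of data file := mini.img\n"
            "number format := unsigned integer\n"
            "number of bytes per pixel := 2\n"
            "data offset in bytes := 0\n"
            "matrix size [1] := 2\n"
            "matrix size [2] := 2\n"
            "matrix size [3] := 2\n"
            "scaling factor (mm/pixel) [1] := 4.8\n"
            "scaling factor (mm/pixel) [2] := 4.8\n"
            "scaling factor (mm/pixel) [3] := 4.8\n"
        )
        # x varies fastest: value = i + 2j + 4k
        (tmp_path / "mini.img").write_bytes(struct.pack("<8H", *range(8)))
        vol = read_volume(str(hdr), format="interfile")
        expect = np.array([[[0, 4], [2, 6]], [[1, 5], [3, 7]]], dtype=float)
        np.testing.assert_array_equal(vol.data, expect)
        assert vol.spacing == (4.8, 4.8, 4.8)

    def test_interfile_missing_key_raises(self, tmp_path):
        hdr = tmp_path / "bad.hdr"
        hdr.write_text("!INTERFILE :=\nmatrix size [1] := 2\n")
        with pytest.raises(FormatError, match="mandatory key"):
            read_volume(str(hdr), format="interfile")

    def test_nifti_round_trip_preserves_spacing(self, tmp_path, rng):
        vol = Volume(rng.random((6, 5, 4)), (4.8, 4.8, 4.8), (0.0, 0.0, 0.0))
        p = str(tmp_path / "vol.nii")
        write_volume(vol, p)
        back = read_volume(p)
        np.testing.assert_allclose(back.spacing, (4.8, 4.8, 4.8), rtol=1e-6)
        np.testing.assert_allclose(back.data, vol.data, atol=1e-6)

    def test_overwrite_requires_flag(self, tmp_path, rng):
        vol = Volume(rng.random((4, 4, 4)))
        p = str(tmp_path / "vol.nii")
        write_volume(vol, p)
        with pytest.raises(FileExistsError):
            write_volume(vol, p)
        write_volume(vol, p, overwrite=True)

    def test_unknown_format_rejected(self, tmp_path, rng):
        vol = Volume(rng.random((4, 4, 4)))
        with pytest.raises(FormatError):
            write_volume(vol, str(tmp_path / "x.xyz"), format="analyze")

    def test_dicom_series_read(self, tmp_path, rng):
        pydicom = pytest.importorskip("pydicom")
        from pydicom.dataset import Dataset, FileMetaDataset
        from pydicom.uid import ExplicitVRLittleEndian, generate_uid

        data = (rng.random((4, 4, 3)) * 1000).astype(np.uint16)
        for k in range(3):
            ds = Dataset()
            ds.file_meta = FileMetaDataset()
            ds.file_meta.TransferSyntaxUID = ExplicitVRLittleEndian
            ds.file_meta.MediaStorageSOPClassUID = generate_uid()
            ds.file_meta.MediaStorageSOPInstanceUID = generate_uid()
            ds.SOPClassUID = ds.file_meta.MediaStorageSOPClassUID
            ds.SOPInstanceUID = ds.file_meta.MediaStorageSOPInstanceUID
            ds.InstanceNumber = k + 1
            ds.Rows, ds.Columns = 4, 4
            ds.PixelSpacing = [4.8, 4.8]
            ds.SliceThickness = 4.8
            ds.BitsAllocated, ds.BitsStored, ds.HighBit = 16, 16, 15
            ds.PixelRepresentation = 0
            ds.SamplesPerPixel = 1
            ds.PhotometricInterpretation = "MONOCHROME2"
            ds.PixelData = data[:, :, k].T.tobytes()  # rows=y, cols=x
            ds.save_as(str(tmp_path / f"slice{k}.dcm"), enforce_file_format=True)
        vol = read_volume(str(tmp_path), format="dicom_series")
        assert vol.shape == (4, 4, 3)
        assert vol.spacing == (4.8, 4.8, 4.8)
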