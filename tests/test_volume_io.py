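import numpy as np
import pytest
import SimpleITK as sitk

from coroseg.centerline import (Centerline, Branch, read_centerline,
                                resample_centerline, write_centerline)
from coroseg.errors import ContentError, FormatError, ParameterError
from coroseg.volume import CTVolume, read_volume, resample_isotropic, write_mask, write_volume


@pytest.mark.parametrize("suffix", [".nii.gz", ".nrrd"])
def test_volume_round_trip_identity(tmp_path, rng, suffix):
    vol = CTVolume(rng.normal(100, 300, (10, 12, 14)),
                   spacing=(0.5, 0.5, 0.62), origin=(1.0, -2.0, 3.0))
    path = tmp_path / f"vol{suffix}"
    write_volume(vol, path)
    back = read_volume(path)
    np.testing.assert_array_equal(back.voxels, vol.voxels)
    np.testing.assert_allclose(back.spacing, vol.spacing)
    np.testing.assert_allclose(back.origin, vol.origin)


def test_read_volume_rejects_2d(tmp_path):
    img = sitk.GetImageFromArray(np.zeros((8, 8), dtype=np.float32))
    path = tmp_path / "flat.nii.gz"
    sitk.WriteImage(img, str(path))
    with pytest.raises(FormatError):
        read_volume(path)


def test_read_volume_missing_file(tmp_path):
    with pytest.raises(FormatError):
        read_volume(tmp_path / "nothing.nrrd")


def test_mask_round_trip(tmp_path, rng):
    ref = CTVolume(np.zeros((6, 7, 8)), np.full(3, 0.25))
    grid = rng.random((6, 7, 8)) > 0.5
    path = tmp_path / "mask.nrrd"
    write_mask(grid, ref, path)
    back = read_volume(path)
    np.testing.assert_array_equal(back.voxels.astype(bool), grid)


def test_write_mask_shape_mismatch(tmp_path):
    ref = CTVolume(np.zeros((6, 7, 8)), np.full(3, 0.25))
    from coroseg.errors import GeometryError
    with pytest.raises(GeometryError):
        write_mask(np.zeros((5, 7, 8), dtype=bool), ref, tmp_path / "m.nrrd")


def test_resample_constant_volume():
    vol = CTVolume(np.full((10, 10, 10), 250.0), (0.5, 0.5, 0.62))
    out = resample_isotropic(vol, 0.25)
    np.testing.assert_allclose(out.spacing, 0.25)
    np.testing.assert_allclose(out.voxels, 250.0)


def test_resample_linear_ramp_matches_analytic():
    # HU = 10 * z_mm: linear interpolation reproduces the ramp exactly at the
    # new voxel centres.
    shape = (6, 6, 20)
    z_mm = np.arange(shape[2]) * 0.62
    vox = np.broadcast_to(10.0 * z_mm, shape).copy()
    vol = CTVolume(vox, (0.5, 0.5, 0.62))
    out = resample_isotropic(vol, 0.25)
    new_z = np.arange(out.shape[2]) * 0.25
    expected = np.broadcast_to(10.0 * new_z, out.shape)
    np.testing.assert_allclose(out.voxels, expected, atol=1e-9)
    # world extent preserved within one voxel
    assert abs(out.shape[2] * 0.25 - shape[2] * 0.62) < 0.62 + 0.25


def test_resample_idempotent_at_target(rng):
    vol = CTVolume(rng.normal(size=(8, 8, 8)), np.full(3, 0.25))
    assert resample_isotropic(vol, 0.25) is vol
    with pytest.raises(ParameterError):
        resample_isotropic(vol, -1.0)


def test_centerline_csv_round_trip_and_tangents(tmp_path):
    pts = np.column_stack([np.zeros(5), np.zeros(5), np.arange(5) * 0.25])
    cl = Centerline([Branch(1, None, pts)])
    path = tmp_path / "cl.csv"
    write_centerline(cl, path)
    back = read_centerline(path)
    assert len(back) == 1 and back.branches[0].parent_id is None
    np.testing.assert_allclose(back.branches[0].tangents,
                               np.tile([0, 0, 1.0], (5, 1)))


def test_centerline_missing_column(tmp_path):
    path = tmp_path / "bad.csv"
    path.write_text("branch_id,x_mm,y_mm,z_mm\n1,0,0,0\n1,0,0,1\n")
    with pytest.raises(FormatError):
        read_centerline(path)


def test_centerline_single_point_branch_rejected(tmp_path):
    path = tmp_path / "short.csv"
    path.write_text("branch_id,parent_id,point_index,x_mm,y_mm,z_mm\n1,-1,0,0,0,0\n")
    with pytest.raises(ContentError):
        read_centerline(path)


def test_branch_linkage_preserved(tmp_path):
    rows = ["branch_id,parent_id,point_index,x_mm,y_mm,z_mm"]
    for i in range(3):
        rows.append(f"1,-1,{i},0,0,{i * 0.25}")
    for i in range(3):
        rows.append(f"2,1,{i},{i * 0.25},0,0.5")
    path = tmp_path / "tree.csv"
    path.write_text("\n".join(rows) + "\n")
    cl = read_centerline(path)
    assert {b.branch_id: b.parent_id for b in cl} == {1: None, 2: 1}


def test_circle_tangents_orthogonal_to_radius():
    theta = np.arange(0, 2 * np.pi, 0.25 / 5.0)  # 5 mm radius, 0.25 mm steps
    pts = np.column_stack([5 * np.cos(theta), 5 * np.sin(theta),
                           np.zeros_like(theta)])
    b = Branch(1, None, pts)
    radial = pts / np.linalg.norm(pts, axis=1, keepdims=True)
    dots = np.abs(np.sum(b.tangents * radial, axis=1))
    # central differences are second order; the one-sided endpoints are not
    assert dots[1:-1].max() < 1e-3


def test_resample_segment_arithmetic():
    pts = np.array([[0, 0, 0.0], [0, 0, 1.0]])
    out = resample_centerline(Centerline([Branch(1, None, pts)]), 0.25)
    b = out.branches[0]
    assert len(b) == 5
    np.testing.assert_allclose(np.diff(b.points[:, 2]), 0.25)


def test_resample_preserves_endpoints_and_compliance():
    pts = np.array([[0, 0, 0], [0.1, 0, 0.1], [0.2, 0.1, 0.2]])
    out = resample_centerline(Centerline([Branch(1, None, pts)]), 0.25)
    b = out.branches[0]
    np.testing.assert_array_equal(b.points[0], pts[0])
    np.testing.assert_array_equal(b.points[-1], pts[-1])
    assert len(b) == len(pts)  # already compliant: unchanged


def test_resample_step_bound_and_arclength_over_random_polylines(rng):
    # spacing never exceeds the bound and total arclength is preserved
    for _ in range(1000):
        n = int(rng.integers(2, 8))
        pts = rng.uniform(0, 10, (n, 3))
        before = np.linalg.norm(np.diff(pts, axis=0), axis=1).sum()
        out = resample_centerline(Centerline([Branch(1, None, pts)]), 0.25)
        steps = np.linalg.norm(np.diff(out.branches[0].points, axis=0), axis=1)
        assert steps.max() <= 0.25 + 1e-12
        assert abs(steps.sum() - before) < 1e-6
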