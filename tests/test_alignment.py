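import math
from types import SimpleNamespace

import numpy as np
import pytest

import blockstack as bs
from blockstack.alignment import alignments_to_csv, border_median_color

from conftest import relative_truth


def _fids(centers, dims=(600, 400), slice_index=0):
    dets = [bs.MarkerDetection(center=(float(x), float(y)), radius=10.0, score=1.0)
            for x, y in centers]
    return bs.assign_corners(dets, dims, slice_index=slice_index)


CORNERS_PX = [(50, 50), (550, 50), (50, 350), (550, 350)]


def test_magnification_identity_and_forced_shrink():
    ref = _fids(CORNERS_PX)
    assert bs.compute_magnification(ref, ref) == pytest.approx(1.0, abs=0)
    center = np.array([299.5, 199.5])
    shrunk = [(tuple(center + 0.5 * (np.array(c) - center))) for c in CORNERS_PX]
    assert bs.compute_magnification(_fids(shrunk), ref) == pytest.approx(2.0, abs=1e-9)


def test_magnification_degenerate_geometry_rejected():
    ref = _fids(CORNERS_PX)
    tiny = [(299.5, 199.5), (300.0, 199.5), (299.5, 200.0), (300.2, 200.2)]
    dets = [bs.MarkerDetection(center=c, radius=0.1, score=1.0) for c in tiny]
    # bypass quadrant checks: construct the set directly around the center
    src = bs.FiducialSet(0, dict(zip(("TL", "TR", "BL", "BR"), dets)), (600, 400))
    with pytest.raises(bs.DegenerateGeometryError):
        bs.compute_magnification(src, ref)


def test_magnification_tracks_drift_model(stack600, fids600):
    _, records = stack600
    for i in (2, 5):
        est = bs.compute_magnification(fids600[i], fids600[0])
        true_ratio = records[0].true_transform.scale / records[i].true_transform.scale
        assert est == pytest.approx(true_ratio, abs=1e-3)


def test_rigid_fit_identity_and_pure_rotation():
    ref = _fids(CORNERS_PX)
    fit = bs.estimate_rigid(ref, ref, 1.0)
    assert fit.transform.is_identity(atol=1e-12)
    assert fit.rms_residual_px == pytest.approx(0.0, abs=1e-12)

    rot = bs.SimilarityTransform.about_point(1.0, math.radians(5.0), (299.5, 199.5))
    src = _fids([tuple(rot.apply(np.array(c, float))) for c in CORNERS_PX])
    fit = bs.estimate_rigid(src, ref, 1.0)
    assert fit.transform.rotation_rad == pytest.approx(-math.radians(5.0), abs=1e-9)
    assert fit.rms_residual_px < 1e-6


def test_rigid_fit_rejects_near_coincident_markers():
    ref = _fids(CORNERS_PX)
    # four markers within half a pixel of the image center, one per quadrant
    tight = [(299.9, 199.9), (300.1, 199.9), (299.9, 200.1), (300.1, 200.1)]
    dets = [bs.MarkerDetection(center=c, radius=0.1, score=1.0) for c in tight]
    src = bs.FiducialSet(0, dict(zip(("TL", "TR", "BL", "BR"), dets)), (600, 400))
    with pytest.raises(bs.DegenerateGeometryError):
        bs.estimate_rigid(src, ref, 1.0)


def test_rigid_fit_matches_rotation_grid_search_oracle():
    """Closed-form LSQ vs brute force over rotation at 1e-4 rad + analytic translation."""
    rng = np.random.default_rng(42)
    true = bs.SimilarityTransform(1.04, rng.uniform(-0.2, 0.2),
                                  tuple(rng.uniform(-20, 20, 2)))
    p = np.array(CORNERS_PX, dtype=float)
    q = true.apply(p)
    src = _fids(p)
    # target corners need not sit in canonical quadrants for the fit itself
    ref = SimpleNamespace(centers=lambda: q)
    scale = bs.compute_magnification(src, ref)
    fit = bs.estimate_rigid(src, ref, scale)

    step = 1e-4
    thetas = np.arange(-math.pi, math.pi, step)
    c, s = np.cos(thetas), np.sin(thetas)
    pc = p - p.mean(axis=0)
    qc = q - q.mean(axis=0)
    # residual for each candidate rotation with the analytic best translation
    rx = scale * (c[:, None] * pc[:, 0] - s[:, None] * pc[:, 1]) - qc[:, 0]
    ry = scale * (s[:, None] * pc[:, 0] + c[:, None] * pc[:, 1]) - qc[:, 1]
    sse = (rx ** 2 + ry ** 2).sum(axis=1)
    best_theta = thetas[np.argmin(sse)]
    assert abs(fit.transform.rotation_rad - best_theta) <= step
    assert abs(fit.transform.scale - true.scale) < 1e-9
    assert fit.rms_residual_px < 1e-6


def test_scale_is_taken_as_given_not_refit():
    ref = _fids(CORNERS_PX)
    fit = bs.estimate_rigid(ref, ref, 1.2345)
    assert fit.transform.scale == 1.2345


def test_joint_similarity_fit_agrees_on_noiseless_points():
    true = bs.SimilarityTransform(0.97, 0.02, (8.0, -6.0))
    p = np.array(CORNERS_PX, dtype=float)
    src, ref = _fids(p), _fids(true.apply(p))
    fit = bs.estimate_similarity(src, ref)
    assert fit.transform.scale == pytest.approx(true.scale, abs=1e-12)
    assert fit.transform.rotation_rad == pytest.approx(true.rotation_rad, abs=1e-12)
    assert fit.rms_residual_px < 1e-9


def test_residual_matches_independent_recomputation(stack600, fids600):
    scale = bs.compute_magnification(fids600[3], fids600[0])
    fit = bs.estimate_rigid(fids600[3], fids600[0], scale)
    res = fit.transform.apply(fids600[3].centers()) - fids600[0].centers()
    rms = math.sqrt(float((res ** 2).sum(axis=1).mean()))
    assert abs(rms - fit.rms_residual_px) < 1e-9


def test_apply_identity_transform_is_byte_exact(stack600):
    images, _ = stack600
    img = images[0]
    out = bs.apply_transform(img, bs.SimilarityTransform.identity(), img.dims)
    assert np.array_equal(out.pixels[2:-2, 2:-2], img.pixels[2:-2, 2:-2])


def test_apply_integer_translation_is_exact(stack600):
    images, _ = stack600
    img = images[0]
    t = bs.SimilarityTransform(1.0, 0.0, (7.0, -5.0))
    out = bs.apply_transform(img, t, img.dims)
    # output[y, x] = input[y + 5, x - 7] for in-range pixels
    assert np.array_equal(out.pixels[:-5, 7:], img.pixels[5:, :-7])


def test_apply_non_integer_transform_fills_border_with_paraffin(stack600):
    images, _ = stack600
    img = images[0]
    t = bs.SimilarityTransform(1.0, 0.001, (150.5, 0.25))
    out = bs.apply_transform(img, t, img.dims)
    fill = border_median_color(img)
    # the left strip now maps outside the source: filled with paraffin-like color
    strip = out.pixels[100:300, :140].reshape(-1, 3).mean(axis=0)
    assert np.abs(strip - np.array(fill)).max() < 3


def test_aligned_stack_markers_land_on_reference(stack600, fids600, radius_range600):
    images, _ = stack600
    aligned, results = bs.align_stack(images, fids600)
    assert results[0].transform.is_identity()
    ref_centers = fids600[0].centers()
    for i in (1, 3, 5):
        fs = bs.detect_fiducials(aligned[i], radius_range600, slice_index=i)
        rms = np.sqrt(((fs.centers() - ref_centers) ** 2).sum(axis=1).mean())
        assert rms <= 0.5
        assert results[i].rms_residual_px <= 0.5


def test_estimated_transforms_match_ground_truth(stack600, fids600):
    _, records = stack600
    for i in range(1, 6):
        scale = bs.compute_magnification(fids600[i], fids600[0])
        fit = bs.estimate_rigid(fids600[i], fids600[0], scale)
        truth = relative_truth(records, i)
        assert abs(fit.transform.scale - truth.scale) < 1e-3
        assert abs(fit.transform.rotation_rad - truth.rotation_rad) < math.radians(0.1)
        t_err = np.abs(np.array(fit.transform.translation) -
                       np.array(truth.translation))
        assert t_err.max() < 0.5


def test_alignment_csv_export(tmp_path, stack600, fids600):
    images, _ = stack600
    _, results = bs.align_stack(images, fids600)
    path = tmp_path / "transforms.csv"
    alignments_to_csv(results, path)
    lines = path.read_text().strip().splitlines()
    assert len(lines) == 1 + len(results)
    assert lines[0] == "slice_index,scale,rotation_deg,tx,ty,rms_residual_px"
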