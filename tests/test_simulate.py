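import math

import numpy as np
import pytest

import blockstack as bs
from blockstack.simulate import marker_positions_px, render_labels, render_slice

from conftest import relative_truth


def test_same_seed_gives_bit_identical_stacks(params600, phantom):
    a, _ = bs.generate_stack(params600, phantom, 3, bs.JitterSpec(), seed=11)
    b, _ = bs.generate_stack(params600, phantom, 3, bs.JitterSpec(), seed=11)
    for ia, ib in zip(a, b):
        assert np.array_equal(ia.pixels, ib.pixels)


def test_no_jitter_no_drift_yields_identical_slices(params600):
    # constant specimen outline: shape modulation is a phantom property, off here
    static = bs.PhantomSpec(shape_modulation_amp=0.0)
    images, records = bs.generate_stack(params600, static, 4, bs.JitterSpec.none(),
                                        seed=5)
    for img, rec in zip(images[1:], records[1:]):
        assert np.array_equal(img.pixels, images[0].pixels)
        assert rec.true_transform.is_identity()


def test_slice_spacing_follows_cut_schedule():
    p = bs.AcquisitionParams(cut_thickness_um=20, photo_every_k=10)
    assert p.slice_spacing_mm == pytest.approx(0.2)


def test_marker_centers_equal_hand_applied_transform(params600, phantom):
    """Stored centers must equal s·R·p + t evaluated with plain trigonometry."""
    _, records = bs.generate_stack(params600, phantom, 5, bs.JitterSpec(), seed=7)
    nominal = marker_positions_px(phantom, params600)
    for rec in records:
        t = rec.true_transform
        c, s = math.cos(t.rotation_rad), math.sin(t.rotation_rad)
        for (px, py), (mx, my) in zip(nominal, rec.marker_centers_px):
            assert abs(t.scale * (c * px - s * py) + t.translation[0] - mx) < 1e-9
            assert abs(t.scale * (s * px + c * py) + t.translation[1] - my) < 1e-9


def test_intermarker_distance_strictly_decreases_with_drift(params600, phantom):
    jitter = bs.JitterSpec(rotation_deg=(0, 0), translation_px=(0, 0),
                           exposure_gain=(1, 1), wb_tint=(1, 1), d0_mm=500.0)
    _, records = bs.generate_stack(params600, phantom, 6, jitter, seed=0)
    means = []
    for rec in records:
        centers = np.asarray(rec.marker_centers_px)
        diffs = centers[:, None, :] - centers[None, :, :]
        d = np.sqrt((diffs ** 2).sum(-1))
        means.append(d[np.triu_indices(4, 1)].mean())
    assert all(a > b for a, b in zip(means, means[1:]))


def test_out_of_frame_jitter_rejected(params600, phantom):
    huge = bs.JitterSpec(translation_px=(500.0, 500.0))
    with pytest.raises(ValueError, match="out of frame"):
        bs.generate_stack(params600, phantom, 2, huge, seed=0)
    with pytest.raises(ValueError, match="n_slices"):
        bs.generate_stack(params600, phantom, 1, bs.JitterSpec(), seed=0)


def _truth(phantom, params, **overrides):
    t = overrides.pop("transform", bs.SimilarityTransform.identity())
    centers = t.apply(marker_positions_px(phantom, params))
    return bs.GroundTruthRecord(
        slice_index=overrides.pop("slice_index", 0),
        true_transform=t,
        exposure_gain=overrides.pop("exposure_gain", 1.0),
        wb_tint=overrides.pop("wb_tint", (1.0, 1.0, 1.0)),
        marker_centers_px=tuple((float(x), float(y)) for x, y in centers),
    )


def test_marker_pixels_are_darkest(params600, phantom):
    img = render_slice(phantom, params600, _truth(phantom, params600))
    for cx, cy in marker_positions_px(phantom, params600):
        assert img.pixels[int(round(cy)), int(round(cx))].max() <= 30
    labels = render_labels(phantom, params600, bs.SimilarityTransform.identity(), 0)
    marker_max = int(img.pixels[labels == 4].max())
    non_marker_min = (img.pixels[labels != 4].astype(int).sum(axis=-1)).min()
    assert marker_max * 3 < non_marker_min


def test_exposure_gain_doubles_flat_pixels(params600, phantom):
    base = render_slice(phantom, params600, _truth(phantom, params600))
    doubled = render_slice(phantom, params600,
                           _truth(phantom, params600, exposure_gain=2.0))
    palette = [phantom.paraffin_rgb, phantom.marker_rgb, *phantom.territory_colors]
    flat = np.zeros(base.pixels.shape[:2], dtype=bool)
    for col in palette:
        flat |= (base.pixels == np.array(col, dtype=np.uint8)).all(axis=-1)
    assert flat.mean() > 0.9  # interiors dominate the frame
    b = base.pixels[flat].astype(int)
    d = doubled.pixels[flat].astype(int)
    unsaturated = 2 * b <= 255
    assert np.array_equal(d[unsaturated], 2 * b[unsaturated])


def test_wb_tint_scales_paraffin_channel_ratio(params600, phantom):
    neutral = render_slice(phantom, params600, _truth(phantom, params600))
    tinted = render_slice(phantom, params600,
                          _truth(phantom, params600, wb_tint=(1.1, 1.0, 0.9)))
    labels = render_labels(phantom, params600, bs.SimilarityTransform.identity(), 0)
    paraffin = labels == 0
    ratio0 = (neutral.pixels[paraffin, 0].mean() / neutral.pixels[paraffin, 2].mean())
    ratio1 = (tinted.pixels[paraffin, 0].mean() / tinted.pixels[paraffin, 2].mean())
    assert ratio1 / ratio0 == pytest.approx(1.1 / 0.9, rel=0.01)


def test_ground_truth_sidecar_roundtrip(tmp_path, params600, phantom, stack600):
    images, records = stack600
    bs.save_stack(tmp_path, images, records)
    loaded = bs.load_stack(tmp_path, params600.pixel_size_mm)
    assert len(loaded) == len(images)
    assert np.array_equal(loaded[2].pixels, images[2].pixels)
    recs = bs.load_ground_truth(tmp_path / "ground_truth.json")
    for a, b in zip(recs, records):
        assert a.true_transform.scale == pytest.approx(b.true_transform.scale)
        np.testing.assert_allclose(np.asarray(a.marker_centers_px),
                                   np.asarray(b.marker_centers_px), atol=1e-12)


def test_phantom_validation_rejects_bad_specs():
    with pytest.raises(ValueError, match="distinguishable"):
        bs.PhantomSpec(territory_colors=((10, 10, 10), (20, 20, 20), (200, 0, 0)))
    with pytest.raises(ValueError, match="inside the specimen"):
        bs.PhantomSpec(marker_positions_mm=((75, 50), (138, 12), (12, 88), (138, 88)))
    with pytest.raises(ValueError, match="non-square"):
        bs.AcquisitionParams(fov_mm=(150, 100), resolution_px=(6000, 4200))


def test_relative_truth_helper_is_consistent(stack600):
    """Sanity of the test helper itself: T_rel maps slice-i marker centers onto slice 0's."""
    _, records = stack600
    rel = relative_truth(records, 3)
    mapped = rel.apply(np.asarray(records[3].marker_centers_px))
    np.testing.assert_allclose(mapped, np.asarray(records[0].marker_centers_px),
                               atol=1e-9)
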