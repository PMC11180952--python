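import math

import numpy as np
import pytest
from hypothesis import settings

import blockstack as bs

settings.register_profile("suite", derandomize=True, max_examples=50)
settings.load_profile("suite")


@pytest.fixture(scope="session")
def params600() -> bs.AcquisitionParams:
    """Small 600x400 px frame over the standard 150x100 mm FOV (0.25 mm pixels)."""
    return bs.AcquisitionParams(resolution_px=(600, 400), photo_every_k=25,
                                target_voxel_mm=0.5)


@pytest.fixture(scope="session")
def phantom() -> bs.PhantomSpec:
    return bs.PhantomSpec()


@pytest.fixture(scope="session")
def radius_range600(params600, phantom):
    nominal = phantom.marker_radius_mm / params600.pixel_size_mm
    return (0.7 * nominal, 1.3 * nominal)


@pytest.fixture(scope="session")
def stack600(params600, phantom):
    """Six jittered slices with drift, plus ground truth (seed 7)."""
    images, records = bs.generate_stack(params600, phantom, 6, bs.JitterSpec(), seed=7)
    return images, records


@pytest.fixture(scope="session")
def fids600(stack600, radius_range600):
    images, _ = stack600
    return [bs.detect_fiducials(img, radius_range600, slice_index=i)
            for i, img in enumerate(images)]


def draw_disk(shape, center, radius, fg=0.0, bg=255.0, supersample=8):
    """Anti-aliased disk rendered analytically — independent of the simulator."""
    h, w = shape
    ss = supersample
    ys = (np.arange(h * ss) + 0.5) / ss - 0.5
    xs = (np.arange(w * ss) + 0.5) / ss - 0.5
    gx, gy = np.meshgrid(xs, ys)
    inside = (gx - center[0]) ** 2 + (gy - center[1]) ** 2 <= radius ** 2
    img = np.where(inside, fg, bg)
    return img.reshape(h, ss, w, ss).mean(axis=(1, 3))


def gray_to_rgb_raster(gray, pixel_size_mm=0.1):
    px = bs.quantize_u8(np.repeat(gray[..., None], 3, axis=2))
    return bs.RasterImage(px, pixel_size_mm)


def template_match_circle(gray, radii):
    """Brute-force oracle: normalized matched filter over all integer centers/radii.

    Correlates the inverted image with a unit-energy disk template of each
    candidate radius and returns (x, y, radius) of the global best match.
    """
    from scipy.signal import fftconvolve

    inv = gray.max() - gray
    best = None
    for r in radii:
        ys, xs = np.mgrid[-r:r + 1, -r:r + 1]
        disk = ((xs ** 2 + ys ** 2) <= r ** 2).astype(float)
        tmpl = disk / math.sqrt(disk.sum())
        corr = fftconvolve(inv, tmpl[::-1, ::-1], mode="same")
        iy, ix = np.unravel_index(np.argmax(corr), corr.shape)
        if best is None or corr[iy, ix] > best[0]:
            best = (corr[iy, ix], int(ix), int(iy), int(r))
    _, x, y, r = best
    return x, y, r


def relative_truth(records, i, ref=0):
    """Ground-truth transform mapping slice i's image frame onto the reference frame."""
    return records[ref].true_transform.compose(records[i].true_transform.inverse())
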