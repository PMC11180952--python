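"""Magnification correction and rigid coregistration onto the first image.

The camera–block distance grows as the block is cut down, so each image is
slightly smaller than the first.  Following the two-stage structure of the
original method, the scale factor is computed first from inter-marker
distances, and the rotation+translation is then fit by least squares on the
scale-corrected marker positions (closed-form 2D Procrustes/Kabsch).  A
joint 4-dof similarity fit is offered as an optional comparison mode.
"""

from __future__ import annotations

import csv
import math
from dataclasses import dataclass
from itertools import combinations
from pathlib import Path

import numpy as np
from scipy import ndimage

from .errors import DegenerateGeometryError
from .fiducials import FiducialSet
from .image import RasterImage, quantize_u8
from .transform import SimilarityTransform


@dataclass(frozen=True)
class RigidFit:
    """A fitted transform together with its post-fit corner residual."""

    transform: SimilarityTransform
    rms_residual_px: float


def compute_magnification(fids_src: FiducialSet, fids_ref: FiducialSet) -> float:
    """Scale factor mapping the source image onto the reference.

    The mean over all six corner-pair distances of (reference distance /
    source distance).  Dimensionless; > 1 when the source image is smaller
    (camera further away).

    Raises
    ------
    DegenerateGeometryError
        If any source pairwise distance is below 1 px.
    """
    src = fids_src.centers()
    ref = fids_ref.centers()
    ratios = []
    for i, j in combinations(range(4), 2):
        d_src = float(np.hypot(*(src[i] - src[j])))
        d_ref = float(np.hypot(*(ref[i] - ref[j])))
        if d_src < 1.0:
            raise DegenerateGeometryError(
                f"source markers {i} and {j} are {d_src:.3f} px apart (< 1 px)"
            )
        ratios.append(d_ref / d_src)
    return float(np.mean(ratios))


def estimate_rigid(
    fids_src: FiducialSet,
    fids_ref: FiducialSet,
    scale: float,
) -> RigidFit:
    """Least-squares rotation+translation on the scale-corrected markers.

    Corner correspondences come from the shared labels.  The given scale is
    folded into the returned transform, which maps raw source coordinates
    to reference coordinates; the transform's ``scale`` equals the input
    ``scale`` exactly (it is not re-fit).  The attached RMS residual is
    computed over the four corners.

    Raises
    ------
    DegenerateGeometryError
        If the source markers are (near-)collinear or coincident.
    """
    if not scale > 0:
        raise ValueError(f"scale must be > 0, got {scale}")
    p = fids_src.centers() * scale
    q = fids_ref.centers()

    p_mean = p.mean(axis=0)
    q_mean = q.mean(axis=0)
    pc = p - p_mean
    qc = q - q_mean
    sv = np.linalg.svd(pc, compute_uv=False)
    if sv[0] < 1.0 or sv[1] < 1e-6 * sv[0]:
        raise DegenerateGeometryError(
            f"marker geometry is degenerate (singular values {sv[0]:.3g}, {sv[1]:.3g})"
        )
    # closed-form 2D least-squares rotation
    num = float((pc[:, 0] * qc[:, 1] - pc[:, 1] * qc[:, 0]).sum())
    den = float((pc[:, 0] * qc[:, 0] + pc[:, 1] * qc[:, 1]).sum())
    theta = math.atan2(num, den)
    rot = SimilarityTransform(1.0, theta)
    t = q_mean - rot.apply(p_mean)
    full = SimilarityTransform(scale, theta,
                               (float(t[0]), float(t[1])))
    res = full.apply(fids_src.centers()) - q
    rms = float(np.sqrt((res ** 2).sum(axis=1).mean()))
    return RigidFit(transform=full, rms_residual_px=rms)


def estimate_similarity(fids_src: FiducialSet, fids_ref: FiducialSet) -> RigidFit:
    """Optional joint 4-dof fit: scale, rotation and translation together.

    Full Procrustes on the corner correspondences; for comparison with the
    two-stage estimate, not used by the default pipeline.
    """
    p = fids_src.centers()
    q = fids_ref.centers()
    pc = p - p.mean(axis=0)
    qc = q - q.mean(axis=0)
    denom = float((pc ** 2).sum())
    if denom < 1.0:
        raise DegenerateGeometryError("source markers are nearly coincident")
    num = float((pc[:, 0] * qc[:, 1] - pc[:, 1] * qc[:, 0]).sum())
    den = float((pc[:, 0] * qc[:, 0] + pc[:, 1] * qc[:, 1]).sum())
    theta = math.atan2(num, den)
    scale = math.hypot(num, den) / denom
    rot = SimilarityTransform(1.0, theta)
    t = q.mean(axis=0) - scale * rot.apply(p.mean(axis=0))
    full = SimilarityTransform(scale, theta, (float(t[0]), float(t[1])))
    res = full.apply(p) - q
    return RigidFit(full, float(np.sqrt((res ** 2).sum(axis=1).mean())))


def border_median_color(image: RasterImage, ring_px: int = 10) -> tuple[float, float, float]:
    """Per-channel median of a border ring — approximates the paraffin color."""
    px = image.pixels
    h, w = px.shape[:2]
    r = min(ring_px, h // 2, w // 2)
    mask = np.zeros((h, w), dtype=bool)
    mask[:r, :] = mask[-r:, :] = True
    mask[:, :r] = mask[:, -r:] = True
    ring = px[mask]
    return tuple(float(np.median(ring[:, c])) for c in range(3))


def apply_transform(
    image: RasterImage,
    t: SimilarityTransform,
    out_dims: tuple[int, int],
    fill: tuple[float, float, float] | None = None,
    order: int = 3,
) -> RasterImage:
    """Resample ``image`` into the reference frame defined by ``t``.

    Output pixel q is sampled from the source at T⁻¹(q) by bicubic (spline)
    interpolation; pixels mapping outside the source are filled with
    ``fill`` (default: the image's own 10-px border-ring median, which
    approximates paraffin).  Channels are rounded half up and clipped to
    [0, 255].  Pure integer translations take an exact copy path.
    """
    w_out, h_out = out_dims
    if fill is None:
        fill = border_median_color(image)

    tinv = t.inverse()
    tx, ty = tinv.translation
    # exact path for integer shifts at unit scale / zero rotation
    if (
        abs(tinv.scale - 1.0) < 1e-12
        and abs(tinv.rotation_rad) < 1e-12
        and abs(tx - round(tx)) < 1e-9
        and abs(ty - round(ty)) < 1e-9
    ):
        out = np.empty((h_out, w_out, 3), dtype=np.float64)
        out[..., 0], out[..., 1], out[..., 2] = fill
        dx, dy = int(round(tx)), int(round(ty))
        h_in, w_in = image.pixels.shape[:2]
        ys = np.arange(h_out) + dy
        xs = np.arange(w_out) + dx
        yv = (ys >= 0) & (ys < h_in)
        xv = (xs >= 0) & (xs < w_in)
        out[np.ix_(np.flatnonzero(yv), np.flatnonzero(xv))] = (
            image.pixels[np.ix_(ys[yv], xs[xv])]
        )
        return RasterImage(quantize_u8(out), image.pixel_size_mm)

    # scipy.ndimage works in (row, col) = (y, x); permute the (x, y) matrix
    a = tinv.matrix
    m_yx = np.array([[a[1, 1], a[1, 0]], [a[0, 1], a[0, 0]]])
    off = (a[1, 2], a[0, 2])
    out = np.empty((h_out, w_out, 3), dtype=np.float64)
    for c in range(3):
        out[..., c] = ndimage.affine_transform(
            image.pixels[..., c].astype(np.float64),
            m_yx, offset=off, output_shape=(h_out, w_out),
            order=order, mode="grid-constant", cval=fill[c],
        )
    return RasterImage(quantize_u8(out), image.pixel_size_mm)


@dataclass(frozen=True)
class SliceAlignment:
    """Per-slice alignment result for QC export."""

    slice_index: int
    transform: SimilarityTransform
    rms_residual_px: float


def align_stack(
    images: list[RasterImage],
    fiducial_sets: list[FiducialSet],
    fill: tuple[float, float, float] | None = None,
) -> tuple[list[RasterImage], list[SliceAlignment]]:
    """Register every image onto the first (the reference) via its markers.

    The reference keeps its pixels untouched; every other slice is scale-
    corrected from inter-marker distances and rigidly registered, then
    resampled into the reference frame at the reference dimensions.
    """
    if len(images) != len(fiducial_sets):
        raise ValueError("one fiducial set per image required")
    ref = fiducial_sets[0]
    ref_dims = images[0].dims
    if fill is None:
        fill = border_median_color(images[0])
    aligned: list[RasterImage] = []
    results: list[SliceAlignment] = []
    for i, (img, fids) in enumerate(zip(images, fiducial_sets)):
        if i == 0:
            aligned.append(img.copy())
            results.append(SliceAlignment(0, SimilarityTransform.identity(), 0.0))
            continue
        scale = compute_magnification(fids, ref)
        fit = estimate_rigid(fids, ref, scale)
        aligned.append(apply_transform(img, fit.transform, ref_dims, fill=fill))
        results.append(SliceAlignment(i, fit.transform, fit.rms_residual_px))
    return aligned, results


def alignments_to_csv(results: list[SliceAlignment], path: str | Path) -> None:
    with open(path, "w", newline="") as fh:
        writer = csv.writer(fh)
        writer.writerow(["slice_index", "scale", "rotation_deg", "tx", "ty",
                         "rms_residual_px"])
        for r in results:
            t = r.transform
            writer.writerow([
                r.slice_index, f"{t.scale:.8f}",
                f"{math.degrees(t.rotation_rad):.6f}",
                f"{t.translation[0]:.4f}", f"{t.translation[1]:.4f}",
                f"{r.rms_residual_px:.6f}",
            ])
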