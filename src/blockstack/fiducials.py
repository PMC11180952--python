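"""Detection of the four dark circular fiducial markers in a blockface image.

The markers are black-paraffin-filled holes drilled near the block corners;
they are the darkest structures in the frame.  Detection follows the
classical recipe: grayscale conversion, intensity inversion, edge map,
circular Hough accumulation over a radius range, peak extraction with
non-maximum suppression, and finally subpixel refinement of each center as
the intensity-weighted centroid of the dark pixels inside the detected
circle (threshold chosen by Otsu on the circle's neighborhood).
"""

from __future__ import annotations

import csv
import math
from dataclasses import dataclass
from itertools import combinations
from pathlib import Path

import numpy as np
from skimage.feature import canny
from skimage.filters import threshold_otsu
from skimage.transform import hough_circle, hough_circle_peaks

from .errors import AmbiguityError, DetectionError
from .image import RasterImage

CORNERS = ("TL", "TR", "BL", "BR")


@dataclass(frozen=True)
class MarkerDetection:
    """One detected circle: center (x, y) in px, radius in px, accumulator score."""

    center: tuple[float, float]
    radius: float
    score: float


@dataclass(frozen=True)
class FiducialSet:
    """Four corner-labeled marker detections for one image.

    Invariants checked on construction: exactly one marker per corner
    label; each marker lies in its quadrant relative to the image center;
    every center is at least its radius away from every image border.
    """

    slice_index: int
    markers: dict[str, MarkerDetection]
    image_dims: tuple[int, int]  # (w, h)

    def __post_init__(self):
        if set(self.markers) != set(CORNERS):
            raise ValueError(f"markers must carry exactly the labels {CORNERS}, "
                             f"got {sorted(self.markers)}")
        w, h = self.image_dims
        for label, det in self.markers.items():
            x, y = det.center
            if _quadrant(x, y, w, h) != label:
                raise ValueError(f"marker labeled {label} at ({x:.1f}, {y:.1f}) is not "
                                 f"in its quadrant of a {w}x{h} image")
            r = det.radius
            if not (r <= x <= w - 1 - r and r <= y <= h - 1 - r):
                raise ValueError(f"marker {label} center ({x:.1f}, {y:.1f}) is closer than "
                                 f"its radius {r:.1f} px to the image border")

    def centers(self) -> np.ndarray:
        """Marker centers as a (4, 2) array in fixed corner order TL, TR, BL, BR."""
        return np.array([self.markers[c].center for c in CORNERS])


def _quadrant(x: float, y: float, w: int, h: int) -> str:
    return ("T" if y < h / 2.0 else "B") + ("L" if x < w / 2.0 else "R")


def _grayscale(pixels: np.ndarray) -> np.ndarray:
    # ITU-R 601 luma on linear 8-bit values
    return pixels @ np.array([0.299, 0.587, 0.114])


def detect_markers(
    image: RasterImage,
    radius_range: tuple[float, float],
    n_expected: int = 4,
    score_floor: float = 0.3,
    canny_sigma: float = 2.0,
) -> list[MarkerDetection]:
    """Detect the ``n_expected`` strongest non-overlapping dark circles.

    Returned detections are sorted by descending score (ties broken toward
    lower y, then lower x) and their centers are pairwise at least
    2·max_radius apart.  Scores are Hough accumulator strengths normalized
    by circle circumference, so a complete, well-formed circle scores near 1
    regardless of its radius.

    Raises
    ------
    DetectionError
        If fewer than ``n_expected`` peaks survive the score floor.
    """
    rmin, rmax = radius_range
    h, w = image.pixels.shape[:2]
    if not (0 < rmin <= rmax < min(w, h) / 4):
        raise ValueError(f"radius_range {radius_range} must lie within (0, {min(w, h) / 4})")

    gray = _grayscale(image.pixels.astype(np.float64))
    if gray.std() < 1.0:
        raise DetectionError(
            f"expected {n_expected} markers, found 0 (image has no structure)",
            n_found=0, n_expected=n_expected,
        )
    # invert and normalize so dark markers become the brightest structures and
    # detection is invariant to a global exposure gain
    inv = gray.max() - gray
    inv /= inv.max()
    edges = canny(inv, sigma=canny_sigma, low_threshold=0.1, high_threshold=0.3)

    radii = np.arange(int(math.floor(rmin)), int(math.ceil(rmax)) + 1)
    hspaces = hough_circle(edges, radii)
    accums, cxs, cys, rads = hough_circle_peaks(
        hspaces, radii,
        min_xdistance=int(2 * rmax), min_ydistance=int(2 * rmax),
        total_num_peaks=max(16, 4 * n_expected),
    )

    # deterministic greedy euclidean NMS: strongest first, ties toward low (y, x)
    order = sorted(range(len(accums)), key=lambda i: (-accums[i], cys[i], cxs[i], rads[i]))
    kept: list[MarkerDetection] = []
    for i in order:
        if accums[i] < score_floor:
            continue
        cx, cy, r = float(cxs[i]), float(cys[i]), float(rads[i])
        if any(math.hypot(cx - k.center[0], cy - k.center[1]) < 2 * rmax for k in kept):
            continue
        refined = _refine_center(gray, (cx, cy), r)
        kept.append(MarkerDetection(center=refined, radius=r, score=float(accums[i])))
        if len(kept) == n_expected:
            break

    if len(kept) < n_expected:
        raise DetectionError(
            f"expected {n_expected} markers, found {len(kept)} above score floor "
            f"{score_floor}", n_found=len(kept), n_expected=n_expected,
        )
    return kept


def _refine_center(gray: np.ndarray, center: tuple[float, float],
                   radius: float) -> tuple[float, float]:
    """Subpixel center: weighted centroid of below-Otsu pixels inside the circle.

    The threshold is computed on a window covering the circle interior plus
    an annulus of bright surround, so it separates marker from background
    locally; weights (threshold − intensity) make anti-aliased edge pixels
    contribute fractionally, which is what recovers the subpixel position.
    """
    h, w = gray.shape
    cx, cy = center
    win = int(math.ceil(radius * 1.6)) + 2
    x0, x1 = max(0, int(cx) - win), min(w, int(cx) + win + 1)
    y0, y1 = max(0, int(cy) - win), min(h, int(cy) + win + 1)
    patch = gray[y0:y1, x0:x1]
    if patch.size == 0 or patch.max() - patch.min() < 1.0:
        return center
    thr = threshold_otsu(patch)
    ys, xs = np.mgrid[y0:y1, x0:x1]
    inside = (xs - cx) ** 2 + (ys - cy) ** 2 <= (radius + 1.0) ** 2
    weights = np.where(inside & (patch < thr), thr - patch, 0.0)
    total = weights.sum()
    if total <= 0:
        return center
    return (float((weights * xs).sum() / total), float((weights * ys).sum() / total))


def assign_corners(
    detections: list[MarkerDetection],
    image_dims: tuple[int, int],
    slice_index: int = 0,
) -> FiducialSet:
    """Label four detections by their image quadrant (TL/TR/BL/BR).

    Deterministic and invariant to input order.

    Raises
    ------
    AmbiguityError
        If two detections fall into the same quadrant.
    ValueError
        If the number of detections is not exactly four.
    """
    if len(detections) != 4:
        raise ValueError(f"expected exactly 4 detections, got {len(detections)}")
    w, h = image_dims
    markers: dict[str, MarkerDetection] = {}
    for det in detections:
        q = _quadrant(det.center[0], det.center[1], w, h)
        if q in markers:
            raise AmbiguityError(
                f"two detections in quadrant {q}: {markers[q].center} and {det.center}",
                quadrant=q,
            )
        markers[q] = det
    return FiducialSet(slice_index=slice_index, markers=markers, image_dims=(w, h))


def detect_fiducials(
    image: RasterImage,
    radius_range: tuple[float, float],
    slice_index: int = 0,
    score_floor: float = 0.3,
) -> FiducialSet:
    """Convenience: detect four markers and assign corner labels."""
    dets = detect_markers(image, radius_range, n_expected=4, score_floor=score_floor)
    return assign_corners(dets, image.dims, slice_index=slice_index)


def fiducials_to_csv(sets: list[FiducialSet], path: str | Path) -> None:
    """Export detections for QC: one row per (slice, corner)."""
    with open(path, "w", newline="") as fh:
        writer = csv.writer(fh)
        writer.writerow(["slice_index", "corner", "x", "y", "radius", "score"])
        for fs in sets:
            for corner in CORNERS:
                d = fs.markers[corner]
                writer.writerow([fs.slice_index, corner,
                                 f"{d.center[0]:.4f}", f"{d.center[1]:.4f}",
                                 f"{d.radius:.2f}", f"{d.score:.4f}"])


def pairwise_distances(centers: np.ndarray) -> np.ndarray:
    """The six corner-pair distances of a (4, 2) center array, fixed pair order."""
    return np.array([
        float(np.hypot(*(centers[i] - centers[j])))
        for i, j in combinations(range(4), 2)
    ])
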