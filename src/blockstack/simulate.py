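"""Synthetic blockface stack generator with exact ground truth.

Emulates a serial blockface photography rig: a fixed camera photographs the
cut face of a paraffin block after every k-th microtome cut.  The block
carries four dark circular fiducial markers drilled near its corners, and a
phantom "specimen" — an ellipse split into three distinctly colored
territories, mimicking arterial territories labeled by injected colored
gelatin (blue/red/green).

The physical degradations modeled are the ones a real rig exhibits:

* magnification drift — the camera–block distance grows by one slice
  spacing per photograph, shrinking the specimen on the sensor following a
  pinhole model ``scale_i = d0 / (d0 + i·Δz)``;
* small in-plane rotation/translation jitter from vibration of the rig;
* per-image exposure gain and white-balance tint from uncontrolled
  reflections off the changing block surface.

Every generated slice comes with a :class:`GroundTruthRecord` holding the
exact phantom→image transform, photometric gains, and analytic marker
centers, so each downstream stage has an oracle.
"""

from __future__ import annotations

import json
import math
import re
from dataclasses import dataclass, asdict
from itertools import combinations
from pathlib import Path

import numpy as np

from .errors import ConfigError
from .image import RasterImage, quantize_u8
from .transform import SimilarityTransform


@dataclass(frozen=True)
class AcquisitionParams:
    """Geometry of the acquisition rig.

    Defaults follow a DSLR rig photographing a 150 x 100 mm field of view,
    cutting 20 µm sections and photographing every tenth cut (0.2 mm
    spacing).  The default sensor frame is a 1500 x 1000 px scaled-down
    version of the native 6000 x 4000 px frame (same FOV, 0.1 mm pixels) so
    simulations run in seconds; pass ``resolution_px=(6000, 4000)`` for the
    native geometry (0.025 mm pixels).
    """

    fov_mm: tuple[float, float] = (150.0, 100.0)
    resolution_px: tuple[int, int] = (1500, 1000)
    cut_thickness_um: float = 20.0
    photo_every_k: int = 10
    target_voxel_mm: float = 0.2

    def __post_init__(self):
        if not (self.fov_mm[0] > 0 and self.fov_mm[1] > 0):
            raise ValueError("fov_mm must be strictly positive")
        if not (self.resolution_px[0] >= 1 and self.resolution_px[1] >= 1):
            raise ValueError("resolution_px must be >= 1")
        if not self.cut_thickness_um > 0:
            raise ValueError("cut_thickness_um must be > 0")
        if not (isinstance(self.photo_every_k, int) and self.photo_every_k >= 1):
            raise ValueError("photo_every_k must be an integer >= 1")
        if not self.target_voxel_mm > 0:
            raise ValueError("target_voxel_mm must be > 0")
        rx = self.fov_mm[0] / self.resolution_px[0]
        ry = self.fov_mm[1] / self.resolution_px[1]
        if abs(rx - ry) > 1e-9:
            raise ValueError(f"non-square pixels: {rx} mm/px horizontally vs {ry} mm/px vertically")

    @property
    def pixel_size_mm(self) -> float:
        return self.fov_mm[0] / self.resolution_px[0]

    @property
    def slice_spacing_mm(self) -> float:
        """Physical distance between consecutive photographs, in mm."""
        return self.cut_thickness_um * self.photo_every_k / 1000.0


@dataclass(frozen=True)
class PhantomSpec:
    """Geometry and palette of the synthetic block.

    The specimen is an ellipse centered in the field of view whose
    semi-axes are modulated sinusoidally along the stack (mimicking the
    changing outline of a real specimen from cut to cut).  Its interior is
    split into three angular sectors colored from ``territory_colors``.
    Four dark marker disks sit near the block corners, outside the
    specimen.
    """

    ellipse_center_mm: tuple[float, float] = (75.0, 50.0)
    ellipse_semi_axes_mm: tuple[float, float] = (52.0, 33.0)
    shape_modulation_amp: float = 0.05
    shape_modulation_period: float = 40.0
    # blue / red / green territories (ACA / MCA / PCA-like labeling)
    territory_colors: tuple[tuple[int, int, int], ...] = (
        (70, 90, 200),
        (205, 70, 60),
        (65, 175, 80),
    )
    # sector lower edges in degrees; sector i spans [edge_i, edge_{i+1})
    sector_edges_deg: tuple[float, float, float] = (-90.0, 30.0, 150.0)
    marker_positions_mm: tuple[tuple[float, float], ...] = (
        (12.0, 12.0),
        (138.0, 12.0),
        (12.0, 88.0),
        (138.0, 88.0),
    )
    marker_radius_mm: float = 2.5
    paraffin_rgb: tuple[int, int, int] = (232, 224, 205)
    marker_rgb: tuple[int, int, int] = (8, 8, 8)

    def __post_init__(self):
        if len(self.territory_colors) != 3:
            raise ValueError("exactly three territory colors required")
        for a, b in combinations(self.territory_colors, 2):
            if max(abs(x - y) for x, y in zip(a, b)) < 64:
                raise ValueError(f"territory colors {a} and {b} are not distinguishable "
                                 "(max channel difference < 64)")
        if len(self.marker_positions_mm) != 4:
            raise ValueError("exactly four marker positions required")
        if not self.marker_radius_mm > 0:
            raise ValueError("marker_radius_mm must be > 0")
        # markers must sit outside the specimen even at maximal modulation
        cx, cy = self.ellipse_center_mm
        a = self.ellipse_semi_axes_mm[0] * (1.0 + self.shape_modulation_amp)
        b = self.ellipse_semi_axes_mm[1] * (1.0 + self.shape_modulation_amp)
        for mx, my in self.marker_positions_mm:
            if ((mx - cx) / a) ** 2 + ((my - cy) / b) ** 2 <= 1.0:
                raise ValueError(f"marker at ({mx}, {my}) mm lies inside the specimen ellipse")

    def semi_axes_at(self, slice_index: int) -> tuple[float, float]:
        m = 1.0 + self.shape_modulation_amp * math.sin(
            2.0 * math.pi * slice_index / self.shape_modulation_period
        )
        return (self.ellipse_semi_axes_mm[0] * m, self.ellipse_semi_axes_mm[1] * m)


@dataclass(frozen=True)
class JitterSpec:
    """Per-image acquisition perturbations (uniform ranges) and camera drift.

    ``d0_mm`` is the initial camera–blockface distance of the pinhole drift
    model; ``math.inf`` disables magnification drift.  The rotation and
    translation ranges model slight camera movements during the cutting
    session; exposure gain and per-channel white-balance tint model the
    observed slight exposure differences between photographs.
    """

    rotation_deg: tuple[float, float] = (-1.0, 1.0)
    translation_px: tuple[float, float] = (-20.0, 20.0)
    exposure_gain: tuple[float, float] = (0.9, 1.1)
    wb_tint: tuple[float, float] = (0.95, 1.05)
    d0_mm: float = 500.0

    def __post_init__(self):
        for name in ("rotation_deg", "translation_px", "exposure_gain", "wb_tint"):
            lo, hi = getattr(self, name)
            if not (math.isfinite(lo) and math.isfinite(hi) and lo <= hi):
                raise ValueError(f"{name} range must be finite with lo <= hi")
        if self.exposure_gain[0] <= 0 or self.wb_tint[0] <= 0:
            raise ValueError("gain and tint must be strictly positive")
        if not self.d0_mm > 0:
            raise ValueError("d0_mm must be > 0 (use math.inf to disable drift)")

    @classmethod
    def none(cls) -> "JitterSpec":
        """No jitter, no drift, unit gains: every slice renders identically."""
        return cls(
            rotation_deg=(0.0, 0.0),
            translation_px=(0.0, 0.0),
            exposure_gain=(1.0, 1.0),
            wb_tint=(1.0, 1.0),
            d0_mm=math.inf,
        )


@dataclass(frozen=True)
class GroundTruthRecord:
    """Exact per-slice generation parameters — the oracle for every stage."""

    slice_index: int
    true_transform: SimilarityTransform  # phantom px coords -> image px coords
    exposure_gain: float
    wb_tint: tuple[float, float, float]
    marker_centers_px: tuple[tuple[float, float], ...]

    def __post_init__(self):
        if not self.exposure_gain > 0:
            raise ValueError("exposure_gain must be > 0")
        if any(t <= 0 for t in self.wb_tint):
            raise ValueError("wb_tint components must be > 0")
        if len(self.marker_centers_px) != 4:
            raise ValueError("exactly four marker centers required")


def marker_positions_px(phantom: PhantomSpec, params: AcquisitionParams) -> np.ndarray:
    """Nominal (undistorted) marker centers in pixel coordinates, shape (4, 2)."""
    ps = params.pixel_size_mm
    return np.array([(mx / ps - 0.5, my / ps - 0.5) for mx, my in phantom.marker_positions_mm])


def _px_to_mm(coords_px: np.ndarray, pixel_size_mm: float) -> np.ndarray:
    return (coords_px + 0.5) * pixel_size_mm


def render_slice(
    phantom: PhantomSpec,
    params: AcquisitionParams,
    truth: GroundTruthRecord,
    supersample: int = 4,
    _row_block: int = 256,
) -> RasterImage:
    """Rasterize one blockface photograph from its ground-truth record.

    Deterministic, anti-aliased: each output pixel is the box average of
    ``supersample``² analytic membership samples, so marker edges carry the
    subpixel information the detector needs.  Photometric gains multiply the
    linear RGB signal before 8-bit quantization (round half up, clip 255).
    """
    w, h = params.resolution_px
    ps = params.pixel_size_mm
    tinv = truth.true_transform.inverse()
    c = math.cos(tinv.rotation_rad) * tinv.scale
    s = math.sin(tinv.rotation_rad) * tinv.scale
    itx, ity = tinv.translation

    # marker-in-frame precondition
    r_px = phantom.marker_radius_mm / ps * truth.true_transform.scale
    for mx, my in truth.marker_centers_px:
        if not (r_px <= mx <= w - 1 - r_px and r_px <= my <= h - 1 - r_px):
            raise ValueError(
                f"slice {truth.slice_index}: marker at ({mx:.1f}, {my:.1f}) px is outside "
                f"the {w}x{h} frame (margin {r_px:.1f} px)"
            )

    cx_mm, cy_mm = phantom.ellipse_center_mm
    a_mm, b_mm = phantom.semi_axes_at(truth.slice_index)
    edges = np.asarray(phantom.sector_edges_deg)
    colors = np.asarray(phantom.territory_colors, dtype=np.float32)
    paraffin = np.asarray(phantom.paraffin_rgb, dtype=np.float32)
    marker = np.asarray(phantom.marker_rgb, dtype=np.float32)
    gains = truth.exposure_gain * np.asarray(truth.wb_tint, dtype=np.float32)

    ss = int(supersample)
    if ss < 1:
        raise ValueError("supersample must be >= 1")
    xs = (np.arange(w * ss, dtype=np.float32) + 0.5) / ss - 0.5
    out = np.empty((h, w, 3), dtype=np.uint8)

    for y0 in range(0, h, _row_block):
        y1 = min(y0 + _row_block, h)
        ys = (np.arange(y0 * ss, y1 * ss, dtype=np.float32) + 0.5) / ss - 0.5
        gx, gy = np.meshgrid(xs, ys)
        # image px -> phantom px -> mm
        px = c * gx - s * gy + itx
        py = s * gx + c * gy + ity
        xm = _px_to_mm(px, ps)
        ym = _px_to_mm(py, ps)
        del gx, gy, px, py

        block = np.broadcast_to(paraffin, ((y1 - y0) * ss, w * ss, 3)).copy()
        dx = xm - cx_mm
        dy = ym - cy_mm
        inside = (dx / a_mm) ** 2 + (dy / b_mm) ** 2 <= 1.0
        ang = np.degrees(np.arctan2(dy, dx))
        # sectors: [e0, e1), [e1, e2), remainder
        sect0 = inside & (ang >= edges[0]) & (ang < edges[1])
        sect1 = inside & (ang >= edges[1]) & (ang < edges[2])
        sect2 = inside & ~(sect0 | sect1)
        for m, col in zip((sect0, sect1, sect2), colors):
            block[m] = col
        del dx, dy, ang, inside, sect0, sect1, sect2
        r2 = (phantom.marker_radius_mm) ** 2
        for mx, my in phantom.marker_positions_mm:
            mm = (xm - mx) ** 2 + (ym - my) ** 2 <= r2
            block[mm] = marker
        del xm, ym
        avg = block.reshape(y1 - y0, ss, w, ss, 3).mean(axis=(1, 3), dtype=np.float64)
        out[y0:y1] = quantize_u8(avg * gains)

    return RasterImage(out, ps)


def render_labels(
    phantom: PhantomSpec,
    params: AcquisitionParams,
    transform: SimilarityTransform,
    slice_index: int,
    grid_dims_px: tuple[int, int] | None = None,
    grid_pixel_size_mm: float | None = None,
) -> np.ndarray:
    """Ground-truth label map sampled at pixel centers of an arbitrary grid.

    Labels: 0 = paraffin, 1..3 = territories, 4 = marker.  ``transform``
    maps phantom px coordinates to the frame the grid lives in (e.g. the
    reference slice's true transform for an aligned/reconstructed volume);
    ``grid_pixel_size_mm`` rescales grid pixel centers into that frame for
    downsampled grids.
    """
    w, h = grid_dims_px if grid_dims_px is not None else params.resolution_px
    gps = grid_pixel_size_mm if grid_pixel_size_mm is not None else params.pixel_size_mm
    f = gps / params.pixel_size_mm
    xs = (np.arange(w, dtype=np.float64) + 0.5) * f - 0.5
    ys = (np.arange(h, dtype=np.float64) + 0.5) * f - 0.5
    gx, gy = np.meshgrid(xs, ys)
    tinv = transform.inverse()
    c = math.cos(tinv.rotation_rad) * tinv.scale
    s = math.sin(tinv.rotation_rad) * tinv.scale
    px = c * gx - s * gy + tinv.translation[0]
    py = s * gx + c * gy + tinv.translation[1]
    xm = _px_to_mm(px, params.pixel_size_mm)
    ym = _px_to_mm(py, params.pixel_size_mm)

    labels = np.zeros((h, w), dtype=np.uint8)
    cx, cy = phantom.ellipse_center_mm
    a, b = phantom.semi_axes_at(slice_index)
    dx, dy = xm - cx, ym - cy
    inside = (dx / a) ** 2 + (dy / b) ** 2 <= 1.0
    ang = np.degrees(np.arctan2(dy, dx))
    e = phantom.sector_edges_deg
    sect0 = inside & (ang >= e[0]) & (ang < e[1])
    sect1 = inside & (ang >= e[1]) & (ang < e[2])
    labels[sect0] = 1
    labels[sect1] = 2
    labels[inside & ~(sect0 | sect1)] = 3
    r2 = phantom.marker_radius_mm ** 2
    for mx, my in phantom.marker_positions_mm:
        labels[(xm - mx) ** 2 + (ym - my) ** 2 <= r2] = 4
    return labels


def generate_stack(
    params: AcquisitionParams,
    phantom: PhantomSpec,
    n_slices: int,
    jitter: JitterSpec | None = None,
    seed: int = 0,
    supersample: int = 4,
) -> tuple[list[RasterImage], list[GroundTruthRecord]]:
    """Generate an ordered blockface stack plus its exact ground truth.

    Slice i's magnification follows the pinhole camera-distance model
    ``scale_i = d0 / (d0 + i·Δz)`` with Δz = cut_thickness · photo_every_k;
    rotation/translation jitter, exposure gain and white-balance tint are
    drawn uniformly from the ranges in ``jitter``.  The same seed yields a
    bit-identical stack.

    Raises
    ------
    ValueError
        If ``n_slices < 2`` or drift/jitter pushes any marker out of frame.
    """
    if not (isinstance(n_slices, int) and n_slices >= 2):
        raise ValueError(f"n_slices must be an integer >= 2, got {n_slices}")
    if jitter is None:
        jitter = JitterSpec()
    rng = np.random.default_rng(seed)
    dz = params.slice_spacing_mm
    w, h = params.resolution_px
    center = ((w - 1) / 2.0, (h - 1) / 2.0)
    nominal_markers = marker_positions_px(phantom, params)

    images: list[RasterImage] = []
    records: list[GroundTruthRecord] = []
    for i in range(n_slices):
        scale = 1.0 if math.isinf(jitter.d0_mm) else jitter.d0_mm / (jitter.d0_mm + i * dz)
        rot = math.radians(rng.uniform(*jitter.rotation_deg))
        tx = rng.uniform(*jitter.translation_px)
        ty = rng.uniform(*jitter.translation_px)
        gain = rng.uniform(*jitter.exposure_gain)
        tint = tuple(rng.uniform(*jitter.wb_tint) for _ in range(3))
        t = SimilarityTransform.about_point(scale, rot, center, (tx, ty))
        centers = t.apply(nominal_markers)
        truth = GroundTruthRecord(
            slice_index=i,
            true_transform=t,
            exposure_gain=gain,
            wb_tint=tint,
            marker_centers_px=tuple((float(x), float(y)) for x, y in centers),
        )
        r_px = phantom.marker_radius_mm / params.pixel_size_mm * scale
        for mx, my in truth.marker_centers_px:
            if not (r_px <= mx <= w - 1 - r_px and r_px <= my <= h - 1 - r_px):
                raise ValueError(
                    f"jitter/drift configuration moved a marker out of frame: slice {i} "
                    f"marker at ({mx:.1f}, {my:.1f}) px in a {w}x{h} frame"
                )
        images.append(render_slice(phantom, params, truth, supersample=supersample))
        records.append(truth)
    return images, records


# ---------------------------------------------------------------------------
# stack I/O: numbered PNGs + a JSON ground-truth sidecar


def save_stack(
    out_dir: str | Path,
    images: list[RasterImage],
    records: list[GroundTruthRecord] | None = None,
    fmt: str = "png",
) -> list[Path]:
    """Write ``slice_0000.png`` ... plus ``ground_truth.json`` if records given."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    paths = []
    for i, img in enumerate(images):
        p = out / f"slice_{i:04d}.{fmt}"
        img.to_file(p)
        paths.append(p)
    if records is not None:
        save_ground_truth(out / "ground_truth.json", records, images[0].pixel_size_mm)
    return paths


def save_ground_truth(path: str | Path, records: list[GroundTruthRecord],
                      pixel_size_mm: float) -> None:
    payload = {
        "pixel_size_mm": pixel_size_mm,
        "slices": [
            {
                "slice_index": r.slice_index,
                "transform": {
                    "scale": r.true_transform.scale,
                    "rotation_rad": r.true_transform.rotation_rad,
                    "translation": list(r.true_transform.translation),
                },
                "exposure_gain": r.exposure_gain,
                "wb_tint": list(r.wb_tint),
                "marker_centers_px": [list(c) for c in r.marker_centers_px],
            }
            for r in records
        ],
    }
    Path(path).write_text(json.dumps(payload, indent=1))


def load_ground_truth(path: str | Path) -> list[GroundTruthRecord]:
    payload = json.loads(Path(path).read_text())
    records = []
    for rec in payload["slices"]:
        t = rec["transform"]
        records.append(
            GroundTruthRecord(
                slice_index=rec["slice_index"],
                true_transform=SimilarityTransform(
                    t["scale"], t["rotation_rad"], tuple(t["translation"])
                ),
                exposure_gain=rec["exposure_gain"],
                wb_tint=tuple(rec["wb_tint"]),
                marker_centers_px=tuple(tuple(c) for c in rec["marker_centers_px"]),
            )
        )
    return records


def load_stack(in_dir: str | Path, pixel_size_mm: float) -> list[RasterImage]:
    """Load a numbered image stack (``slice_*.png``/``.jpg``), sorted by index."""
    in_dir = Path(in_dir)
    pat = re.compile(r"slice_(\d+)\.(png|jpg|jpeg)$", re.IGNORECASE)
    found = sorted(
        (int(m.group(1)), p)
        for p in in_dir.iterdir()
        if (m := pat.match(p.name))
    )
    if not found:
        raise FileNotFoundError(f"no slice_NNNN.png/.jpg images found in {in_dir}")
    return [RasterImage.from_file(p, pixel_size_mm) for _, p in found]
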