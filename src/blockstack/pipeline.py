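"""End-to-end reconstruction pipeline and its configuration.

Stage order is fixed: detect fiducials → magnification + rigid registration
onto the first image → resample into the reference frame → white balance →
color enhancement → brightness transfer → Lanczos downsampling → stacking →
NIfTI write.  Every stage logs per-slice diagnostics; reruns with identical
inputs and configuration are byte-identical.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass
from pathlib import Path
from typing import Literal, Optional

import yaml
from pydantic import BaseModel, ConfigDict, ValidationError, field_validator

from . import volume as vol
from .alignment import SliceAlignment, align_stack, alignments_to_csv
from .color_norm import PatchRegion, normalize_stack
from .errors import AnisotropyError, BlockstackError, ConfigError
from .fiducials import FiducialSet, detect_fiducials, fiducials_to_csv
from .image import RasterImage
from .simulate import AcquisitionParams, load_stack

logger = logging.getLogger("blockstack")


class _Model(BaseModel):
    model_config = ConfigDict(extra="forbid")


class AcquisitionConfig(_Model):
    fov_mm: tuple[float, float] = (150.0, 100.0)
    resolution_px: tuple[int, int] = (1500, 1000)
    cut_thickness_um: float = 20.0
    photo_every_k: int = 10
    target_voxel_mm: float = 0.2

    def to_params(self) -> AcquisitionParams:
        try:
            return AcquisitionParams(
                fov_mm=self.fov_mm,
                resolution_px=self.resolution_px,
                cut_thickness_um=self.cut_thickness_um,
                photo_every_k=self.photo_every_k,
                target_voxel_mm=self.target_voxel_mm,
            )
        except ValueError as exc:
            raise ConfigError(str(exc)) from exc


class FiducialsConfig(_Model):
    marker_radius_mm: float = 2.5
    radius_factors: tuple[float, float] = (0.7, 1.3)
    score_floor: float = 0.3

    @field_validator("marker_radius_mm")
    @classmethod
    def _positive(cls, v):
        if v <= 0:
            raise ValueError("marker_radius_mm must be > 0")
        return v

    def radius_range_px(self, pixel_size_mm: float) -> tuple[float, float]:
        nominal = self.marker_radius_mm / pixel_size_mm
        return (self.radius_factors[0] * nominal, self.radius_factors[1] * nominal)


class PatchConfig(_Model):
    # None: a region between the top-left marker and the specimen, which is
    # paraffin for the default phantom and clear of warp edge effects
    x: Optional[int] = None
    y: Optional[int] = None
    w: int = 25
    h: int = 25

    def to_region(self, image_dims: tuple[int, int]) -> PatchRegion:
        iw, ih = image_dims
        x = self.x if self.x is not None else iw // 4
        y = self.y if self.y is not None else ih // 10
        return PatchRegion(x=x, y=y, w=self.w, h=self.h)


class ColorConfig(_Model):
    patch: PatchConfig = PatchConfig()
    enhance_factor: float = 1.3
    brightness_reference: Literal["first", "global"] = "first"


class VolumeConfig(_Model):
    encoding: Literal["rgb", "split"] = "rgb"


class IOConfig(_Model):
    input_dir: Optional[str] = None
    output_volume: Optional[str] = None
    qc_dir: Optional[str] = None


class PipelineConfig(_Model):
    """Validated configuration for the whole pipeline."""

    acquisition: AcquisitionConfig = AcquisitionConfig()
    fiducials: FiducialsConfig = FiducialsConfig()
    color: ColorConfig = ColorConfig()
    volume: VolumeConfig = VolumeConfig()
    io: IOConfig = IOConfig()
    seed: int = 0

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        try:
            raw = yaml.safe_load(Path(path).read_text()) or {}
            return cls.model_validate(raw)
        except (ValidationError, yaml.YAMLError) as exc:
            raise ConfigError(f"invalid configuration in {path}: {exc}") from exc


@dataclass
class PipelineResult:
    """Artifacts and diagnostics of one pipeline run."""

    volume_path: Path
    volume: vol.VolumeGrid
    fiducial_sets: list[FiducialSet]
    alignments: list[SliceAlignment]
    transforms_csv: Optional[Path] = None
    fiducials_csv: Optional[Path] = None


def run_pipeline(
    config: PipelineConfig,
    images: list[RasterImage] | None = None,
    output_volume: str | Path | None = None,
) -> PipelineResult:
    """Run detect → register → resample → normalize → downsample → stack → write.

    ``images`` may be passed directly (e.g. straight from the simulator);
    otherwise they are loaded from ``config.io.input_dir``.  The isotropy
    requirement (target voxel == slice spacing) is checked up front, before
    any work, so a misconfigured run fails before writing anything.
    """
    params = config.acquisition.to_params()
    spacing = params.slice_spacing_mm
    if abs(params.target_voxel_mm - spacing) > 1e-9:
        raise AnisotropyError(
            f"target voxel {params.target_voxel_mm} mm does not match slice spacing "
            f"{spacing} mm; adjust target_voxel_mm, cut_thickness_um or photo_every_k"
        )

    if images is None:
        if config.io.input_dir is None:
            raise ConfigError("no input images: pass `images` or set io.input_dir")
        images = load_stack(config.io.input_dir, params.pixel_size_mm)
    if len(images) < 2:
        raise ConfigError(f"need at least 2 images, got {len(images)}")
    out_path = Path(output_volume or config.io.output_volume or "volume.nii.gz")
    qc_dir = Path(config.io.qc_dir) if config.io.qc_dir else None
    if qc_dir:
        qc_dir.mkdir(parents=True, exist_ok=True)

    # stage 1: fiducial detection
    radius_range = config.fiducials.radius_range_px(images[0].pixel_size_mm)
    logger.info("detect: %d slices, radius range (%.1f, %.1f) px",
                len(images), *radius_range)
    fiducial_sets = []
    for i, img in enumerate(images):
        try:
            fs = detect_fiducials(img, radius_range, slice_index=i,
                                  score_floor=config.fiducials.score_floor)
        except BlockstackError as exc:
            raise type(exc)(f"stage 'detect', slice {i}: {exc}", *_extra_args(exc)) from exc
        logger.info("detect: slice %d centers %s", i,
                    [tuple(round(v, 2) for v in m) for m in fs.centers()])
        fiducial_sets.append(fs)

    # stage 2+3: magnification + rigid registration, resample onto first image
    try:
        aligned, alignments = align_stack(images, fiducial_sets)
    except BlockstackError as exc:
        raise type(exc)(f"stage 'align': {exc}", *_extra_args(exc)) from exc
    for a in alignments:
        logger.info(
            "align: slice %d scale %.6f rot %.4f deg t (%.2f, %.2f) rms %.4f px",
            a.slice_index, a.transform.scale, math.degrees(a.transform.rotation_rad),
            a.transform.translation[0], a.transform.translation[1], a.rms_residual_px,
        )

    # stage 4-6: white balance, color enhancement, brightness transfer
    patch = config.color.patch.to_region(aligned[0].dims)
    logger.info("color: patch %dx%d at (%d, %d), enhance %.2f, reference '%s'",
                patch.w, patch.h, patch.x, patch.y,
                config.color.enhance_factor, config.color.brightness_reference)
    normalized = normalize_stack(
        aligned, patch,
        enhance_factor=config.color.enhance_factor,
        brightness_reference=config.color.brightness_reference,
    )

    # stage 7: downsample to the target in-plane resolution
    small = [vol.downsample(img, params.target_voxel_mm) for img in normalized]
    logger.info("downsample: %dx%d px at %.4f mm -> %dx%d px at %.4f mm",
                normalized[0].width, normalized[0].height, normalized[0].pixel_size_mm,
                small[0].width, small[0].height, small[0].pixel_size_mm)

    # stage 8+9: stack and write
    grid = vol.build_volume(small, spacing)
    out_path.parent.mkdir(parents=True, exist_ok=True)
    vol.write_nifti(grid, out_path, split_channels=(config.volume.encoding == "split"))
    logger.info("volume: %s, %d x %d x %d voxels at %.3f mm isotropic",
                out_path, *grid.voxels.shape[:3], grid.voxel_size_mm)

    transforms_csv = fids_csv = None
    if qc_dir:
        for i, img in enumerate(aligned):
            img.to_file(qc_dir / f"aligned_{i:04d}.png")
        transforms_csv = qc_dir / "transforms.csv"
        alignments_to_csv(alignments, transforms_csv)
        fids_csv = qc_dir / "fiducials.csv"
        fiducials_to_csv(fiducial_sets, fids_csv)

    return PipelineResult(
        volume_path=out_path, volume=grid, fiducial_sets=fiducial_sets,
        alignments=alignments, transforms_csv=transforms_csv, fiducials_csv=fids_csv,
    )


def _extra_args(exc: BlockstackError) -> tuple:
    """Preserve extra constructor args when re-raising stage-tagged errors."""
    if hasattr(exc, "n_found"):
        return (exc.n_found, exc.n_expected)
    if hasattr(exc, "quadrant"):
        return (exc.quadrant,)
    return ()
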