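"""Downsampling to the target in-plane resolution and 3D volume assembly.

The reconstructed volume is isotropic by construction: the in-plane pixel
size after Lanczos downsampling must equal the physical slice spacing
(e.g. 0.025 mm native pixels × 8 = 0.2 mm = 20 µm cuts × 10).  The builder
enforces this instead of silently resampling, and the volume is written as
NIfTI-1 with either the RGB24 datatype or a 4-D uint8 fallback for viewers
without RGB support.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import nibabel as nib
import numpy as np
from PIL import Image

from .errors import AnisotropyError
from .image import RasterImage

_RGB_DTYPE = np.dtype([("R", "u1"), ("G", "u1"), ("B", "u1")])


def compute_pixel_size(fov_mm: tuple[float, float],
                       resolution_px: tuple[int, int]) -> float:
    """Physical pixel size in mm from field of view and sensor resolution.

    Requires square pixels: the width and height ratios must agree to 1e-9.
    """
    fw, fh = fov_mm
    pw, ph = resolution_px
    if not (fw > 0 and fh > 0 and pw > 0 and ph > 0):
        raise ValueError("field of view and resolution must be strictly positive")
    rx = fw / pw
    ry = fh / ph
    if abs(rx - ry) > 1e-9:
        raise ValueError(
            f"non-square pixel geometry: {rx} mm/px horizontally vs {ry} mm/px vertically"
        )
    return rx


def compute_slice_spacing(cut_thickness_um: float, photo_every_k: int) -> float:
    """Physical spacing between photographed blockfaces, in mm."""
    if not (cut_thickness_um > 0 and photo_every_k >= 1):
        raise ValueError("cut thickness must be > 0 and photo interval >= 1")
    return cut_thickness_um * photo_every_k / 1000.0


def downsample(image: RasterImage, target_mm: float) -> RasterImage:
    """Lanczos (a = 3) downsampling to the target physical resolution.

    Output dimensions are ``round(dim · pixel_size / target)`` per axis, so
    the physical extent is preserved to within one output pixel.  A target
    equal to the current pixel size is the identity; a smaller target
    (upsampling) is rejected.
    """
    if target_mm < image.pixel_size_mm - 1e-12:
        raise ValueError(
            f"upsampling requested (target {target_mm} mm < pixel {image.pixel_size_mm} mm); "
            "only downsampling is supported"
        )
    if abs(target_mm - image.pixel_size_mm) <= 1e-12:
        return image.copy()
    w_out = int(round(image.width * image.pixel_size_mm / target_mm))
    h_out = int(round(image.height * image.pixel_size_mm / target_mm))
    if w_out < 1 or h_out < 1:
        raise ValueError(f"target {target_mm} mm collapses the image to zero size")
    resized = Image.fromarray(image.pixels).resize((w_out, h_out),
                                                   resample=Image.Resampling.LANCZOS)
    return RasterImage(np.asarray(resized).copy(), target_mm)


@dataclass
class VolumeGrid:
    """Isotropic 3D RGB voxel grid, slice index first.

    ``voxels[d]`` is slice d of the stack; axes are (slice, y, x, channel).
    The affine maps (x, y, slice) voxel indices to a right-handed physical
    frame in mm with the slice index increasing along +z (the cutting
    direction); the first photographed blockface is slice 0.
    """

    voxels: np.ndarray  # D x H x W x 3, uint8
    voxel_size_mm: float

    def __post_init__(self):
        self.voxels = np.asarray(self.voxels)
        if self.voxels.ndim != 4 or self.voxels.shape[3] != 3:
            raise ValueError(f"voxels must be D x H x W x 3, got shape {self.voxels.shape}")
        if self.voxels.dtype != np.uint8:
            raise ValueError(f"voxels must be uint8, got {self.voxels.dtype}")
        if not self.voxel_size_mm > 0:
            raise ValueError("voxel_size_mm must be > 0")
        self.voxel_size_mm = float(self.voxel_size_mm)

    @property
    def n_slices(self) -> int:
        return self.voxels.shape[0]

    @property
    def affine(self) -> np.ndarray:
        v = self.voxel_size_mm
        return np.diag([v, v, v, 1.0])


def build_volume(stack: list[RasterImage], spacing_mm: float) -> VolumeGrid:
    """Stack aligned, downsampled slices into an isotropic volume.

    Raises
    ------
    ValueError
        If slices disagree in dimensions (the offending slice is named).
    AnisotropyError
        If the in-plane pixel size does not equal the slice spacing within
        1e-9 mm — adjust the downsampling target or the photograph interval.
    """
    if not stack:
        raise ValueError("empty stack")
    dims0 = stack[0].dims
    ps0 = stack[0].pixel_size_mm
    for i, img in enumerate(stack):
        if img.dims != dims0:
            raise ValueError(
                f"slice {i} has dimensions {img.dims}, expected {dims0} (mixed dims)"
            )
        if abs(img.pixel_size_mm - ps0) > 1e-9:
            raise ValueError(f"slice {i} has pixel size {img.pixel_size_mm}, expected {ps0}")
    if abs(ps0 - spacing_mm) > 1e-9:
        raise AnisotropyError(
            f"in-plane resolution {ps0} mm differs from slice spacing {spacing_mm} mm; "
            "the volume would not be isotropic — adjust the downsampling target or the "
            "photograph interval"
        )
    voxels = np.stack([img.pixels for img in stack], axis=0)
    return VolumeGrid(voxels=voxels, voxel_size_mm=spacing_mm)


def write_nifti(vol: VolumeGrid, path: str | Path, split_channels: bool = False) -> Path:
    """Write the volume as NIfTI-1.

    Default encoding is the 24-bit RGB datatype; ``split_channels`` writes a
    4-D uint8 image with a trailing channel axis of size 3 instead, for
    viewers lacking RGB support.  Voxel data round-trips losslessly and
    pixdim carries the isotropic voxel size on all three spatial axes.
    """
    path = Path(path)
    # internal (slice, y, x, c) -> NIfTI (x, y, slice[, c])
    arr = np.ascontiguousarray(vol.voxels.transpose(2, 1, 0, 3))
    if split_channels:
        img = nib.Nifti1Image(arr, vol.affine)
    else:
        structured = arr.view(_RGB_DTYPE).reshape(arr.shape[:3])
        img = nib.Nifti1Image(structured, vol.affine)
    img.header.set_xyzt_units("mm")
    nib.save(img, str(path))
    return path


def read_nifti(path: str | Path) -> VolumeGrid:
    """Read a volume written by :func:`write_nifti` (either encoding)."""
    img = nib.load(str(path))
    zooms = img.header.get_zooms()[:3]
    if max(zooms) - min(zooms) > 1e-6:
        raise AnisotropyError(f"volume at {path} is not isotropic: pixdim {zooms}")
    data = np.asanyarray(img.dataobj)
    if data.dtype.names is not None:
        stacked = np.stack([data[name] for name in ("R", "G", "B")], axis=-1)
    elif data.ndim == 4 and data.shape[3] == 3:
        stacked = data.astype(np.uint8)
    else:
        raise ValueError(f"unsupported NIfTI layout: dtype {data.dtype}, shape {data.shape}")
    return VolumeGrid(
        voxels=np.ascontiguousarray(stacked.transpose(2, 1, 0, 3)),
        voxel_size_mm=float(zooms[0]),
    )
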