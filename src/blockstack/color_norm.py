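"""Photometric normalization of aligned blockface images.

Three operations, applied in this order by the pipeline:

1. white balance against a small patch of pure paraffin treated as the
   "true" neutral reference;
2. saturation enhancement about the per-pixel luminance (a cosmetic step —
   colors of raw blockface photographs look muted);
3. brightness transfer: match the mean/std of the HSV value channel to a
   reference image's, leaving hue and saturation untouched.

All operations consume and produce 8-bit RGB rasters; intermediate math is
floating point with a single round-half-up quantization at the end of each
operation.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
from skimage.color import hsv2rgb, rgb2hsv

from .image import RasterImage, quantize_u8

logger = logging.getLogger(__name__)

# ITU-R 601 luma weights
_LUMA = np.array([0.299, 0.587, 0.114])


@dataclass(frozen=True)
class PatchRegion:
    """Axis-aligned pixel rectangle assumed to contain only paraffin."""

    x: int
    y: int
    w: int = 25
    h: int = 25

    def __post_init__(self):
        if self.w < 1 or self.h < 1:
            raise ValueError("patch must be at least 1x1 px")
        if self.x < 0 or self.y < 0:
            raise ValueError("patch origin must be non-negative")

    def validate_inside(self, image: RasterImage) -> None:
        if self.x + self.w > image.width or self.y + self.h > image.height:
            raise ValueError(
                f"patch {self.w}x{self.h} at ({self.x}, {self.y}) exceeds the "
                f"{image.width}x{image.height} image"
            )

    def extract(self, image: RasterImage) -> np.ndarray:
        self.validate_inside(image)
        return image.pixels[self.y:self.y + self.h, self.x:self.x + self.w]


@dataclass(frozen=True)
class ChannelStats:
    """First two moments of one intensity channel."""

    channel: str
    mean: float
    std: float
    n: int

    def __post_init__(self):
        if self.std < 0:
            raise ValueError("std must be >= 0")
        if self.n < 1:
            raise ValueError("n must be >= 1")


def white_balance(
    image: RasterImage,
    patch: PatchRegion,
    std_ceiling: float = 12.0,
) -> RasterImage:
    """Neutralize the paraffin patch at its own mean luminance.

    Per-channel gains g_c = L / m_c, where m_c is the patch mean of channel
    c and L = (m_R + m_G + m_B) / 3; the whole frame is rescaled by these
    gains.  After the operation the patch has equal channel means (neutral
    gray) at unchanged overall luminance — the patch is treated as the
    "true" neutral reference without blowing out the rest of the image.

    A patch whose channel standard deviation exceeds ``std_ceiling``
    probably contains specimen rather than pure paraffin; this is logged as
    a warning, not an error.

    Raises
    ------
    ValueError
        If any patch channel mean is below 1 (a black patch cannot define
        a white point).
    """
    region = patch.extract(image).astype(np.float64)
    means = region.reshape(-1, 3).mean(axis=0)
    if np.any(means < 1.0):
        raise ValueError(f"patch channel means {means} too dark to serve as white reference")
    stds = region.reshape(-1, 3).std(axis=0)
    if np.any(stds > std_ceiling):
        logger.warning(
            "white-balance patch at (%d, %d) has channel std %s > %.1f — "
            "it may not contain only paraffin", patch.x, patch.y,
            np.round(stds, 1), std_ceiling,
        )
    target = means.mean()
    gains = target / means
    out = image.pixels.astype(np.float64) * gains
    return RasterImage(quantize_u8(out), image.pixel_size_mm)


def enhance_color(image: RasterImage, factor: float) -> RasterImage:
    """Scale per-pixel chroma about the luminance.

    ``out = gray + factor · (in − gray)`` with gray the ITU-R 601 luminance
    replicated across channels.  Factor 1 is the identity, 0 produces full
    desaturation, > 1 boosts saturation (values are clipped at the 8-bit
    range).

    Raises
    ------
    ValueError
        If ``factor`` is negative or not finite.
    """
    if not np.isfinite(factor) or factor < 0:
        raise ValueError(f"enhancement factor must be finite and >= 0, got {factor}")
    px = image.pixels.astype(np.float64)
    gray = px @ _LUMA
    out = gray[..., None] + factor * (px - gray[..., None])
    return RasterImage(quantize_u8(out), image.pixel_size_mm)


def value_channel_stats(image: RasterImage, channel: str = "V") -> ChannelStats:
    """Mean/std of the HSV value channel on the [0, 255] scale."""
    v = rgb2hsv(image.pixels.astype(np.float64) / 255.0)[..., 2] * 255.0
    return ChannelStats(channel=channel, mean=float(v.mean()), std=float(v.std()),
                        n=int(v.size))


def transfer_brightness(image: RasterImage, ref: ChannelStats) -> RasterImage:
    """Match the image's HSV value-channel statistics to a reference's.

    The image is converted to HSV (hexcone model, V ≡ max(R, G, B)); the
    value channel is remapped as ``V' = (V − μ_src)·(σ_ref/σ_src) + μ_ref``
    and clipped to the valid range; hue and saturation are untouched; the
    result is converted back to RGB and quantized.

    Raises
    ------
    ValueError
        If the image's own V standard deviation is zero (a constant image
        carries no contrast to rescale).
    """
    hsv = rgb2hsv(image.pixels.astype(np.float64) / 255.0)
    v = hsv[..., 2] * 255.0
    mu_src = v.mean()
    sigma_src = v.std()
    if sigma_src == 0:
        raise ValueError("source V channel is constant (std = 0); cannot transfer brightness")
    v_new = (v - mu_src) * (ref.std / sigma_src) + ref.mean
    hsv[..., 2] = np.clip(v_new, 0.0, 255.0) / 255.0
    out = hsv2rgb(hsv) * 255.0
    return RasterImage(quantize_u8(out), image.pixel_size_mm)


def normalize_stack(
    images: list[RasterImage],
    patch: PatchRegion,
    enhance_factor: float = 1.3,
    brightness_reference: str = "first",
) -> list[RasterImage]:
    """White-balance, enhance and brightness-match a stack of aligned images.

    ``brightness_reference`` selects the V-channel statistics target:
    ``'first'`` uses the first (reference) slice after its own white
    balance and enhancement; ``'global'`` uses the mean of all slices'
    statistics.
    """
    if brightness_reference not in ("first", "global"):
        raise ValueError("brightness_reference must be 'first' or 'global'")
    staged = [enhance_color(white_balance(img, patch), enhance_factor) for img in images]
    stats = [value_channel_stats(img) for img in staged]
    if brightness_reference == "first":
        ref = stats[0]
    else:
        ref = ChannelStats(
            channel="V",
            mean=float(np.mean([s.mean for s in stats])),
            std=float(np.mean([s.std for s in stats])),
            n=sum(s.n for s in stats),
        )
    return [transfer_brightness(img, ref) for img in staged]
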