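"""2D similarity transforms (uniform scale + rotation + translation).

The block cannot flip between cuts, so reflections are excluded: ``scale``
is strictly positive and the linear part is always a rotation scaled
uniformly.  Coordinates are image pixel coordinates: origin at the top-left
pixel center, x rightward, y downward, 0-based.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np


def wrap_angle(a: float) -> float:
    """Wrap an angle in radians to the interval (-pi, pi]."""
    a = math.remainder(a, 2.0 * math.pi)
    if a <= -math.pi:
        a += 2.0 * math.pi
    return a


@dataclass(frozen=True)
class SimilarityTransform:
    """Maps source coordinates ``p`` to reference coordinates ``q = s·R(θ)·p + t``.

    Parameters
    ----------
    scale : float
        Uniform scale factor, strictly positive (no reflection).
    rotation_rad : float
        Rotation angle in radians, stored wrapped to (-pi, pi].
        Positive angles rotate x toward y (clockwise on screen with
        y pointing down).
    translation : tuple of float
        (tx, ty) in pixels.
    """

    scale: float = 1.0
    rotation_rad: float = 0.0
    translation: tuple[float, float] = (0.0, 0.0)

    def __post_init__(self):
        if not (math.isfinite(self.scale) and self.scale > 0.0):
            raise ValueError(f"scale must be finite and > 0, got {self.scale}")
        if not math.isfinite(self.rotation_rad):
            raise ValueError("rotation must be finite")
        tx, ty = self.translation
        if not (math.isfinite(tx) and math.isfinite(ty)):
            raise ValueError("translation must be finite")
        object.__setattr__(self, "rotation_rad", wrap_angle(float(self.rotation_rad)))
        object.__setattr__(self, "scale", float(self.scale))
        object.__setattr__(self, "translation", (float(tx), float(ty)))

    @classmethod
    def identity(cls) -> "SimilarityTransform":
        return cls()

    @property
    def matrix(self) -> np.ndarray:
        """Homogeneous 3x3 matrix acting on column vectors (x, y, 1)."""
        c = math.cos(self.rotation_rad)
        s = math.sin(self.rotation_rad)
        a = self.scale
        tx, ty = self.translation
        return np.array(
            [[a * c, -a * s, tx],
             [a * s, a * c, ty],
             [0.0, 0.0, 1.0]]
        )

    @classmethod
    def from_matrix(cls, m: np.ndarray, atol: float = 1e-8) -> "SimilarityTransform":
        """Build from a homogeneous matrix, verifying it is a similarity."""
        m = np.asarray(m, dtype=float)
        if m.shape != (3, 3):
            raise ValueError("expected a 3x3 homogeneous matrix")
        lin = m[:2, :2]
        det = np.linalg.det(lin)
        if det <= 0:
            raise ValueError("linear part has non-positive determinant (reflection or collapse)")
        scale = math.sqrt(det)
        r = lin / scale
        if not np.allclose(r.T @ r, np.eye(2), atol=atol):
            raise ValueError("linear part is not a scaled rotation")
        rot = math.atan2(r[1, 0], r[0, 0])
        return cls(scale=scale, rotation_rad=rot, translation=(m[0, 2], m[1, 2]))

    def apply(self, points: np.ndarray) -> np.ndarray:
        """Transform points of shape (..., 2); returns the same shape."""
        p = np.asarray(points, dtype=float)
        c = math.cos(self.rotation_rad)
        s = math.sin(self.rotation_rad)
        a = self.scale
        x = a * (c * p[..., 0] - s * p[..., 1]) + self.translation[0]
        y = a * (s * p[..., 0] + c * p[..., 1]) + self.translation[1]
        return np.stack([x, y], axis=-1)

    def inverse(self) -> "SimilarityTransform":
        """The transform mapping reference coordinates back to source coordinates."""
        inv_scale = 1.0 / self.scale
        c = math.cos(-self.rotation_rad)
        s = math.sin(-self.rotation_rad)
        tx, ty = self.translation
        itx = -inv_scale * (c * tx - s * ty)
        ity = -inv_scale * (s * tx + c * ty)
        return SimilarityTransform(inv_scale, -self.rotation_rad, (itx, ity))

    def compose(self, other: "SimilarityTransform") -> "SimilarityTransform":
        """Return self ∘ other (``other`` applied first)."""
        a = self.scale
        c = math.cos(self.rotation_rad)
        s = math.sin(self.rotation_rad)
        ox, oy = other.translation
        tx = a * (c * ox - s * oy) + self.translation[0]
        ty = a * (s * ox + c * oy) + self.translation[1]
        return SimilarityTransform(
            scale=a * other.scale,
            rotation_rad=self.rotation_rad + other.rotation_rad,
            translation=(tx, ty),
        )

    def __matmul__(self, other: "SimilarityTransform") -> "SimilarityTransform":
        return self.compose(other)

    def is_identity(self, atol: float = 1e-12) -> bool:
        return (
            abs(self.scale - 1.0) <= atol
            and abs(self.rotation_rad) <= atol
            and abs(self.translation[0]) <= atol
            and abs(self.translation[1]) <= atol
        )

    @classmethod
    def about_point(
        cls,
        scale: float,
        rotation_rad: float,
        center: tuple[float, float],
        extra_translation: tuple[float, float] = (0.0, 0.0),
    ) -> "SimilarityTransform":
        """Scale+rotate about ``center`` and then shift by ``extra_translation``.

        T(p) = s·R·(p − c) + c + d  — convenient for camera-centered
        magnification and rotation jitter.
        """
        base = cls(scale=scale, rotation_rad=rotation_rad)
        cx, cy = center
        dx, dy = extra_translation
        rc = base.apply(np.array([cx, cy], dtype=float))
        return cls(
            scale=scale,
            rotation_rad=rotation_rad,
            translation=(cx + dx - rc[0], cy + dy - rc[1]),
        )
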