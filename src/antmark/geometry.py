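"""Ground footprint of a tilted camera and filmed scene areas.

A camera at height ``OA`` above the ground, tilted by ``alpha`` degrees from
the horizontal-plane normal direction and imaging an angular extent of
``2 * beta`` about its optical axis, covers a ground segment of length

    BD = Height * (tan(alpha + beta) - tan(alpha - beta)).

The printed angles of view (16 degrees horizontal, 7.5 degrees vertical) act
as the half-angle ``beta`` in this relation: with camera height 30 cm that is
the only convention reproducing the published scene dimensions (17 cm wide,
8 cm deep untilted; 16 cm deep at 45 degrees; 11 cm at 30 degrees).  The
horizontal width is always computed with alpha = 0 since the tilt is purely in
the vertical plane — consistent with every scene printing a 17 cm width.

Reported dimensions are rounded to the nearest centimetre and the scene area
is the product of the *rounded* dimensions (136 = 17 * 8, not 17.21 * 7.90).
"""

from __future__ import annotations

import math
from dataclasses import dataclass

from .errors import DomainError, FootprintError
from .mot_io import SequenceMeta

__all__ = ["CameraSetup", "SceneArea", "ground_extent", "scene_area", "scene_area_from_meta"]


@dataclass(frozen=True)
class CameraSetup:
    """Filming geometry: camera height, tilt and the two angles of view."""

    height_cm: float
    tilt_deg: float
    view_angle_h_deg: float = 16.0
    view_angle_v_deg: float = 7.5

    def __post_init__(self) -> None:
        if self.height_cm <= 0:
            raise DomainError("camera height must be > 0")
        if not (0 <= abs(self.tilt_deg) < 90):
            raise DomainError("tilt angle must lie in (-90, 90)")
        if self.view_angle_h_deg <= 0 or self.view_angle_v_deg <= 0:
            raise DomainError("view angles must be > 0")

    @classmethod
    def from_meta(cls, meta: SequenceMeta) -> "CameraSetup":
        return cls(
            height_cm=meta.camera_height_cm,
            tilt_deg=meta.tilt_angle_deg,
            view_angle_h_deg=meta.view_angle_h_deg,
            view_angle_v_deg=meta.view_angle_v_deg,
        )


@dataclass(frozen=True)
class SceneArea:
    width_cm: int
    depth_cm: int
    area_cm2: int

    def __str__(self) -> str:
        return f"{self.width_cm} cm × {self.depth_cm} cm = {self.area_cm2} cm²"


def ground_extent(height_cm: float, alpha_deg: float, beta_deg: float) -> float:
    """Length of the ground segment imaged along one axis, in cm.

    Symmetric in the sign of ``alpha`` (tangent oddness); reduces to
    ``2 * h * tan(beta)`` for an untilted camera.  A view cone reaching the
    horizon (``|alpha| + beta >= 90``) has an unbounded footprint and raises.
    """
    if height_cm <= 0:
        raise DomainError("camera height must be > 0")
    if beta_deg < 0:
        raise DomainError("view half-angle must be >= 0")
    alpha = abs(alpha_deg)
    if alpha + beta_deg >= 90:
        raise FootprintError(
            f"view cone reaches the horizon (alpha {alpha} + beta {beta_deg} >= 90 deg)"
        )
    a = math.radians(alpha)
    b = math.radians(beta_deg)
    return height_cm * (math.tan(a + b) - math.tan(a - b))


def _round_cm(x: float) -> int:
    return int(math.floor(x + 0.5))


def scene_area(setup: CameraSetup) -> SceneArea:
    """Filmed scene dimensions and area, rounded to whole centimetres.

    Width uses the horizontal angle of view with no tilt; depth uses the
    vertical angle of view with the camera's tilt.
    """
    width = ground_extent(setup.height_cm, 0.0, setup.view_angle_h_deg)
    depth = ground_extent(setup.height_cm, setup.tilt_deg, setup.view_angle_v_deg)
    w, d = _round_cm(width), _round_cm(depth)
    return SceneArea(width_cm=w, depth_cm=d, area_cm2=w * d)


def scene_area_from_meta(meta: SequenceMeta) -> SceneArea:
    """Scene area of a manifest sequence."""
    return scene_area(CameraSetup.from_meta(meta))
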