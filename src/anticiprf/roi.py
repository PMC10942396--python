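"""Wedge ROIs around the four attentional targets and polar-angle utilities.

Polar convention (package-wide): 0 deg = right horizontal meridian,
counterclockwise positive, 90 deg = up. Targets sit at 6 deg eccentricity on
the cardinal meridians.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

__all__ = [
    "TARGET_ANGLES",
    "TARGET_ECCENTRICITY",
    "target_center",
    "polar_angle_distance",
    "cart_to_polar",
    "WedgeROISpec",
    "select_wedge_roi",
]

TARGET_ANGLES = {"up": 90.0, "down": 270.0, "left": 180.0, "right": 0.0}
TARGET_ECCENTRICITY = 6.0


def target_center(location: str, eccentricity: float = TARGET_ECCENTRICITY):
    """(x, y) of a cardinal target in degrees of visual angle."""
    theta = np.deg2rad(TARGET_ANGLES[location])
    return (eccentricity * np.cos(theta), eccentricity * np.sin(theta))


def polar_angle_distance(a, b):
    """Wrap-aware signed angular difference a - b in (-180, 180] degrees."""
    d = (np.asarray(a, dtype=float) - np.asarray(b, dtype=float) + 180.0) % 360.0 - 180.0
    d = np.where(d == -180.0, 180.0, d)
    return d if d.ndim else float(d)


def cart_to_polar(x, y):
    """(polar angle in [0, 360), eccentricity) from visual-field coordinates."""
    angle = np.rad2deg(np.arctan2(y, x)) % 360.0
    ecc = np.hypot(x, y)
    return angle, ecc


@dataclass
class WedgeROISpec:
    """Vertex-selection rule for a cortical target ROI.

    Vertices qualify when their average-condition pRF has an eccentricity in
    ``ecc_range``, a polar angle within ``half_width`` of the target meridian
    (so the printed wedges, e.g. up: 60-120 deg), and a GLM variance explained
    above ``min_glm_ve``. Interval bounds are closed on angle and
    eccentricity, exclusive on variance explained (">5%").
    """

    target_angle: float
    ecc_range: tuple = (4.0, 8.0)
    half_width: float = 30.0
    min_glm_ve: float = 0.05

    def __post_init__(self):
        if not (0 < self.half_width <= 90):
            raise ValueError("half_width must lie in (0, 90]")
        if self.ecc_range[0] >= self.ecc_range[1]:
            raise ValueError("eccentricity band must have low < high")


def select_wedge_roi(prfs: pd.DataFrame, spec: WedgeROISpec) -> np.ndarray:
    """Indices of vertices inside a wedge ROI.

    ``prfs`` needs columns x, y (average-condition pRF center, degrees) and
    glm_ve (GLM variance explained, fraction). Returns positional indices;
    empty selections are returned (with a warning), not raised.
    """
    angle, ecc = cart_to_polar(prfs["x"].to_numpy(), prfs["y"].to_numpy())
    dist = np.abs(polar_angle_distance(angle, spec.target_angle))
    keep = (
        (ecc >= spec.ecc_range[0])
        & (ecc <= spec.ecc_range[1])
        & (dist <= spec.half_width)
        & (prfs["glm_ve"].to_numpy() > spec.min_glm_ve)
    )
    idx = np.flatnonzero(keep)
    if idx.size == 0:
        import warnings

        warnings.warn("wedge ROI selection is empty", stacklevel=2)
    return idx
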