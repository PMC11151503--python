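"""Synthetic fiber-mat images emulating SEM views of electrospun scaffolds.

Fibers are anti-aliased straight tubes spanning the image, with angles drawn
from a configurable orientation law.  Angles follow the package convention:
degrees in [-90, 90), 0 deg = image x-axis, counter-clockwise positive
(y up).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional, Union

import numpy as np

from ..core import ChannelImage
from .scenes import GroundTruth

__all__ = ["FiberSceneSpec", "sample_fiber_angles", "simulate_fiber_image"]


def wrap_angle_deg(theta: np.ndarray) -> np.ndarray:
    """Wrap angles to [-90, 90) on the 180-degree orientation period."""
    return (np.asarray(theta, float) + 90.0) % 180.0 - 90.0


@dataclass
class FiberSceneSpec:
    """Fiber-image specification.

    orientation_law : one of
        ``("delta", theta0)`` — every fiber at exactly theta0;
        ``("uniform",)`` — uniform on [-90, 90);
        ``("wrapped_normal", theta0, kappa)`` — normal with standard
        deviation ``1/sqrt(kappa)`` radians around theta0, wrapped to the
        orientation period (kappa -> inf collapses to delta; kappa -> 0 is
        effectively uniform).
    fiber_width_px : constant width, or ``(mean, sd)`` for a clipped normal
        per-fiber width draw.
    """

    image_shape: tuple[int, int] = (1024, 1024)
    n_fibers: int = 50
    orientation_law: tuple = ("uniform",)
    fiber_width_px: Union[float, tuple] = 8.0
    intensity: float = 1.0
    noise_model: str = "none"  # "none" | "gaussian:<sigma>"
    pixel_size_um: float = 0.05
    seed: Optional[int] = None

    def __post_init__(self) -> None:
        if self.n_fibers < 1:
            raise ValueError("n_fibers must be >= 1")
        law = self.orientation_law[0]
        if law not in ("delta", "uniform", "wrapped_normal"):
            raise ValueError(f"unknown orientation law {law!r}")
        if law in ("delta", "wrapped_normal"):
            theta0 = float(self.orientation_law[1])
            if not (-90.0 <= theta0 < 90.0):
                raise ValueError("theta0 must lie in [-90, 90)")
        widths = (
            self.fiber_width_px
            if isinstance(self.fiber_width_px, (tuple, list))
            else (self.fiber_width_px,)
        )
        if widths[0] <= 0:
            raise ValueError("fiber width must be positive")
        if self.intensity <= 0:
            raise ValueError("intensity must be positive")


def sample_fiber_angles(
    law: tuple, n: int, rng: np.random.Generator
) -> np.ndarray:
    """Draw ``n`` fiber orientation angles (degrees in [-90, 90))."""
    kind = law[0]
    if kind == "delta":
        return np.full(n, float(law[1]))
    if kind == "uniform":
        return rng.uniform(-90.0, 90.0, n)
    if kind == "wrapped_normal":
        theta0, kappa = float(law[1]), float(law[2])
        if kappa <= 0:
            return rng.uniform(-90.0, 90.0, n)
        sigma_deg = np.degrees(1.0 / np.sqrt(kappa))
        return wrap_angle_deg(theta0 + rng.normal(0.0, sigma_deg, n))
    raise ValueError(f"unknown orientation law {kind!r}")


def _sample_widths(spec: FiberSceneSpec, rng: np.random.Generator) -> np.ndarray:
    if isinstance(spec.fiber_width_px, (tuple, list)):
        mean, sd = spec.fiber_width_px
        return np.clip(rng.normal(mean, sd, spec.n_fibers), 1.0, None)
    return np.full(spec.n_fibers, float(spec.fiber_width_px))


def simulate_fiber_image(spec: FiberSceneSpec) -> tuple[ChannelImage, GroundTruth]:
    """Render ``n_fibers`` anti-aliased straight fibers.

    Each fiber is an infinite line through a random anchor point; pixel
    intensity falls off linearly over the last pixel of the half-width
    (anti-aliasing), and overlapping fibers compose by maximum, emulating an
    opaque mat.  True angles and widths are returned in the ground truth.
    """
    rng = np.random.default_rng(spec.seed)
    angles = sample_fiber_angles(spec.orientation_law, spec.n_fibers, rng)
    widths = _sample_widths(spec, rng)
    h, w = spec.image_shape
    rr, cc = np.mgrid[0:h, 0:w]
    # math coords: x right, y up
    px = cc.astype(float)
    py = (h - 1 - rr).astype(float)
    img = np.zeros((h, w))
    for theta, width in zip(angles, widths):
        t = np.deg2rad(theta)
        dx, dy = np.cos(t), np.sin(t)
        ax = rng.uniform(0, w)
        ay = rng.uniform(0, h)
        dist = np.abs((px - ax) * dy - (py - ay) * dx)
        tube = np.clip(width / 2.0 + 0.5 - dist, 0.0, 1.0)
        np.maximum(img, tube, out=img)
    img *= spec.intensity
    if spec.noise_model.startswith("gaussian:"):
        sigma = float(spec.noise_model.split(":", 1)[1])
        img = np.clip(img + rng.normal(0.0, sigma, img.shape), 0.0, None)
    elif spec.noise_model != "none":
        raise ValueError("fiber images support 'none' or 'gaussian:<sigma>' noise")
    return (
        ChannelImage(img, channel="other", pixel_size_um=spec.pixel_size_um),
        GroundTruth(fiber_angles_deg=angles, fiber_widths_px=widths),
    )
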