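"""Scaffold architecture: fiber orientation, Herman's index, diameter, modulus.

Local fiber orientation is estimated per pixel from the 2x2 structure
tensor; each pixel contributes its orientation weighted by tensor coherence
times gradient energy.  The scalar order parameter is the 2D Herman
orientation index

    S = 2 <cos^2 theta> - 1,

with theta measured from a reference axis: S = 1 for perfect alignment
along the axis, 0 for an isotropic mat, -1 for alignment perpendicular to a
fixed axis.  When no reference is given the principal direction (the
maximizer of S) is used, which guarantees S in [0, 1] and makes the result
rotation-invariant.

Angles follow the package convention: degrees in [-90, 90), 0 = image
x-axis, counter-clockwise (y up).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional

import numpy as np
import pandas as pd
from scipy import stats
from skimage.feature import structure_tensor
from skimage.filters import threshold_li
from skimage.morphology import skeletonize
from scipy import ndimage as ndi

from .core import ChannelImage

__all__ = [
    "OrientationDistribution",
    "OrientationResult",
    "ModulusResult",
    "orientation_distribution",
    "hermans_index",
    "fiber_diameter",
    "young_modulus",
]


@dataclass
class OrientationDistribution:
    """Weighted sample of orientation angles (degrees in [-90, 90))."""

    angles_deg: np.ndarray
    weights: np.ndarray
    source: str = "per-pixel tensor"

    def __post_init__(self) -> None:
        self.angles_deg = np.asarray(self.angles_deg, float)
        self.weights = np.asarray(self.weights, float)
        if self.angles_deg.size == 0:
            raise ValueError("empty orientation distribution")
        if np.any(self.weights < 0):
            raise ValueError("weights must be non-negative")
        total = self.weights.sum()
        if total <= 0:
            raise ValueError("weights must have positive sum")
        self.weights = self.weights / total

    @classmethod
    def from_angles(cls, angles_deg, source="per-fiber") -> "OrientationDistribution":
        angles_deg = np.asarray(angles_deg, float)
        return cls(angles_deg, np.full(angles_deg.size, 1.0 / angles_deg.size), source)


@dataclass
class OrientationResult:
    """Herman orientation index with the reference axis used."""

    S: float
    reference_angle_deg: float
    n_samples: int


@dataclass
class ModulusResult:
    """Young's modulus from the linear region of a stress-strain record."""

    modulus_mpa: float
    intercept_mpa: float
    r_squared: float
    stderr_mpa: float
    strain_window: tuple[float, float]
    n_points: int


def orientation_distribution(
    image: ChannelImage,
    tensor_scale_px: float = 2.0,
    energy_fraction: float = 0.05,
    border_margin: Optional[int] = None,
) -> OrientationDistribution:
    """Per-pixel local orientation from the structure tensor.

    The gradient-covariance (structure) tensor is smoothed at
    ``tensor_scale_px``; pixel weights are coherence x energy, and pixels
    with energy below ``energy_fraction`` of the maximum (background) or
    within ``border_margin`` of the image edge (default ``3 * scale``) are
    excluded.
    """
    img = image.pixels
    if np.ptp(img) == 0:
        raise ValueError("constant image has no orientation")
    Arr, Arc, Acc = structure_tensor(img, sigma=tensor_scale_px, order="rc")
    half_trace = (Arr + Acc) / 2.0
    root = np.sqrt(((Arr - Acc) / 2.0) ** 2 + Arc**2)
    l1, l2 = half_trace + root, half_trace - root
    energy = l1 + l2
    coherence = np.where(energy > 0, (l1 - l2) / np.where(energy > 0, energy, 1.0), 0.0)
    # dominant gradient direction relative to the row axis equals the fiber
    # direction relative to the x axis in the y-up convention
    theta = np.degrees(0.5 * np.arctan2(2.0 * Arc, Arr - Acc))
    margin = border_margin if border_margin is not None else int(3 * tensor_scale_px) + 1
    keep = energy > energy_fraction * energy.max()
    if margin > 0:
        border = np.zeros(img.shape, bool)
        border[margin:-margin or None, margin:-margin or None] = True
        keep &= border
    if not keep.any():
        raise ValueError("no pixels above the energy threshold")
    return OrientationDistribution(
        angles_deg=theta[keep],
        weights=(coherence * energy)[keep],
        source="per-pixel tensor",
    )


def hermans_index(
    dist: OrientationDistribution,
    reference_angle_deg: Optional[float] = None,
    form: str = "2d",
) -> OrientationResult:
    """Herman orientation index of a weighted angle distribution.

    With the default auto reference (principal direction) S lies in [0, 1];
    a fixed reference axis admits S down to -1 (all mass perpendicular).
    ``form="3d"`` returns the three-dimensional variant
    ``(3 <cos^2> - 1)/2``.
    """
    two_theta = np.deg2rad(2.0 * dist.angles_deg)
    c = float(np.sum(dist.weights * np.cos(two_theta)))
    s = float(np.sum(dist.weights * np.sin(two_theta)))
    if reference_angle_deg is None:
        reference_angle_deg = float(np.degrees(0.5 * np.arctan2(s, c)))
        s_2d = float(np.hypot(c, s))
    else:
        phi = np.deg2rad(2.0 * reference_angle_deg)
        # <cos 2(theta - ref)> = C cos2ref + S sin2ref
        s_2d = c * np.cos(phi) + s * np.sin(phi)
    if form == "2d":
        value = s_2d
    elif form == "3d":
        cos2 = (1.0 + s_2d) / 2.0  # <cos^2 (theta - ref)>
        value = (3.0 * cos2 - 1.0) / 2.0
    else:
        raise ValueError("form must be '2d' or '3d'")
    return OrientationResult(
        S=float(value),
        reference_angle_deg=float(reference_angle_deg),
        n_samples=int(dist.angles_deg.size),
    )


def fiber_diameter(
    image: ChannelImage,
    pixel_size_um: Optional[float] = None,
) -> pd.Series:
    """Fiber diameter distribution (micrometres) via skeleton + distance map.

    Minimum cross-entropy threshold -> skeletonize -> diameter at each
    skeleton pixel = 2 x Euclidean distance to background.  Returns the
    per-skeleton-pixel diameters; use ``.mean()``/``.std()`` for the
    summary.
    """
    px = pixel_size_um if pixel_size_um is not None else image.pixel_size_um
    img = image.pixels
    if np.ptp(img) == 0:
        raise ValueError("empty foreground: constant image")
    mask = img > threshold_li(img)
    if not mask.any():
        raise ValueError("empty foreground after thresholding")
    skel = skeletonize(mask)
    edt = ndi.distance_transform_edt(mask)
    # EDT at a centerline pixel of a w-px ribbon is (w+1)/2, hence the -1
    diameters = np.maximum(2.0 * edt[skel] - 1.0, 0.0) * px
    return pd.Series(diameters, name="diameter_um")


def young_modulus(
    curve: pd.DataFrame,
    linear_region: Optional[tuple[float, float]] = None,
    min_points: int = 5,
    r2_threshold: float = 0.99,
) -> ModulusResult:
    """Least-squares slope of stress vs strain over the linear region.

    With an explicit ``linear_region`` (strain window) the slope is fitted
    directly.  Otherwise the maximal leading window with coefficient of
    determination >= ``r2_threshold`` is selected; if no window qualifies an
    error reports the best window found.
    """
    strain = np.asarray(curve["strain"], float)
    stress = np.asarray(curve["stress_mpa"], float)
    if strain.size < min_points:
        raise ValueError(f"need at least {min_points} points, got {strain.size}")
    if np.any(np.diff(strain) <= 0):
        raise ValueError("strain must be strictly increasing")

    def fit(sel: np.ndarray) -> ModulusResult:
        res = stats.linregress(strain[sel], stress[sel])
        return ModulusResult(
            modulus_mpa=float(res.slope),
            intercept_mpa=float(res.intercept),
            r_squared=float(res.rvalue**2),
            stderr_mpa=float(res.stderr),
            strain_window=(float(strain[sel].min()), float(strain[sel].max())),
            n_points=int(sel.sum()),
        )

    if linear_region is not None:
        lo, hi = linear_region
        sel = (strain >= lo) & (strain <= hi)
        if sel.sum() < min_points:
            raise ValueError("fewer than min_points in the requested strain window")
        return fit(sel)

    best: Optional[ModulusResult] = None
    chosen: Optional[ModulusResult] = None
    for end in range(min_points, strain.size + 1):
        sel = np.zeros(strain.size, bool)
        sel[:end] = True
        result = fit(sel)
        if best is None or result.r_squared > best.r_squared:
            best = result
        if result.r_squared >= r2_threshold:
            chosen = result  # maximal leading window that still qualifies
    if chosen is None:
        raise ValueError(
            "no leading window reaches "
            f"R^2 >= {r2_threshold}; best was R^2 = {best.r_squared:.4f} over "
            f"strain {best.strain_window}"
        )
    return chosen
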