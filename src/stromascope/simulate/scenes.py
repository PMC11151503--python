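"""Synthetic cell fields of view: intensity channels and FLIM stacks.

Cells are rendered as disks with an elliptical nucleus; each cell carries
per-channel mean intensities (or a programmed redox state, from which NADH
and FAD means follow) and, for FLIM scenes, two-component decay parameters.
The paired :class:`GroundTruth` records the true label maps, the noiseless
per-cell integrated intensities and every programmed parameter, so
downstream stages have exact bookkeeping oracles.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
import pandas as pd

from ..core import ChannelImage, DecayHistogram, FLIMImage, LabelMap, CHANNEL_TAGS
from .decay import expected_decay_counts

__all__ = [
    "CellSpec",
    "SceneSpec",
    "GroundTruth",
    "simulate_flim_image",
    "simulate_channel_scene",
]


@dataclass
class CellSpec:
    """One synthetic cell: geometry, channel intensities, decay parameters.

    ``nucleus_radius`` is the nuclear semi-minor axis; the semi-major axis is
    ``nucleus_radius * nucleus_aspect`` and must fit inside the cell radius.
    ``redox_state``, if given, is the programmed true ORR; NADH and FAD
    channel means are then derived as ``(1-orr)*redox_total`` and
    ``orr*redox_total``.
    """

    center: tuple[float, float]  # (row, col)
    radius: float
    nucleus_radius: float = 0.0
    nucleus_aspect: float = 1.0
    nucleus_angle_deg: float = 0.0
    channel_means: dict = field(default_factory=dict)
    nucleus_means: dict = field(default_factory=dict)
    decay: Optional[dict] = None  # {tau1_ns, tau2_ns, alpha1, photons_per_pixel}
    redox_state: Optional[float] = None
    redox_total: float = 100.0

    def __post_init__(self) -> None:
        if self.radius <= 0:
            raise ValueError("cell radius must be positive")
        if self.nucleus_radius < 0:
            raise ValueError("nucleus_radius must be >= 0")
        if self.nucleus_aspect < 1.0:
            raise ValueError("nucleus_aspect is semi-major/semi-minor, must be >= 1")
        if self.nucleus_radius * self.nucleus_aspect > self.radius:
            raise ValueError("nucleus must lie inside its cell")
        for d in (self.channel_means, self.nucleus_means):
            for ch, v in d.items():
                if ch not in CHANNEL_TAGS:
                    raise ValueError(f"unknown channel name {ch!r}")
                if v < 0:
                    raise ValueError("channel intensities must be >= 0")
        if self.redox_state is not None:
            if not (0.0 <= self.redox_state <= 1.0):
                raise ValueError("redox_state (true ORR) must lie in [0, 1]")
            self.channel_means = dict(self.channel_means)
            self.channel_means.setdefault("FAD", self.redox_state * self.redox_total)
            self.channel_means.setdefault(
                "NADH", (1.0 - self.redox_state) * self.redox_total
            )

    def mean_for(self, channel: str, region: str) -> float:
        if region == "nucleus" and channel in self.nucleus_means:
            return self.nucleus_means[channel]
        if channel in self.channel_means:
            return self.channel_means[channel]
        if channel in self.nucleus_means:
            # nucleus-only stain (e.g. DRAQ5): zero in cytoplasm
            return 0.0
        raise ValueError(f"channel {channel!r} not named in cell descriptor")


@dataclass
class SceneSpec:
    """A field of view: image grid, cells, background and noise model."""

    image_shape: tuple[int, int] = (256, 256)
    pixel_size_um: float = 0.39  # ~100 um field over 256 px
    cells: Sequence[CellSpec] = field(default_factory=list)
    background_level: float = 0.0
    background_tau_ns: float = 1.0  # mono-exponential decay of FLIM background
    noise_model: str = "none"  # "none" | "poisson" | "gaussian:<sigma>"
    seed: Optional[int] = None

    def __post_init__(self) -> None:
        if self.background_level < 0:
            raise ValueError("background_level must be >= 0")
        nm = self.noise_model
        if nm not in ("none", "poisson") and not nm.startswith("gaussian:"):
            raise ValueError("noise_model must be 'none', 'poisson' or 'gaussian:<sigma>'")

    def gaussian_sigma(self) -> Optional[float]:
        if self.noise_model.startswith("gaussian:"):
            return float(self.noise_model.split(":", 1)[1])
        return None


@dataclass
class GroundTruth:
    """Paired ground truth for a generated scene, fiber image or table."""

    cell_labels: Optional[LabelMap] = None
    nuclei_labels: Optional[LabelMap] = None
    per_cell: Optional[pd.DataFrame] = None
    fiber_angles_deg: Optional[np.ndarray] = None
    fiber_widths_px: Optional[np.ndarray] = None
    fold_changes: Optional[dict] = None
    modulus_mpa: Optional[float] = None


def _render_labels(spec: SceneSpec) -> tuple[LabelMap, LabelMap]:
    """Rasterize cell and nucleus label maps; overlaps resolved by nearest
    center (with a warning)."""
    h, w = spec.image_shape
    rr, cc = np.mgrid[0:h, 0:w]
    cells = np.zeros((h, w), np.int32)
    nuclei = np.zeros((h, w), np.int32)
    best_d2 = np.full((h, w), np.inf)
    overlap = False
    for i, cell in enumerate(spec.cells, start=1):
        cy, cx = cell.center
        d2 = (rr - cy) ** 2 + (cc - cx) ** 2
        inside = d2 <= cell.radius**2
        overlap = overlap or bool(np.any(inside & (cells > 0)))
        take = inside & (d2 < best_d2)
        cells[take] = i
        best_d2[take] = d2[take]
    if overlap:
        warnings.warn("overlapping cells resolved by nearest-center assignment",
                      stacklevel=3)
    for i, cell in enumerate(spec.cells, start=1):
        if cell.nucleus_radius <= 0:
            continue
        cy, cx = cell.center
        th = np.deg2rad(cell.nucleus_angle_deg)
        a = cell.nucleus_radius * cell.nucleus_aspect
        b = cell.nucleus_radius
        # x right, y up: y = -(row offset)
        x = cc - cx
        y = -(rr - cy)
        u = x * np.cos(th) + y * np.sin(th)
        v = -x * np.sin(th) + y * np.cos(th)
        inside = (u / a) ** 2 + (v / b) ** 2 <= 1.0
        nuclei[inside & (cells == i)] = i
    return (
        LabelMap(cells, kind="cell", provenance="synthetic scene"),
        LabelMap(nuclei, kind="nuclei", provenance="synthetic scene"),
    )


def _apply_noise(img: np.ndarray, spec: SceneSpec, rng: np.random.Generator) -> np.ndarray:
    if spec.noise_model == "poisson":
        return rng.poisson(img).astype(float)
    sigma = spec.gaussian_sigma()
    if sigma is not None:
        return np.clip(img + rng.normal(0.0, sigma, img.shape), 0.0, None)
    return img


def simulate_channel_scene(
    scene: SceneSpec, channels: Sequence[str]
) -> tuple[dict, GroundTruth]:
    """Render one image per requested channel on a shared grid.

    Returns ``(images, truth)`` where ``images`` maps channel name to
    :class:`ChannelImage` and ``truth.per_cell`` records the noiseless
    integrated intensity of every cell (whole-cell label) and nucleus per
    channel.
    """
    for ch in channels:
        if ch not in CHANNEL_TAGS:
            raise ValueError(f"unknown channel name {ch!r}")
    cell_labels, nuclei_labels = _render_labels(scene)
    rng = np.random.default_rng(scene.seed)
    images: dict[str, ChannelImage] = {}
    rows: list[dict] = []
    for i, cell in enumerate(scene.cells, start=1):
        row = {"cell_id": i}
        if cell.redox_state is not None:
            row["true_orr"] = cell.redox_state
        if cell.decay is not None:
            row.update(
                true_alpha1=cell.decay["alpha1"],
                true_tau1_ns=cell.decay["tau1_ns"],
                true_tau2_ns=cell.decay["tau2_ns"],
            )
        rows.append(row)
    for ch in channels:
        img = np.full(scene.image_shape, float(scene.background_level))
        for i, cell in enumerate(scene.cells, start=1):
            cyto = (cell_labels.labels == i) & (nuclei_labels.labels != i)
            nuc = nuclei_labels.labels == i
            img[cyto] = cell.mean_for(ch, "cytoplasm")
            img[nuc] = cell.mean_for(ch, "nucleus")
        for i in range(len(scene.cells)):
            cid = i + 1
            rows[i][f"true_integrated_{ch}"] = float(
                img[cell_labels.labels == cid].sum()
            )
            rows[i][f"true_nucleus_integrated_{ch}"] = float(
                img[nuclei_labels.labels == cid].sum()
            )
        noisy = _apply_noise(img, scene, rng)
        images[ch] = ChannelImage(noisy, channel=ch, pixel_size_um=scene.pixel_size_um)
    truth = GroundTruth(
        cell_labels=cell_labels,
        nuclei_labels=nuclei_labels,
        per_cell=pd.DataFrame(rows),
    )
    return images, truth


def simulate_flim_image(
    scene: SceneSpec,
    period_ns: float = 50.0,
    n_bins: int = 256,
) -> tuple[FLIMImage, GroundTruth]:
    """Render a per-pixel decay-histogram stack for a cell scene.

    Every cell descriptor must carry ``decay`` parameters; pixels take the
    decay of their owning region (cell, or background with
    ``scene.background_tau_ns``).  With ``noise_model='poisson'`` each
    (pixel, bin) count is an independent Poisson draw.
    """
    for cell in scene.cells:
        if cell.decay is None:
            raise ValueError("every cell descriptor must carry decay parameters")
    cell_labels, nuclei_labels = _render_labels(scene)
    h, w = scene.image_shape
    counts = np.zeros((h, w, n_bins))
    if scene.background_level > 0:
        profile = expected_decay_counts(
            [scene.background_tau_ns], [1.0], scene.background_level,
            period_ns, n_bins,
        )
        counts[:, :, :] = profile
    rows = []
    for i, cell in enumerate(scene.cells, start=1):
        d = cell.decay
        profile = expected_decay_counts(
            [d["tau1_ns"], d["tau2_ns"]],
            [d["alpha1"], 1.0 - d["alpha1"]],
            d.get("photons_per_pixel", 5000.0),
            period_ns,
            n_bins,
        )
        counts[cell_labels.labels == i] = profile
        rows.append(
            {
                "cell_id": i,
                "true_alpha1": d["alpha1"],
                "true_tau1_ns": d["tau1_ns"],
                "true_tau2_ns": d["tau2_ns"],
                "true_metabolic_index": d["alpha1"] / (1.0 - d["alpha1"])
                if d["alpha1"] < 1.0 else np.inf,
                "true_mean_lifetime_ns": d["alpha1"] * d["tau1_ns"]
                + (1.0 - d["alpha1"]) * d["tau2_ns"],
            }
        )
    if scene.noise_model == "poisson":
        rng = np.random.default_rng(scene.seed)
        counts = rng.poisson(counts).astype(float)
    elif scene.gaussian_sigma() is not None:
        raise ValueError("FLIM stacks support only 'none' or 'poisson' noise")
    truth = GroundTruth(
        cell_labels=cell_labels,
        nuclei_labels=nuclei_labels,
        per_cell=pd.DataFrame(rows),
    )
    return (
        FLIMImage(counts, period_ns=period_ns, pixel_size_um=scene.pixel_size_um),
        truth,
    )
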