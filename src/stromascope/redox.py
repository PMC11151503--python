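"""Optical redox ratio (ORR) imaging from NADH and FAD intensity channels.

ORR = I_FAD / (I_FAD + I_NADH) per pixel: 1 indicates a shift toward
oxidative phosphorylation, 0 toward glycolysis.  Images acquired under
different settings are first normalized by the spatial mean of a reference
dye (Rhodamine B) acquired at the same settings.  Per-cell values are the
mean ORR over the cytoplasm (whole cell minus nucleus), excluding
background and undefined (zero-denominator) pixels, which are masked and
never imputed.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Optional

import numpy as np
import pandas as pd

from .core import ChannelImage, LabelMap

__all__ = ["OrrResult", "normalize_by_reference", "orr_map", "per_cell_orr"]


@dataclass
class OrrResult:
    """Pixel-wise ORR map (masked where undefined) and per-cell means."""

    orr: np.ndarray  # float map, NaN where undefined
    mask: np.ndarray  # True where defined
    per_cell: Optional[pd.DataFrame] = None


def normalize_by_reference(image: ChannelImage, reference: ChannelImage) -> ChannelImage:
    """Divide an image by the spatial mean of its reference-dye image."""
    ref_mean = float(reference.pixels.mean())
    if ref_mean <= 0:
        raise ValueError("reference image has non-positive mean")
    return ChannelImage(
        image.pixels / ref_mean,
        channel=image.channel,
        normalized=True,
        pixel_size_um=image.pixel_size_um,
    )


def orr_map(
    nadh: ChannelImage,
    fad: ChannelImage,
    background: Optional[dict] = None,
) -> OrrResult:
    """Pixel-wise optical redox ratio.

    Optional per-channel scalar backgrounds (``{"NADH": b1, "FAD": b2}``)
    are subtracted with negative values clipped to zero; pixels where the
    resulting denominator is zero are masked.
    """
    if nadh.shape != fad.shape:
        raise ValueError("NADH and FAD images differ in shape")
    if nadh.normalized != fad.normalized:
        raise ValueError("normalization-flag mismatch between NADH and FAD images")
    b = background or {}
    i_nadh = np.clip(nadh.pixels - float(b.get("NADH", 0.0)), 0.0, None)
    i_fad = np.clip(fad.pixels - float(b.get("FAD", 0.0)), 0.0, None)
    denom = i_fad + i_nadh
    mask = denom > 0
    orr = np.full(denom.shape, np.nan)
    orr[mask] = i_fad[mask] / denom[mask]
    return OrrResult(orr=orr, mask=mask)


def estimate_background(image: ChannelImage, cell_labels: LabelMap) -> float:
    """Mean intensity over pixels outside all cell labels."""
    outside = cell_labels.labels == 0
    if not outside.any():
        return 0.0
    return float(image.pixels[outside].mean())


def per_cell_orr(
    result: OrrResult,
    cell_labels: LabelMap,
    nucleus_labels: Optional[LabelMap] = None,
    min_pixels: int = 20,
) -> OrrResult:
    """Mean ORR per cell over (cell mask - nucleus mask - undefined pixels).

    Cells with fewer than ``min_pixels`` qualifying pixels are dropped with
    a warning.  An empty nucleus map reduces to whole-cell aggregation.
    """
    if cell_labels.shape != result.orr.shape:
        raise ValueError("label map does not share the image grid")
    nuc = (
        nucleus_labels.labels
        if nucleus_labels is not None
        else np.zeros_like(cell_labels.labels)
    )
    rows, dropped = [], []
    for cid in cell_labels.ids:
        sel = (cell_labels.labels == cid) & (nuc != cid) & result.mask
        n = int(sel.sum())
        if n < min_pixels:
            dropped.append(int(cid))
            continue
        rows.append(
            {"cell_id": int(cid), "mean_orr": float(result.orr[sel].mean()),
             "n_pixels": n}
        )
    if dropped:
        warnings.warn(f"dropped cells with < {min_pixels} ORR pixels: {dropped}",
                      stacklevel=2)
    if not rows:
        raise ValueError("no cell has qualifying ORR pixels")
    return OrrResult(
        orr=result.orr, mask=result.mask,
        per_cell=pd.DataFrame(rows, columns=["cell_id", "mean_orr", "n_pixels"]),
    )
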