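"""Per-cell segmentation and quantification.

Nuclei are detected as primary objects by global minimum cross-entropy (Li)
thresholding, size-filtered and declumped by a distance-transform watershed.
Whole cells are grown from the nuclear seeds by propagation over a
distance-intensity hybrid cost (the CellProfiler-style secondary-object
strategy), restricted to the minimum cross-entropy foreground of the
cytoplasmic channel.  Per-cell measurements cover integrated intensity,
baseline-normalized fold change and nuclear circularity
4*pi*area/perimeter^2.
"""

from __future__ import annotations

import heapq
import warnings
from typing import Optional

import numpy as np
import pandas as pd
from scipy import ndimage as ndi
from skimage.feature import peak_local_max
from skimage.filters import threshold_li
from skimage.measure import find_contours, perimeter as _pixel_perimeter, perimeter_crofton
from skimage.segmentation import relabel_sequential, watershed

from .core import ChannelImage, LabelMap

__all__ = [
    "segment_nuclei",
    "propagate_cells",
    "integrated_intensity",
    "fold_change",
    "nuclear_circularity",
]


# ---------------------------------------------------------------------------
# segmentation
# ---------------------------------------------------------------------------

def segment_nuclei(
    nuclei_channel: ChannelImage,
    min_area_px: int = 50,
    max_area_px: int = 10_000,
    declump: bool = True,
    smoothing_sigma: float = 2.0,
) -> LabelMap:
    """Detect nuclei as primary objects.

    Global minimum cross-entropy threshold -> connected components -> size
    filter -> distance-transform watershed split of touching objects.
    """
    img = nuclei_channel.pixels
    if np.ptp(img) == 0:
        raise ValueError("no threshold: nuclei channel is constant")
    mask = img > threshold_li(img)
    labels, _ = ndi.label(mask)
    if declump and labels.max() > 0:
        distance = ndi.distance_transform_edt(mask)
        smoothed = ndi.gaussian_filter(distance, smoothing_sigma)
        coords = peak_local_max(
            smoothed, labels=labels, min_distance=int(2 * smoothing_sigma) + 1,
            exclude_border=False,
        )
        markers = np.zeros_like(labels)
        for i, (r, c) in enumerate(coords, start=1):
            markers[r, c] = i
        if markers.max() > 0:
            labels = watershed(-smoothed, markers, mask=mask)
    # size filter then contiguous relabel
    sizes = np.bincount(labels.ravel())
    kill = (sizes < min_area_px) | (sizes > max_area_px)
    kill[0] = False
    labels[np.isin(labels, np.nonzero(kill)[0])] = 0
    labels, _, _ = relabel_sequential(labels)
    return LabelMap(labels, kind="nuclei", provenance="minimum cross-entropy + watershed")


def propagate_cells(
    nuclei: LabelMap,
    cyto_channel: ChannelImage,
    regularization: float = 0.05,
) -> LabelMap:
    """Grow whole-cell labels from nuclear seeds by propagation.

    Foreground is the minimum cross-entropy threshold of the cytoplasmic
    channel united with the nuclei.  Each foreground pixel is assigned to
    the seed reached at minimum accumulated cost, where one step of length
    ``d`` between pixels with intensities ``a, b`` (intensity scaled to
    [0, 1]) costs ``d * regularization + |a - b|``.  With uniform intensity
    this reduces to nearest-seed geodesic distance.
    """
    if nuclei.shape != cyto_channel.shape:
        raise ValueError("nuclei and cytoplasm channel differ in shape")
    if nuclei.labels.max() == 0:
        raise ValueError("no nuclei seeds to propagate from")
    img = cyto_channel.pixels
    fg = (img > threshold_li(img)) if np.ptp(img) > 0 else np.zeros(img.shape, bool)
    fg |= nuclei.labels > 0
    if not fg.any():
        raise ValueError("no foreground to propagate into")
    span = np.ptp(img)
    norm = img / span if span > 0 else np.zeros_like(img)

    h, w = img.shape
    labels = np.zeros((h, w), np.int32)
    cost = np.full((h, w), np.inf)
    heap: list[tuple[float, int, int, int]] = []
    seeds = nuclei.labels > 0
    cost[seeds] = 0.0
    labels[seeds] = nuclei.labels[seeds]
    for r, c in zip(*np.nonzero(seeds)):
        heapq.heappush(heap, (0.0, int(nuclei.labels[r, c]), int(r), int(c)))
    steps = [(-1, -1, np.sqrt(2)), (-1, 0, 1.0), (-1, 1, np.sqrt(2)),
             (0, -1, 1.0), (0, 1, 1.0),
             (1, -1, np.sqrt(2)), (1, 0, 1.0), (1, 1, np.sqrt(2))]
    while heap:
        d, lab, r, c = heapq.heappop(heap)
        if d > cost[r, c]:
            continue
        for dr, dc, step in steps:
            rr, cc = r + dr, c + dc
            if rr < 0 or rr >= h or cc < 0 or cc >= w or not fg[rr, cc]:
                continue
            nd = d + step * regularization + abs(norm[rr, cc] - norm[r, c])
            if nd < cost[rr, cc]:
                cost[rr, cc] = nd
                labels[rr, cc] = lab
                heapq.heappush(heap, (nd, lab, rr, cc))
    return LabelMap(labels, kind="cell", provenance="propagation from nuclei seeds")


# ---------------------------------------------------------------------------
# per-cell measurements
# ---------------------------------------------------------------------------

def integrated_intensity(
    channel: ChannelImage,
    labels: LabelMap,
    condition: Optional[str] = None,
) -> pd.DataFrame:
    """Sum of pixel intensities and area per labelled object."""
    if channel.shape != labels.shape:
        raise ValueError("channel and label map differ in shape")
    ids = labels.ids
    if ids.size == 0:
        return pd.DataFrame(columns=["cell_id", "condition", "integrated_intensity",
                                     "area_px"])
    sums = ndi.sum_labels(channel.pixels, labels.labels, index=ids)
    areas = ndi.sum_labels(np.ones(labels.shape), labels.labels, index=ids)
    return pd.DataFrame(
        {
            "cell_id": ids.astype(int),
            "condition": condition,
            "integrated_intensity": sums,
            "area_px": areas.astype(int),
        }
    )


def fold_change(
    table: pd.DataFrame,
    baseline_condition: str,
    value_col: str = "integrated_intensity",
) -> pd.DataFrame:
    """Per-cell values divided by the mean value of the baseline condition.

    By construction the baseline condition's mean fold change is 1.
    """
    if baseline_condition not in set(table["condition"]):
        raise ValueError(f"baseline condition {baseline_condition!r} missing")
    baseline_mean = table.loc[
        table["condition"] == baseline_condition, value_col
    ].mean()
    out = table.copy()
    out["fold_change"] = out[value_col] / baseline_mean
    return out


# ---------------------------------------------------------------------------
# nuclear circularity
# ---------------------------------------------------------------------------

def _contour_perimeter(mask: np.ndarray, sigma: float) -> float:
    """Boundary length of a Gaussian-smoothed marching-squares contour.

    Smoothing the binary mask before contouring removes the staircase bias
    of rasterization (a naive pixel-edge count overstates a disk's
    perimeter by up to 27%), giving near-unbiased lengths for disks,
    squares and ellipses alike.
    """
    pad = int(np.ceil(3 * sigma)) + 2
    padded = np.pad(mask.astype(float), pad)
    smoothed = ndi.gaussian_filter(padded, sigma, mode="constant")
    contours = find_contours(smoothed, 0.5)
    return float(
        sum(np.hypot(*np.diff(c, axis=0).T).sum() for c in contours)
    )


def nuclear_circularity(
    nuclei: LabelMap,
    estimator: str = "contour",
    smoothing_sigma: float = 2.0,
) -> pd.DataFrame:
    """Circularity 4*pi*area/perimeter^2 per nucleus.

    ``estimator`` selects the perimeter measure: ``"contour"`` (smoothed
    marching-squares boundary length, default), ``"crofton"``
    (four-direction Crofton) or ``"pixel"`` (weighted pixel-edge count).
    Reported circularity is clipped at 1.0 (discretization can push raw
    values slightly above); the raw value is retained.  Single-pixel
    objects have undefined circularity (NaN) and are flagged.
    """
    ids = nuclei.ids
    if ids.size == 0:
        raise ValueError("empty label map")
    if estimator not in ("contour", "crofton", "pixel"):
        raise ValueError(f"unknown perimeter estimator {estimator!r}")
    objects = ndi.find_objects(nuclei.labels)
    rows = []
    for cid in ids:
        sl = objects[cid - 1]
        mask = nuclei.labels[sl] == cid
        area = int(mask.sum())
        if area <= 1:
            warnings.warn(f"nucleus {cid}: single-pixel object, circularity undefined",
                          stacklevel=2)
            rows.append({"cell_id": int(cid), "area_px": area,
                         "perimeter_px": np.nan, "circularity": np.nan,
                         "circularity_raw": np.nan})
            continue
        padded = np.pad(mask, 1)
        if estimator == "contour":
            perim = _contour_perimeter(padded, smoothing_sigma)
        elif estimator == "crofton":
            perim = float(perimeter_crofton(padded, directions=4))
        else:
            perim = float(_pixel_perimeter(padded, neighborhood=4))
        raw = 4.0 * np.pi * area / perim**2 if perim > 0 else np.nan
        rows.append(
            {"cell_id": int(cid), "area_px": area, "perimeter_px": perim,
             "circularity": min(raw, 1.0), "circularity_raw": raw}
        )
    return pd.DataFrame(rows)
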