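"""File I/O: TIFF images and FLIM stacks, CSV tables, JSON records.

Intensity images are written as 32-bit float TIFF; label maps as 16-bit
unsigned TIFF; FLIM stacks as multi-frame TIFF (one frame per time bin, bin
index in frame order) with a JSON sidecar holding period and bin count.
"""

from __future__ import annotations

import json
from pathlib import Path
from typing import Optional, Union

import numpy as np
import tifffile

from .core import ChannelImage, FLIMImage, LabelMap

__all__ = [
    "write_channel_tiff", "read_channel_tiff",
    "write_label_tiff", "read_label_tiff",
    "write_flim_stack", "read_flim_stack",
    "dump_json",
]

PathLike = Union[str, Path]


def write_channel_tiff(path: PathLike, image: ChannelImage) -> None:
    tifffile.imwrite(str(path), image.pixels.astype(np.float32))


def read_channel_tiff(
    path: PathLike, channel: str = "other", pixel_size_um: float = 1.0,
    normalized: bool = False,
) -> ChannelImage:
    return ChannelImage(
        tifffile.imread(str(path)).astype(float), channel=channel,
        normalized=normalized, pixel_size_um=pixel_size_um,
    )


def write_label_tiff(path: PathLike, labels: LabelMap) -> None:
    if labels.labels.max() > np.iinfo(np.uint16).max:
        raise ValueError("too many labels for 16-bit TIFF")
    tifffile.imwrite(str(path), labels.labels.astype(np.uint16))


def read_label_tiff(path: PathLike, kind: str = "cell") -> LabelMap:
    return LabelMap(tifffile.imread(str(path)).astype(np.int32), kind=kind,
                    provenance=str(path))


def write_flim_stack(path: PathLike, image: FLIMImage) -> None:
    """One TIFF frame per time bin plus a JSON sidecar {period_ns, n_bins}."""
    frames = np.moveaxis(image.counts, 2, 0).astype(np.float32)
    tifffile.imwrite(str(path), frames)
    sidecar = Path(str(path)).with_suffix(".json")
    sidecar.write_text(json.dumps(
        {"period_ns": image.period_ns, "n_bins": image.n_bins,
         "pixel_size_um": image.pixel_size_um}
    ))


def read_flim_stack(path: PathLike) -> FLIMImage:
    frames = tifffile.imread(str(path)).astype(float)
    sidecar = Path(str(path)).with_suffix(".json")
    meta = json.loads(sidecar.read_text()) if sidecar.exists() else {}
    counts = np.moveaxis(frames, 0, 2)
    return FLIMImage(
        counts, period_ns=float(meta.get("period_ns", 50.0)),
        pixel_size_um=float(meta.get("pixel_size_um", 1.0)),
    )


class _NumpyEncoder(json.JSONEncoder):
    def default(self, obj):
        if isinstance(obj, (np.integer,)):
            return int(obj)
        if isinstance(obj, (np.floating,)):
            return float(obj)
        if isinstance(obj, np.ndarray):
            return obj.tolist()
        if isinstance(obj, (np.bool_,)):
            return bool(obj)
        return super().default(obj)


def dump_json(obj, path: Optional[PathLike] = None, **kw) -> str:
    """Serialize (numpy-safe, sorted keys); optionally write to ``path``."""
    text = json.dumps(obj, cls=_NumpyEncoder, sort_keys=True, indent=2, **kw)
    if path is not None:
        Path(str(path)).write_text(text + "\n")
    return text
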