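"""Reading confocal z-stacks, maximum-intensity projection, pre-scaling.

Intensity measurements downstream always use unrescaled projected data;
:func:`rescale_to_range` exists for the fixed-range pre-scaling applied to
the DAPI channel before nuclear detection.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping

import numpy as np
import tifffile

__all__ = ["FieldStack", "FieldImage", "read_field", "max_project", "rescale_to_range"]

CHANNEL_ROLES = ("dapi", "tubulin", "target")


@dataclass
class FieldStack:
    """One field's multi-channel z-stack.

    ``channels`` maps channel name to a (z, y, x) array; all channels share
    a shape. Always includes the roles ``dapi`` and ``tubulin`` plus one or
    more protein ("target") channels.
    """

    channels: dict[str, np.ndarray]
    pixel_size: float
    z_step: float = 1.0
    provenance: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.pixel_size <= 0:
            raise ValueError("pixel_size must be > 0")
        shapes = {c.shape for c in self.channels.values()}
        if len(shapes) > 1:
            raise ValueError(f"channels disagree on shape: {shapes}")
        for name, arr in self.channels.items():
            if arr.ndim == 2:  # single-plane acquisition
                self.channels[name] = arr[None, :, :]
            elif arr.ndim != 3:
                raise ValueError(f"channel {name!r} must be 2-D or 3-D")

    @property
    def n_z(self) -> int:
        return next(iter(self.channels.values())).shape[0]


@dataclass
class FieldImage:
    """Per-channel 2-D projections of one field."""

    channels: dict[str, np.ndarray]
    pixel_size: float
    provenance: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        shapes = {c.shape for c in self.channels.values()}
        if len(shapes) > 1:
            raise ValueError(f"channels disagree on shape: {shapes}")

    @property
    def shape(self) -> tuple[int, int]:
        return next(iter(self.channels.values())).shape

    def __getitem__(self, channel: str) -> np.ndarray:
        return self.channels[channel]


def read_field(
    path: Path | str,
    channel_map: Mapping[str, int | str] | None = None,
    pixel_size: float | None = None,
    z_step: float = 1.0,
    provenance: dict | None = None,
) -> FieldStack:
    """Read a multi-page TIFF into a :class:`FieldStack`.

    ``channel_map`` maps channel names to channel indices (or, for files
    written with labelled ImageJ metadata, to stored label names) and must
    cover the roles dapi, tubulin and target. For files written by
    :mod:`rbploc.synthetic` the stored labels and pixel size are picked up
    automatically.
    """
    path = Path(path)
    with tifffile.TiffFile(path) as tf:
        arr = tf.asarray()
        axes = tf.series[0].axes
        labels = None
        meta = tf.imagej_metadata or {}
        if meta.get("Labels"):
            labels = list(meta["Labels"])
    arr = np.asarray(arr, dtype=np.float64)
    if arr.ndim == 2:  # single plane, single channel
        arr = arr[None, None]
    elif arr.ndim == 3:
        # ambiguous: CYX for multichannel single-plane, ZYX otherwise
        arr = arr[None] if axes.startswith("C") else arr[:, None]
    elif arr.ndim != 4:
        raise ValueError(f"cannot interpret TIFF with {arr.ndim} axes")
    if axes.startswith("C") and arr.ndim == 4 and axes[:2] == "CZ":
        arr = arr.transpose(1, 0, 2, 3)
    n_channels = arr.shape[1]
    if channel_map is None:
        if labels is None:
            raise ValueError("channel_map required: file carries no channel labels")
        channel_map = {name: name for name in labels}
    missing = [r for r in CHANNEL_ROLES if not _role_present(r, channel_map)]
    if missing:
        raise ValueError(f"missing channel: {missing[0]}")
    channels: dict[str, np.ndarray] = {}
    for name, key in channel_map.items():
        if isinstance(key, str):
            if labels is None or key not in labels:
                raise ValueError(f"channel label {key!r} not present in {path.name}")
            idx = labels.index(key)
        else:
            idx = int(key)
        if not 0 <= idx < n_channels:
            raise ValueError(f"channel index {idx} out of range for {path.name}")
        data = arr[:, idx]
        if not np.issubdtype(data.dtype, np.number):
            raise ValueError(f"channel {name!r} is non-numeric")
        if data.min() < 0:
            raise ValueError(f"channel {name!r} has negative intensities")
        channels[name] = data
    return FieldStack(
        channels=channels,
        pixel_size=pixel_size if pixel_size is not None else 1.0,
        z_step=z_step,
        provenance=provenance or {},
    )


def _role_present(role: str, channel_map: Mapping[str, int | str]) -> bool:
    if role in channel_map:
        return True
    # any extra named protein channel satisfies the "target" role
    return role == "target" and bool(set(channel_map) - {"dapi", "tubulin"})


def max_project(stack: FieldStack) -> FieldImage:
    """Per-channel maximum-intensity projection over z."""
    return FieldImage(
        channels={name: arr.max(axis=0) for name, arr in stack.channels.items()},
        pixel_size=stack.pixel_size,
        provenance=dict(stack.provenance),
    )


def rescale_to_range(image: np.ndarray, lo: float = 0.0, hi: float = 500.0) -> np.ndarray:
    """Linearly map an image's intensity range onto [lo, hi].

    The minimum maps to ``lo`` and the maximum to ``hi``; a constant image
    maps to ``lo`` everywhere. Rank order is preserved.
    """
    if hi <= lo:
        raise ValueError("hi must be > lo")
    image = np.asarray(image, dtype=np.float64)
    mn, mx = image.min(), image.max()
    if mx == mn:
        return np.full_like(image, lo)
    return lo + (image - mn) * ((hi - lo) / (mx - mn))
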