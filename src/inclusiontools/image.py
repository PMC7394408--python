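"""Multi-channel image container and TIFF round-trip.

A :class:`MultiChannelImage` is the unit every image operation consumes:
a mapping of named 2D float arrays (one per fluorescence channel) sharing a
single shape. Channels are named for the role the fluorophore plays in the
assay (``cerulean``, ``flash``, ``tmr``, ``antibody``, ``hoechst`` ...).

On disk an image is a multi-page TIFF, one page per channel, with the channel
names recorded as JSON in the description tag of the first page so a round
trip preserves naming.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import tifffile


@dataclass
class MultiChannelImage:
    channels: dict[str, np.ndarray] = field(default_factory=dict)

    def __post_init__(self) -> None:
        shapes = {ch.shape for ch in self.channels.values()}
        if len(shapes) > 1:
            raise ValueError(f"channels have mismatched shapes: {shapes}")
        for name, ch in self.channels.items():
            arr = np.asarray(ch, dtype=float)
            if arr.ndim != 2:
                raise ValueError(f"channel {name!r} is not 2D")
            self.channels[name] = arr

    @property
    def shape(self) -> tuple[int, int]:
        if not self.channels:
            raise ValueError("image has no channels")
        return next(iter(self.channels.values())).shape

    @property
    def channel_names(self) -> list[str]:
        return list(self.channels)

    def __getitem__(self, name: str) -> np.ndarray:
        return self.channels[name]

    def __contains__(self, name: str) -> bool:
        return name in self.channels


def write_tiff(image: MultiChannelImage, path: str | Path) -> None:
    """Write one page per channel; channel names go into the description tag."""
    names = image.channel_names
    stack = np.stack([image[n] for n in names]).astype(np.float32)
    tifffile.imwrite(
        path,
        stack,
        description=json.dumps({"channels": names}),
        photometric="minisblack",
    )


def read_tiff(path: str | Path, channel_names: list[str] | None = None) -> MultiChannelImage:
    """Read a multi-page TIFF back into a :class:`MultiChannelImage`.

    Channel names come from the embedded JSON description when present;
    otherwise they must be supplied (or default to ``page0``, ``page1``...).
    """
    with tifffile.TiffFile(path) as tif:
        stack = tif.asarray()
        desc = tif.pages[0].description or ""
    if stack.ndim == 2:
        stack = stack[None]
    names = channel_names
    if names is None:
        try:
            names = json.loads(desc)["channels"]
        except (json.JSONDecodeError, KeyError, TypeError):
            names = [f"page{i}" for i in range(stack.shape[0])]
    if len(names) != stack.shape[0]:
        raise ValueError(
            f"{len(names)} channel names for {stack.shape[0]} pages in {path}"
        )
    return MultiChannelImage({n: stack[i].astype(float) for i, n in enumerate(names)})


def write_frame_series(
    frames: list[MultiChannelImage],
    channel: str,
    path: str | Path,
    times: list[float] | None = None,
) -> None:
    """Write one channel of an image time series, one page per frame."""
    stack = np.stack([f[channel] for f in frames]).astype(np.float32)
    meta = {"channel": channel}
    if times is not None:
        meta["times_min"] = list(map(float, times))
    tifffile.imwrite(path, stack, description=json.dumps(meta), photometric="minisblack")


def read_frame_series(path: str | Path) -> tuple[np.ndarray, dict]:
    """Read a frame series written by :func:`write_frame_series`.

    Returns the (n_frames, rows, cols) array and the embedded metadata dict.
    """
    with tifffile.TiffFile(path) as tif:
        stack = tif.asarray().astype(float)
        desc = tif.pages[0].description or "{}"
    if stack.ndim == 2:
        stack = stack[None]
    try:
        meta = json.loads(desc)
    except json.JSONDecodeError:
        meta = {}
    return stack, meta
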