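"""Two-channel image container and TIFF plumbing."""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import tifffile


@dataclass
class TwoChannelImage:
    """Registered A/B fluorescence (or volume-fraction) intensity arrays.

    channel_A / channel_B are 2-D non-negative arrays of equal shape;
    pixel_size is the physical length per pixel (grid units or um).
    """

    channel_A: np.ndarray
    channel_B: np.ndarray
    pixel_size: float = 1.0
    metadata: dict = field(default_factory=dict)

    def __post_init__(self):
        self.channel_A = np.asarray(self.channel_A, dtype=float)
        self.channel_B = np.asarray(self.channel_B, dtype=float)
        if self.channel_A.shape != self.channel_B.shape:
            raise ValueError("channel shapes differ")
        if self.channel_A.ndim != 2:
            raise ValueError("channels must be 2-D")
        if (self.channel_A < 0).any() or (self.channel_B < 0).any():
            raise ValueError("intensities must be non-negative")

    @property
    def shape(self) -> tuple[int, int]:
        return self.channel_A.shape

    def stack(self) -> np.ndarray:
        """(2, H, W) array with channel A first."""
        return np.stack([self.channel_A, self.channel_B])


def write_tiff(path: str | Path, img: TwoChannelImage) -> None:
    """Write a two-channel 16-bit TIFF (channels as pages, A first).

    Intensities are rescaled jointly by the image maximum so relative channel
    brightness is preserved.
    """
    data = img.stack()
    peak = data.max()
    scale = 65535.0 / peak if peak > 0 else 1.0
    tifffile.imwrite(
        Path(path),
        (data * scale).round().astype(np.uint16),
        metadata={"axes": "CYX", "pixel_size": img.pixel_size},
    )


def read_tiff(
    path: str | Path, channel_order: tuple[int, int] = (0, 1), pixel_size: float = 1.0
) -> TwoChannelImage:
    """Read a two-channel TIFF (multi-page or multi-sample).

    ``channel_order`` selects which planes are channel A and B respectively.
    """
    data = np.asarray(tifffile.imread(Path(path)), dtype=float)
    if data.ndim == 2:
        raise ValueError("single-channel TIFF: two channels required")
    if data.ndim == 3 and data.shape[-1] in (2, 3, 4) and data.shape[0] not in (2, 3, 4):
        data = np.moveaxis(data, -1, 0)  # H,W,C -> C,H,W
    if data.ndim != 3 or data.shape[0] <= max(channel_order):
        raise ValueError(f"cannot interpret TIFF of shape {data.shape} as two channels")
    a, b = channel_order
    return TwoChannelImage(data[a], data[b], pixel_size=pixel_size)
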