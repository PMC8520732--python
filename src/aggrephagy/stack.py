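"""Multi-channel image stacks with acquisition metadata."""

from __future__ import annotations

import json
from dataclasses import dataclass, replace
from pathlib import Path

import numpy as np
import tifffile

__all__ = ["ImageStack", "CHANNEL_ROLES"]

#: Canonical channel order: mKeima excited at 445 nm, mKeima excited at
#: 561 nm, GFP-tagged marker.
CHANNEL_ROLES = ("mkeima_ex445", "mkeima_ex561", "gfp_marker")


@dataclass
class ImageStack:
    """Pixel data ``(T, C, Y, X)`` (or ``(Z, C, Y, X)`` in fixed-timepoint
    mode, with ``z_planes`` set) plus physical metadata.

    ``frame_interval`` is in seconds (20 s default, matching the live
    acquisition cadence); ``pixel_size`` in micrometres.
    """

    pixels: np.ndarray
    channel_roles: tuple[str, ...] = CHANNEL_ROLES
    frame_interval: float = 20.0
    pixel_size: float = 0.16
    z_planes: int | None = None

    def __post_init__(self) -> None:
        self.pixels = np.asarray(self.pixels)
        if self.pixels.ndim != 4:
            raise ValueError(f"pixels must be 4-D (T,C,Y,X), got shape {self.pixels.shape}")
        if self.pixels.shape[1] != len(self.channel_roles):
            raise ValueError("channel axis does not match channel_roles")
        if len(set(self.channel_roles)) != len(self.channel_roles):
            raise ValueError("channel_roles must be unique")
        if self.frame_interval <= 0:
            raise ValueError("frame_interval must be > 0")
        if np.any(self.pixels < 0):
            raise ValueError("pixel counts must be non-negative")

    @property
    def n_frames(self) -> int:
        return self.pixels.shape[0]

    @property
    def shape_yx(self) -> tuple[int, int]:
        return self.pixels.shape[2], self.pixels.shape[3]

    def channel(self, role: str) -> np.ndarray:
        """All frames of one channel, shape (T, Y, X)."""
        return self.pixels[:, self.channel_roles.index(role)]

    def save(self, path: str | Path) -> None:
        """Write as TCYX TIFF with a JSON metadata description."""
        meta = {
            "channel_roles": list(self.channel_roles),
            "frame_interval": self.frame_interval,
            "pixel_size": self.pixel_size,
            "z_planes": self.z_planes,
        }
        tifffile.imwrite(
            str(path),
            self.pixels.astype(np.float32),
            photometric="minisblack",
            metadata={"axes": "TCYX"},
            description=json.dumps(meta),
        )

    @classmethod
    def load(cls, path: str | Path) -> "ImageStack":
        with tifffile.TiffFile(str(path)) as tif:
            pixels = tif.asarray()
            desc = tif.pages[0].description
        meta = {}
        try:
            meta = json.loads(desc)
        except (TypeError, json.JSONDecodeError):
            pass
        if pixels.ndim == 3:  # single frame
            pixels = pixels[None]
        return cls(
            pixels=np.asarray(pixels, dtype=float),
            channel_roles=tuple(meta.get("channel_roles", CHANNEL_ROLES)),
            frame_interval=float(meta.get("frame_interval", 20.0)),
            pixel_size=float(meta.get("pixel_size", 0.16)),
            z_planes=meta.get("z_planes"),
        )

    def with_pixels(self, pixels: np.ndarray, **changes) -> "ImageStack":
        return replace(self, pixels=pixels, **changes)
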