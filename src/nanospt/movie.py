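"""Calibrated single-channel image stacks.

A :class:`Movie` couples a ``(frames, rows, cols)`` intensity array with its
physical calibration: pixel size in micrometres per pixel and the frame
interval in seconds. All downstream coordinates are expressed in micrometres
using the pixel-centre convention: integer pixel ``i`` spans ``[i, i+1)`` in
pixel units, so its centre sits at ``(i + 0.5) * pixel_size`` micrometres.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np
import tifffile


@dataclass
class Movie:
    """A calibrated fluorescence time series.

    Parameters
    ----------
    stack
        Array of shape ``(n_frames, height, width)``; non-negative intensities.
    pixel_size
        Lateral calibration, µm per pixel. Must be positive.
    frame_interval
        Time between consecutive frames, seconds. Must be positive.
    """

    stack: np.ndarray
    pixel_size: float
    frame_interval: float

    def __post_init__(self) -> None:
        self.stack = np.asarray(self.stack)
        if self.stack.ndim != 3 or self.stack.shape[0] < 1:
            raise ValueError("stack must be a (frames, rows, cols) array with >= 1 frame")
        if not (self.pixel_size > 0 and np.isfinite(self.pixel_size)):
            raise ValueError(f"pixel_size must be positive, got {self.pixel_size}")
        if not (self.frame_interval > 0 and np.isfinite(self.frame_interval)):
            raise ValueError(f"frame_interval must be positive, got {self.frame_interval}")
        if np.issubdtype(self.stack.dtype, np.floating) and not np.isfinite(self.stack).all():
            raise ValueError("stack contains non-finite pixels")
        if (self.stack < 0).any():
            raise ValueError("stack contains negative intensities")

    @property
    def n_frames(self) -> int:
        return self.stack.shape[0]

    @property
    def shape_px(self) -> tuple[int, int]:
        """(height, width) in pixels."""
        return self.stack.shape[1], self.stack.shape[2]

    @property
    def fps(self) -> float:
        return 1.0 / self.frame_interval

    def extent_um(self) -> tuple[float, float]:
        """(width, height) of the field of view in µm."""
        h, w = self.shape_px
        return w * self.pixel_size, h * self.pixel_size

    def to_tiff(self, path: str | Path) -> None:
        """Write the stack as a multi-page TIFF with calibration metadata.

        The calibration is stored in the TIFF resolution tags (pixels per µm)
        and in an ImageJ-style metadata block (``finterval`` in seconds), so
        the file round-trips through :meth:`from_tiff` and opens calibrated in
        Fiji/ImageJ.
        """
        data = self.stack
        if np.issubdtype(data.dtype, np.floating):
            data = np.clip(np.rint(data), 0, np.iinfo(np.uint16).max).astype(np.uint16)
        tifffile.imwrite(
            str(path),
            data,
            imagej=True,
            resolution=(1.0 / self.pixel_size, 1.0 / self.pixel_size),
            metadata={"unit": "um", "finterval": self.frame_interval, "axes": "TYX"},
        )

    @classmethod
    def from_tiff(
        cls,
        path: str | Path,
        pixel_size: float | None = None,
        frame_interval: float | None = None,
    ) -> "Movie":
        """Read a multi-page TIFF; calibration from tags unless overridden."""
        with tifffile.TiffFile(str(path)) as tf:
            stack = tf.asarray()
            if stack.ndim == 2:
                stack = stack[None]
            if pixel_size is None:
                try:
                    xres = tf.pages[0].tags["XResolution"].value
                    pixel_size = xres[1] / xres[0]
                except (KeyError, ZeroDivisionError, TypeError):
                    raise ValueError("TIFF lacks resolution tags; pass pixel_size explicitly")
            if frame_interval is None:
                meta = tf.imagej_metadata or {}
                if "finterval" in meta:
                    frame_interval = float(meta["finterval"])
                else:
                    raise ValueError("TIFF lacks frame interval metadata; pass frame_interval")
        return cls(stack=stack, pixel_size=float(pixel_size), frame_interval=float(frame_interval))
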