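"""Per-frame spot detection: Laplacian-of-Gaussian filtering with sub-pixel
refinement by local quadratic fitting.

Bright diffraction-limited particles are found as local maxima of the
scale-normalized, sign-inverted LoG response at the blob-optimal scale
``sigma = diameter / (2 * sqrt(2))`` for a spot of the given diameter. Each
integer maximum is refined by fitting a 2-D quadratic to the 3x3 response
neighbourhood and moving to its stationary point, the deterministic scheme
used by standard tracking software. Coordinates are reported in µm with the
pixel-centre convention (pixel ``i`` spans ``[i, i+1)``).
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from scipy import ndimage
from skimage.filters import threshold_otsu

from .movie import Movie

SPOT_COLUMNS = ["frame", "x_um", "y_um", "quality", "intensity"]


def log_sigma_px(diameter_um: float, pixel_size: float) -> float:
    """Blob-optimal LoG scale (pixels) for a spot of the given diameter."""
    return diameter_um / (2.0 * np.sqrt(2.0)) / pixel_size


def log_response(frame: np.ndarray, diameter_um: float, pixel_size: float) -> np.ndarray:
    """Scale-normalized negated LoG response; bright blobs -> positive maxima."""
    frame = np.asarray(frame, dtype=float)
    if not np.isfinite(frame).all():
        raise ValueError("frame contains non-finite pixels")
    if diameter_um < 2 * pixel_size:
        raise ValueError("diameter must be at least two pixels")
    sigma = log_sigma_px(diameter_um, pixel_size)
    return -(sigma**2) * ndimage.gaussian_laplace(frame, sigma)


def _quadratic_refine(response: np.ndarray, row: int, col: int) -> tuple[float, float]:
    """Sub-pixel offset of the stationary point of a 2-D quadratic fit
    to the 3x3 neighbourhood; falls back to (0, 0) if displaced > 1 px."""
    patch = response[row - 1 : row + 2, col - 1 : col + 2]
    gy = (patch[2, 1] - patch[0, 1]) / 2.0
    gx = (patch[1, 2] - patch[1, 0]) / 2.0
    hyy = patch[2, 1] - 2.0 * patch[1, 1] + patch[0, 1]
    hxx = patch[1, 2] - 2.0 * patch[1, 1] + patch[1, 0]
    hxy = (patch[2, 2] - patch[2, 0] - patch[0, 2] + patch[0, 0]) / 4.0
    det = hxx * hyy - hxy * hxy
    if det == 0:
        return 0.0, 0.0
    dx = -(hyy * gx - hxy * gy) / det
    dy = -(hxx * gy - hxy * gx) / det
    if abs(dx) > 1.0 or abs(dy) > 1.0:
        return 0.0, 0.0
    return dx, dy


def detect_spots(
    movie: Movie,
    diameter_um: float = 0.4,
    quality_threshold: float | None = None,
) -> pd.DataFrame:
    """Detect sub-pixel particle positions in every frame.

    Local maxima of the LoG response above ``quality_threshold`` are kept
    after non-maximum suppression within one spot radius, then refined by the
    3x3 quadratic fit. ``quality_threshold=None`` selects the heuristic auto
    mode (see :func:`auto_quality_threshold`); detection thresholds are
    otherwise an explicit analyst choice, as in interactive tracking tools.

    Returns a table with columns ``frame, x_um, y_um, quality, intensity``
    where ``intensity`` is the raw signal summed over a diameter-sized window.
    """
    if quality_threshold is not None and quality_threshold < 0:
        raise ValueError("quality_threshold must be >= 0")
    if quality_threshold is None:
        quality_threshold = auto_quality_threshold(movie, diameter_um)

    radius_px = max(1, int(round(diameter_um / 2.0 / movie.pixel_size)))
    footprint = np.ones((2 * radius_px + 1, 2 * radius_px + 1), dtype=bool)
    win = radius_px  # half-width of the raw-intensity summation window

    records: list[tuple] = []
    for t in range(movie.n_frames):
        frame = movie.stack[t]
        resp = log_response(frame, diameter_um, movie.pixel_size)
        is_max = (resp == ndimage.maximum_filter(resp, footprint=footprint))
        is_max &= resp > quality_threshold
        is_max[:1, :] = is_max[-1:, :] = False
        is_max[:, :1] = is_max[:, -1:] = False
        rows, cols = np.nonzero(is_max)
        # exact response ties within one radius (possible in noiseless,
        # symmetric images) would otherwise yield duplicate detections;
        # keep the lexicographically first of each tied pair
        kept: list[tuple[int, int]] = []
        for r, c in zip(rows, cols):
            if any(abs(r - rk) <= radius_px and abs(c - ck) <= radius_px
                   and resp[r, c] == resp[rk, ck] for rk, ck in kept):
                continue
            kept.append((r, c))
        for r, c in kept:
            dx, dy = _quadratic_refine(resp, r, c)
            x_um = (c + 0.5 + dx) * movie.pixel_size
            y_um = (r + 0.5 + dy) * movie.pixel_size
            r0, r1 = max(0, r - win), min(frame.shape[0], r + win + 1)
            c0, c1 = max(0, c - win), min(frame.shape[1], c + win + 1)
            intensity = float(frame[r0:r1, c0:c1].sum())
            records.append((t, x_um, y_um, float(resp[r, c]), intensity))

    return pd.DataFrame.from_records(records, columns=SPOT_COLUMNS).astype(
        {"frame": int}
    )


def auto_quality_threshold(movie: Movie, diameter_um: float = 0.4) -> float:
    """Heuristic detection threshold: Otsu split of per-frame LoG maxima.

    Collects every local maximum of the response across all frames and places
    an Otsu threshold between the noise-maxima and spot-maxima populations.
    A convenience for exploration, not a substitute for a tuned threshold.
    """
    radius_px = max(1, int(round(diameter_um / 2.0 / movie.pixel_size)))
    footprint = np.ones((2 * radius_px + 1, 2 * radius_px + 1), dtype=bool)
    maxima: list[np.ndarray] = []
    for t in range(movie.n_frames):
        resp = log_response(movie.stack[t], diameter_um, movie.pixel_size)
        is_max = (resp == ndimage.maximum_filter(resp, footprint=footprint)) & (resp > 0)
        maxima.append(resp[is_max])
    values = np.concatenate(maxima)
    if values.size < 2 or np.ptp(values) == 0:
        return float(values.max() if values.size else 0.0)
    return float(threshold_otsu(values))
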