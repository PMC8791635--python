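"""Mean-square-displacement analysis and diffusion-coefficient estimation.

For a 2-D trajectory sampled at interval ``dt``, the time-averaged MSD at lag
``k`` is the mean over all overlapping pairs of
``(x[i+k]-x[i])**2 + (y[i+k]-y[i])**2``. Free Brownian motion gives
``MSD(t) = 4 D t``, so D is estimated as one quarter of the slope of an
ordinary least-squares line through the first four MSD points, fitted with a
free intercept (the intercept absorbs static localization error instead of
biasing the slope). The anomalous exponent ``alpha`` — the log-log slope of
the same points — separates confined (``alpha < 1``) from free (``alpha ~ 1``)
motion without any model fitting.

An origin-referenced MSD, ``(x[k]-x[0])**2 + (y[k]-y[0])**2`` with a single
pair per lag, is available via ``method="origin"`` for compatibility with
per-particle displacement-from-start summaries; the time-averaged form is the
default because it is the standard, far lower-variance estimator.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd


@dataclass
class MsdCurve:
    """Time-averaged MSD per lag. ``lags`` are in seconds, lag 0 excluded."""

    lags: np.ndarray  # s, strictly increasing
    msd: np.ndarray  # µm²
    n_pairs: np.ndarray  # displacement pairs averaged per lag


@dataclass
class DiffusionEstimate:
    """Diffusion coefficient from the short-lag MSD slope.

    D may be negative for noise-dominated tracks; it is reported as-is with a
    ``"negative_D"`` flag rather than silently clamped, so group medians stay
    unbiased. ``alpha`` is NaN (flag ``"alpha_undefined"``) when any fitted MSD
    value is non-positive.
    """

    D: float  # µm²/s
    intercept: float  # µm²
    alpha: float
    n_lags_used: int
    flags: list[str] = field(default_factory=list)


def compute_msd(
    x: np.ndarray,
    y: np.ndarray,
    frame_interval: float,
    max_lag: int | None = None,
    method: str = "time_averaged",
) -> MsdCurve:
    """MSD curve of one trajectory on consecutive frames.

    ``max_lag`` defaults to ``n_points - 1`` (every available lag).
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    n = x.size
    if n < 2:
        raise ValueError("track needs >= 2 points")
    if max_lag is None:
        max_lag = n - 1
    if not (1 <= max_lag < n):
        raise ValueError(f"max_lag must be in [1, {n - 1}]")
    if method not in ("time_averaged", "origin"):
        raise ValueError(f"unknown MSD method {method!r}")

    msd = np.empty(max_lag)
    n_pairs = np.empty(max_lag, dtype=int)
    for k in range(1, max_lag + 1):
        if method == "time_averaged":
            dx = x[k:] - x[:-k]
            dy = y[k:] - y[:-k]
            msd[k - 1] = np.mean(dx * dx + dy * dy)
            n_pairs[k - 1] = n - k
        else:
            msd[k - 1] = (x[k] - x[0]) ** 2 + (y[k] - y[0]) ** 2
            n_pairs[k - 1] = 1
    lags = frame_interval * np.arange(1, max_lag + 1)
    return MsdCurve(lags=lags, msd=msd, n_pairs=n_pairs)


def fit_diffusion(msd: MsdCurve, n_lags: int = 4) -> DiffusionEstimate:
    """Estimate D as slope/4 of an OLS line through the first ``n_lags`` points."""
    if msd.lags.size < n_lags:
        raise ValueError(f"need >= {n_lags} MSD points, have {msd.lags.size}")
    t = msd.lags[:n_lags]
    y = msd.msd[:n_lags]
    if np.ptp(t) == 0:
        raise ValueError("degenerate lags")
    slope, intercept = np.polyfit(t, y, 1)
    flags: list[str] = []
    if slope < 0:
        flags.append("negative_D")
    if np.all(y > 0):
        alpha = float(np.polyfit(np.log(t), np.log(y), 1)[0])
    else:
        alpha = float("nan")
        flags.append("alpha_undefined")
    return DiffusionEstimate(
        D=float(slope) / 4.0,
        intercept=float(intercept),
        alpha=alpha,
        n_lags_used=n_lags,
        flags=flags,
    )


def analyze_tracks(
    tracks: pd.DataFrame,
    frame_interval: float,
    n_lags: int = 4,
    method: str = "time_averaged",
) -> pd.DataFrame:
    """Per-track diffusion table from a linked-track table.

    Tracks shorter than ``n_lags + 1`` points are skipped (they cannot
    support the fit). Returns columns
    ``track_id, D_um2_s, intercept, alpha, n_points``.

    For a track whose MSD is exactly zero at every lag (a perfectly static
    particle), the estimate is D = 0 with undefined alpha.
    """
    records = []
    for tid, g in tracks.sort_values(["track_id", "frame"]).groupby("track_id"):
        n = len(g)
        if n < n_lags + 1:
            continue
        curve = compute_msd(
            g["x_um"].to_numpy(), g["y_um"].to_numpy(), frame_interval,
            max_lag=min(n - 1, max(n_lags, n // 2)), method=method,
        )
        est = fit_diffusion(curve, n_lags=n_lags)
        records.append((tid, est.D, est.intercept, est.alpha, n))
    return pd.DataFrame.from_records(
        records, columns=["track_id", "D_um2_s", "intercept", "alpha", "n_points"]
    )
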