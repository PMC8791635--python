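"""Ground-truthed synthetic VA-TIRFM-like movies and 1-D intensity profiles.

The generator emulates the three lateral-dynamics regimes that evanescent-field
imaging of plasma-membrane receptors contrasts: particles held in laterally
stable foci (``static``), freely diffusing particles (``brownian``) and
particles diffusing inside a sub-micron domain (``confined``). Trajectories are
simulated in physical units (µm, s) and rendered onto a pixel grid as
integrated 2-D Gaussians with Poisson shot noise, so the detection → linking →
MSD stages can be validated against exact ground truth.

Motion models
-------------
brownian
    Per-axis increments are i.i.d. Gaussian with variance ``2 * D * dt``;
    the 2-D ensemble MSD is ``4 * D * t``.
confined
    The same increments, reflected at the walls of a square domain of side
    ``L`` centred on the start position. The stationary position is uniform on
    the square, so the time-averaged MSD plateaus at ``L**2 / 3`` (two axes,
    each the variance of a difference of independent uniforms, ``L**2 / 6``).
static
    The position never changes (zero-diffusion limit of a stable focus).
"""

from __future__ import annotations

import csv
from dataclasses import dataclass, field
from pathlib import Path
from typing import Literal, Sequence

import numpy as np

from .movie import Movie
from .nanodomain import IntensityProfile

Regime = Literal["brownian", "confined", "static"]

#: Sub-stream key reserved for rendering noise (never collides with particle
#: indices, which key their own sub-streams).
_RENDER_STREAM = 1 << 30


@dataclass
class ParticleSpec:
    """One simulated emitter.

    Parameters
    ----------
    regime
        ``"brownian"``, ``"confined"`` or ``"static"``.
    D_true
        Diffusion coefficient, µm²/s (ignored for ``static``).
    start_position
        Initial ``(x, y)`` in µm.
    domain_side
        Side of the reflecting square, µm; required for ``confined``.
    on_fraction
        Probability the particle emits in any given frame (blinking).
    """

    regime: Regime
    D_true: float
    start_position: tuple[float, float]
    domain_side: float | None = None
    on_fraction: float = 1.0

    def validate(self) -> None:
        if self.regime not in ("brownian", "confined", "static"):
            raise ValueError(f"unknown regime {self.regime!r}")
        if not (np.isfinite(self.D_true) and self.D_true >= 0):
            raise ValueError(f"D_true must be finite and >= 0, got {self.D_true}")
        if not all(np.isfinite(self.start_position)):
            raise ValueError("start_position must be finite")
        if self.regime == "confined":
            if self.domain_side is None or not (self.domain_side > 0):
                raise ValueError("confined regime requires domain_side > 0")
        if not (0 < self.on_fraction <= 1):
            raise ValueError(f"on_fraction must be in (0, 1], got {self.on_fraction}")


@dataclass
class SimulationConfig:
    """Full description of a synthetic acquisition.

    Defaults follow the acquisition used for the fast imaging mode this
    pipeline targets (20 frames per second, i.e. 50 ms per frame) and a
    0.1 µm/px calibration typical of a 160x objective on an EMCCD camera.
    """

    field_of_view: tuple[float, float] = (12.8, 12.8)  # (width, height) µm
    pixel_size: float = 0.1  # µm/px
    frame_interval: float = 0.05  # s (20 fps)
    n_frames: int = 50
    particles: list[ParticleSpec] = field(default_factory=list)
    background_level: float = 100.0  # photons/px/frame
    psf_sigma: float = 0.17  # µm; Gaussian sigma for a 0.4 µm FWHM spot
    photons_per_particle: float = 5000.0  # expected photons/frame
    rng_seed: int = 0

    def validate(self) -> None:
        if not (self.pixel_size > 0 and np.isfinite(self.pixel_size)):
            raise ValueError("pixel_size must be positive")
        if not (self.frame_interval > 0 and np.isfinite(self.frame_interval)):
            raise ValueError("frame_interval must be positive")
        if self.n_frames < 2:
            raise ValueError("n_frames must be >= 2")
        if not (self.psf_sigma > 0 and np.isfinite(self.psf_sigma)):
            raise ValueError("psf_sigma must be positive")
        if not (self.background_level >= 0 and np.isfinite(self.background_level)):
            raise ValueError("background_level must be finite and >= 0")
        if not (self.photons_per_particle >= 0 and np.isfinite(self.photons_per_particle)):
            raise ValueError("photons_per_particle must be finite and >= 0")
        if min(self.field_of_view) <= 0:
            raise ValueError("field_of_view must be positive")
        for p in self.particles:
            p.validate()

    @property
    def shape_px(self) -> tuple[int, int]:
        """(height, width) of the rendered frame in pixels."""
        w_um, h_um = self.field_of_view
        return int(round(h_um / self.pixel_size)), int(round(w_um / self.pixel_size))

    def _stream(self, key: int) -> np.random.Generator:
        # One counter-based stream per run; sub-streams keyed so that adding
        # or removing a particle never perturbs the trajectories of others.
        return np.random.default_rng(np.random.SeedSequence(self.rng_seed, spawn_key=(key,)))


@dataclass
class GroundTruth:
    """True trajectories underlying a rendered movie.

    Attributes
    ----------
    positions
        Array ``(n_particles, n_frames, 2)`` of (x, y) in µm.
    regimes
        Regime label per particle.
    emitting
        Boolean ``(n_particles, n_frames)`` blinking mask.
    """

    positions: np.ndarray
    regimes: list[str]
    emitting: np.ndarray
    config: SimulationConfig

    @property
    def n_particles(self) -> int:
        return self.positions.shape[0]

    def to_csv(self, path: str | Path) -> None:
        """Write the track table (particle_id, frame, x_um, y_um, regime)."""
        with open(path, "w", newline="") as fh:
            writer = csv.writer(fh)
            writer.writerow(["particle_id", "frame", "x_um", "y_um", "regime"])
            for pid in range(self.n_particles):
                for t in range(self.positions.shape[1]):
                    writer.writerow(
                        [pid, t, f"{self.positions[pid, t, 0]:.6f}",
                         f"{self.positions[pid, t, 1]:.6f}", self.regimes[pid]]
                    )


def _reflect(x: np.ndarray, lo: float, hi: float) -> np.ndarray:
    """Fold unbounded coordinates into [lo, hi] by specular reflection."""
    span = hi - lo
    z = np.mod(x - lo, 2.0 * span)
    return lo + np.where(z <= span, z, 2.0 * span - z)


def simulate_tracks(config: SimulationConfig) -> GroundTruth:
    """Simulate all particle trajectories for one acquisition.

    Deterministic given ``config.rng_seed``; each particle consumes an
    independent sub-stream keyed by its index.
    """
    config.validate()
    n_t = config.n_frames
    positions = np.empty((len(config.particles), n_t, 2), dtype=float)
    emitting = np.ones((len(config.particles), n_t), dtype=bool)
    regimes: list[str] = []

    for i, spec in enumerate(config.particles):
        rng = config._stream(i)
        start = np.asarray(spec.start_position, dtype=float)
        if spec.regime == "static" or spec.D_true == 0.0:
            pos = np.tile(start, (n_t, 1))
        else:
            sd = np.sqrt(2.0 * spec.D_true * config.frame_interval)
            steps = rng.normal(0.0, sd, size=(n_t - 1, 2))
            pos = np.vstack([start, start + np.cumsum(steps, axis=0)])
            if spec.regime == "confined":
                half = spec.domain_side / 2.0
                for ax in range(2):
                    pos[:, ax] = _reflect(pos[:, ax], start[ax] - half, start[ax] + half)
        positions[i] = pos
        if spec.on_fraction < 1.0:
            emitting[i] = rng.random(n_t) < spec.on_fraction
        regimes.append(spec.regime)

    return GroundTruth(positions=positions, regimes=regimes, emitting=emitting, config=config)


def _integrated_gaussian_patch(
    x_um: float, y_um: float, sigma_um: float, pixel_size: float,
    shape: tuple[int, int], halfwidth_px: int,
) -> tuple[slice, slice, np.ndarray]:
    """Fraction of a unit photon flux falling in each pixel near (x, y).

    Integrates the 2-D Gaussian over pixel areas (difference of error
    functions per axis), evaluated only on a local window for speed.
    """
    from scipy.special import erf

    h, w = shape
    cx = x_um / pixel_size  # pixel units; pixel i spans [i, i+1)
    cy = y_um / pixel_size
    x0 = max(0, int(np.floor(cx)) - halfwidth_px)
    x1 = min(w, int(np.floor(cx)) + halfwidth_px + 1)
    y0 = max(0, int(np.floor(cy)) - halfwidth_px)
    y1 = min(h, int(np.floor(cy)) + halfwidth_px + 1)
    if x0 >= x1 or y0 >= y1:
        return slice(0, 0), slice(0, 0), np.zeros((0, 0))
    s = sigma_um / pixel_size * np.sqrt(2.0)
    ex = erf((np.arange(x0, x1 + 1) - cx) / s)
    ey = erf((np.arange(y0, y1 + 1) - cy) / s)
    fx = 0.5 * np.diff(ex)
    fy = 0.5 * np.diff(ey)
    return slice(y0, y1), slice(x0, x1), np.outer(fy, fx)


def render_movie(truth: GroundTruth, config: SimulationConfig | None = None,
                 noise: bool = True) -> Movie:
    """Render trajectories into a calibrated image stack.

    Each emitting particle deposits ``photons_per_particle`` photons as an
    integrated Gaussian of width ``psf_sigma``; pixel values are then drawn
    from ``Poisson(background_level + signal)``. With ``noise=False`` the
    expected (noiseless) photon image is returned instead, which is the
    high-photon limit used by localization oracles.
    """
    if config is None:
        config = truth.config
    config.validate()
    sigma_px = config.psf_sigma / config.pixel_size
    if sigma_px < 0.25:
        raise ValueError(f"psf_sigma = {sigma_px:.3f} px is unresolvable (< 0.25 px)")
    if truth.positions.shape[1] != config.n_frames:
        raise ValueError("ground truth and config disagree on n_frames")

    shape = config.shape_px
    halfwidth = max(3, int(np.ceil(5.0 * sigma_px)))
    expected = np.full((config.n_frames, *shape), float(config.background_level))
    for t in range(config.n_frames):
        for pid in range(truth.n_particles):
            if not truth.emitting[pid, t]:
                continue
            x, y = truth.positions[pid, t]
            ys, xs, patch = _integrated_gaussian_patch(
                x, y, config.psf_sigma, config.pixel_size, shape, halfwidth
            )
            expected[t, ys, xs] += config.photons_per_particle * patch

    if noise:
        rng = config._stream(_RENDER_STREAM)
        stack = rng.poisson(expected).astype(np.uint16)
    else:
        stack = expected
    return Movie(stack=stack, pixel_size=config.pixel_size,
                 frame_interval=config.frame_interval)


def make_profile(
    kind: Literal["uniform", "clustered"],
    n_samples: int,
    contrast: float = 10.0,
    noise_sd: float = 0.0,
    seed: int = 0,
    baseline: float = 100.0,
    pixel_size: float = 0.1,
) -> IntensityProfile:
    """Synthetic 1-D intensity profile for clustering-index validation.

    ``uniform`` draws a flat profile (baseline + Gaussian noise); ``clustered``
    additionally raises a 5% minority of samples to ``contrast * baseline``, so
    that the noiseless spatial clustering index of the profile equals
    ``contrast`` exactly. Values are clipped to a small positive floor.
    """
    if n_samples < 20:
        raise ValueError("n_samples must be >= 20")
    if kind not in ("uniform", "clustered"):
        raise ValueError(f"unknown profile kind {kind!r}")
    if kind == "clustered" and contrast < 1:
        raise ValueError("contrast must be >= 1")
    rng = np.random.default_rng(np.random.SeedSequence(seed, spawn_key=(0,)))
    values = np.full(n_samples, float(baseline))
    if kind == "clustered":
        k = max(1, round(0.05 * n_samples))
        peak_idx = rng.choice(n_samples, size=k, replace=False)
        values[peak_idx] = contrast * baseline
    if noise_sd > 0:
        values = values + rng.normal(0.0, noise_sd, size=n_samples)
    values = np.clip(values, 1e-6, None)
    length_um = (n_samples - 1) * pixel_size
    return IntensityProfile(
        samples=values,
        line=((0.0, 0.0), (length_um, 0.0)),
        pixel_size=pixel_size,
    )


# ---------------------------------------------------------------------------
# Scenario presets: one synthetic "cell" per movie.
# ---------------------------------------------------------------------------

#: Mobility of a freely diffusing membrane receptor (µm²/s). Receptor kinases
#: at the plant plasma membrane diffuse in the 0.001-0.1 µm²/s range; the
#: mobile preset sits at the upper end so that motion is unambiguous over a
#: 2-second acquisition.
MOBILE_D = 0.05
#: Side of the confinement domain, matching the estimated particle size (µm).
CONFINED_L = 0.4

SCENARIOS = ("static_clustered", "mobile_dispersed", "confined_dispersed")


def make_scenario(
    name: str,
    seed: int = 0,
    n_particles: int | None = None,
    n_frames: int = 40,
    field_of_view: tuple[float, float] = (12.8, 12.8),
    cluster_size: int = 6,
    **overrides,
) -> SimulationConfig:
    """Build a preset acquisition emulating one imaged cell.

    ``static_clustered``
        Particles grouped ``cluster_size`` at a time into tight immobile foci
        — the stable, strongly organized regime (high clustering index,
        near-zero mobility). Defaults to 360 particles, i.e. 60 foci
        (~0.37 foci/µm² on the default field, the conservative end of
        published plasma-membrane nanodomain densities), so that a random
        8 µm line profile crosses structure more often than not.
    ``mobile_dispersed``
        Particles placed uniformly, diffusing freely at ``MOBILE_D`` — the
        mobile, weakly organized regime. Defaults to 150 particles
        (~0.9 µm⁻²), sparse enough that frame-to-frame linking at a 0.4 µm
        gate stays unambiguous.
    ``confined_dispersed``
        Uniformly placed particles diffusing inside ``CONFINED_L`` squares —
        the intermediate, confined regime (150 particles).
    """
    if name not in SCENARIOS:
        raise ValueError(f"unknown scenario {name!r}; choose from {SCENARIOS}")
    if n_particles is None:
        n_particles = 360 if name == "static_clustered" else 150
    rng = np.random.default_rng(np.random.SeedSequence(seed, spawn_key=(2**20,)))
    w, h = field_of_view
    margin = 1.5  # keep particles (and confinement domains) inside the field
    particles: list[ParticleSpec] = []
    if name == "static_clustered":
        n_clusters = max(1, n_particles // cluster_size)
        centers = rng.uniform([margin, margin], [w - margin, h - margin],
                              size=(n_clusters, 2))
        for i in range(n_particles):
            c = centers[i % n_clusters]
            pos = c + rng.normal(0.0, 0.06, size=2)
            particles.append(ParticleSpec("static", 0.0, (pos[0], pos[1])))
    else:
        starts = rng.uniform([margin, margin], [w - margin, h - margin],
                             size=(n_particles, 2))
        for x, y in starts:
            if name == "mobile_dispersed":
                particles.append(ParticleSpec("brownian", MOBILE_D, (x, y)))
            else:
                particles.append(
                    ParticleSpec("confined", MOBILE_D, (x, y), domain_side=CONFINED_L)
                )
    return SimulationConfig(
        field_of_view=field_of_view,
        n_frames=n_frames,
        particles=particles,
        rng_seed=seed,
        **overrides,
    )


def write_config(config: SimulationConfig, path: str | Path) -> None:
    """Echo the configuration as a plain-text key-value file."""
    lines = [
        f"field_of_view_um = {config.field_of_view[0]} x {config.field_of_view[1]}",
        f"pixel_size_um = {config.pixel_size}",
        f"frame_interval_s = {config.frame_interval}",
        f"n_frames = {config.n_frames}",
        f"n_particles = {len(config.particles)}",
        f"background_level = {config.background_level}",
        f"psf_sigma_um = {config.psf_sigma}",
        f"photons_per_particle = {config.photons_per_particle}",
        f"rng_seed = {config.rng_seed}",
    ]
    Path(path).write_text("\n".join(lines) + "\n")
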