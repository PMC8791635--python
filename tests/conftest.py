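import numpy as np
import pytest

from nanospt.simulate import ParticleSpec, SimulationConfig, render_movie, simulate_tracks


def single_emitter_movie(
    x: float,
    y: float,
    photons: float = 20000.0,
    background: float = 100.0,
    noise: bool = True,
    seed: int = 0,
    n_frames: int = 2,
    fov: tuple[float, float] = (6.4, 6.4),
):
    """A movie containing one static emitter at (x, y) µm."""
    cfg = SimulationConfig(
        field_of_view=fov,
        n_frames=n_frames,
        particles=[ParticleSpec("static", 0.0, (x, y))],
        background_level=background,
        photons_per_particle=photons,
        rng_seed=seed,
    )
    truth = simulate_tracks(cfg)
    return render_movie(truth, cfg, noise=noise), cfg


def grid_positions(n_side: int, spacing: float, offset: float, jitter_rng=None):
    """Well-separated positions on an n_side x n_side grid (µm)."""
    pts = []
    for i in range(n_side):
        for j in range(n_side):
            x = offset + i * spacing
            y = offset + j * spacing
            if jitter_rng is not None:
                x += jitter_rng.uniform(-0.3, 0.3)
                y += jitter_rng.uniform(-0.3, 0.3)
            pts.append((x, y))
    return pts


@pytest.fixture
def rng():
    return np.random.default_rng(12345)
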