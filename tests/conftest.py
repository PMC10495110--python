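"""Shared fixtures: small synthetic recordings with known ground truth."""

import numpy as np
import pytest

from dcvpipe.core import Movie, StimProtocol
from dcvpipe.simulate import (
    EventSpec,
    SimConfig,
    generate_fusion_movie,
    generate_kymo_movie,
    generate_rush_movie,
)


@pytest.fixture(scope="session")
def clean_event_movie():
    """Noise-free recording: 3 puncta, one fusion event, no background.

    Zero background makes per-pixel F/F0 ratios exact multiples of the
    event's peak ratio.
    """
    cfg = SimConfig(
        n_puncta=3,
        punctum_min_separation=15.0,
        background_level=0.0,
        events=(EventSpec(0, 40.0, 3.0, 0.5, 5.0),),
        rng_seed=11,
    )
    movie, truth = generate_fusion_movie(cfg)
    return cfg, movie, truth


@pytest.fixture(scope="session")
def noisy_event_movie():
    """Realistic recording: 5 puncta, stimulus-locked events, camera noise."""
    rng = np.random.default_rng(7)
    events = tuple(
        EventSpec(pid, float(rng.uniform(31, 53)), 2.0, 0.25, 5.0) for pid in range(5)
    )
    cfg = SimConfig(
        n_puncta=5,
        punctum_min_separation=10.0,
        events=events,
        noise_gaussian_sd=3.0,
        noise_poisson_scale=2.0,
        rng_seed=7,
    )
    movie, truth = generate_fusion_movie(cfg)
    return cfg, movie, truth


@pytest.fixture(scope="session")
def pool_movie():
    """Recording with an NH4Cl dequench segment revealing 20 puncta."""
    cfg = SimConfig(
        n_puncta=20,
        punctum_min_separation=8.0,
        image_shape=(96, 96),
        nh4cl_window=(110.0, 120.0),
        dequench_factor=5.0,
        rng_seed=21,
    )
    movie, truth = generate_fusion_movie(cfg)
    return cfg, movie, truth


@pytest.fixture(scope="session")
def rush_clean():
    """Noise-free RUSH movie, k = 0.1/min, peak at 45 min, no background."""
    movie, truth = generate_rush_movie(
        k_true=0.1, t_peak_true=45.0, background_level=0.0, rng_seed=3
    )
    return movie, truth


@pytest.fixture(scope="session")
def kymo_two_particles():
    """Two opposite constant-velocity particles, noise-free."""
    movie, truth = generate_kymo_movie(
        2, [1.0, -1.0], noise_sd=0.0, rng_seed=8
    )
    return movie, truth


@pytest.fixture()
def center_path():
    def make(movie: Movie) -> np.ndarray:
        mid = movie.shape[1] // 2
        return np.array([[mid, 0], [mid, movie.shape[2] - 1]], dtype=float)

    return make
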