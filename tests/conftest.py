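import numpy as np
import pytest

from faceshape.synthetic_data import (
    SyntheticConfig,
    generate_template,
    simulate_faces,
    simulate_ratings,
)
from faceshape.shape_scores import score_table


def small_config(**overrides) -> SyntheticConfig:
    """A fast study configuration: few landmarks, few faces, few raters."""
    defaults = dict(
        n_per_sex=10,
        n_landmarks=12,
        n_semilandmarks=4,
        n_raters_per_group={"CZ": 4, "CZVN": 4, "AVN": 4},
        seed=7,
    )
    defaults.update(overrides)
    return SyntheticConfig(**defaults)


@pytest.fixture(scope="session")
def small_study():
    """One small synthetic study shared across tests: faces, scores, ratings."""
    cfg = small_config()
    configs, covariates, truth = simulate_faces(cfg)
    scores = score_table(configs, covariates)
    ratings = simulate_ratings(scores, cfg)
    return dict(
        config=cfg,
        configs=configs,
        covariates=covariates,
        truth=truth,
        scores=scores,
        ratings=ratings,
    )


@pytest.fixture()
def rng():
    return np.random.default_rng(20240917)


@pytest.fixture(scope="session")
def face_template():
    return generate_template(12, 4)


def random_similarity(coords: np.ndarray, rng: np.random.Generator) -> np.ndarray:
    """Apply a random rotation, positive scaling and translation."""
    theta = rng.uniform(0, 2 * np.pi)
    scale = rng.lognormal(0, 0.3)
    shift = rng.normal(0, 2, size=2)
    c, s = np.cos(theta), np.sin(theta)
    return scale * coords @ np.array([[c, -s], [s, c]]).T + shift


def brute_force_procrustes(a: np.ndarray, b: np.ndarray, step: float = 1e-4) -> float:
    """Independent rotation-grid minimization of the preshape chord distance."""
    from faceshape.gpa import preshape

    pa, pb = preshape(a), preshape(b)
    thetas = np.arange(-np.pi, np.pi, step)
    cos_t, sin_t = np.cos(thetas), np.sin(thetas)
    # rotated pa for all angles at once: (t, k, 2)
    x, y = pa[:, 0], pa[:, 1]
    rx = cos_t[:, None] * x[None, :] - sin_t[:, None] * y[None, :]
    ry = sin_t[:, None] * x[None, :] + cos_t[:, None] * y[None, :]
    ss = ((rx - pb[:, 0][None, :]) ** 2 + (ry - pb[:, 1][None, :]) ** 2).sum(axis=1)
    return float(np.sqrt(ss.min()))
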