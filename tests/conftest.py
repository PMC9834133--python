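import numpy as np
import pytest

from iasmeeg import (
    HyperModel,
    NoiseModel,
    SourceSpace,
    build_anatomical_prior,
    make_random_leadfield,
)


def random_unit_vectors(n, seed):
    rng = np.random.default_rng(seed)
    v = rng.standard_normal((n, 3))
    return v / np.linalg.norm(v, axis=1, keepdims=True)


def make_hyper(theta_star, eta=0.01, snr=10.0, sigma_scaled=1.0):
    """Assemble a HyperModel directly for solver-level tests."""
    theta_star = np.asarray(theta_star, dtype=float)
    return HyperModel(
        theta_star=theta_star,
        eta=float(eta),
        beta=float(eta) + 2.5,
        snr=snr,
        signal_power=1.0,
        cutoff_quantile=1.0,
        cutoff_value=float(theta_star.max()),
        scale_M=1.0,
        scale_b=1.0,
        sigma_scaled=sigma_scaled,
    )


def small_problem(seed, n=4, m=6, eta=0.05, sigma=0.5, delta=0.3):
    """A tiny random inverse problem with all pieces assembled."""
    rng = np.random.default_rng(seed)
    space = SourceSpace(
        positions=rng.standard_normal((n, 3)),
        orientations=random_unit_vectors(n, seed + 1),
    )
    prior = build_anatomical_prior(space, delta=delta)
    M = make_random_leadfield(m, n, seed=seed + 2)
    b = rng.standard_normal(m)
    noise = NoiseModel.isotropic(sigma, m)
    hyper = make_hyper(rng.uniform(0.5, 2.0, n), eta=eta, sigma_scaled=sigma)
    return space, prior, M, b, noise, hyper


@pytest.fixture
def rng():
    return np.random.default_rng(12345)
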