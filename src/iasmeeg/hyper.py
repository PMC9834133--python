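"""Hyperprior scales, sensitivity weighting, noise model and data scaling.

The per-dipole variances theta_j follow a gamma hyperprior with shape
``beta = eta + 5/2`` and scale ``theta*_j``.  The scales are set by an
exchangeability argument: for a user-supplied signal-to-noise ratio
(SNR = signal power / noise power), all dipole configurations of equal
support size should be a priori equally able to explain the data, which
requires theta*_j inversely proportional to the dipole's lead-field
sensitivity:

    theta*_j = P (1 - 1/SNR) / (beta * ||M_j C_j^{1/2}||_F^2),

with P the signal power and M_j the m x 3 local lead field.  This is the
Bayesian form of depth weighting: deep (low-sensitivity) dipoles receive
proportionally larger prior variances.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional

import numpy as np
import scipy.linalg

__all__ = [
    "NoiseModel",
    "HyperModel",
    "estimate_signal_power",
    "sensitivity",
    "compute_theta_star",
    "truncate_theta_star",
    "build_noise_and_scaling",
    "set_parameters",
]


@dataclass
class NoiseModel:
    """Gaussian measurement-noise model with a whitening transform.

    Either a full SPD covariance ``covariance`` or a scalar standard
    deviation ``sigma`` (implying covariance = sigma^2 I).  The whitener W
    satisfies W Sigma W^T = I (equivalently W^T W = Sigma^{-1}).
    """

    m: int
    sigma: Optional[float] = None
    covariance: Optional[np.ndarray] = None
    whitener: Optional[np.ndarray] = None

    @classmethod
    def isotropic(cls, sigma: float, m: int) -> "NoiseModel":
        if sigma <= 0:
            raise ValueError(f"noise std must be positive, got {sigma}")
        return cls(m=m, sigma=float(sigma))

    @classmethod
    def from_covariance(cls, Sigma: np.ndarray) -> "NoiseModel":
        Sigma = np.asarray(Sigma, dtype=float)
        if Sigma.ndim != 2 or Sigma.shape[0] != Sigma.shape[1]:
            raise ValueError("covariance must be square")
        if not np.allclose(Sigma, Sigma.T, atol=1e-10 * max(1.0, np.abs(Sigma).max())):
            raise ValueError("covariance must be symmetric")
        # W = L^{-1} with Sigma = L L^T gives W Sigma W^T = I
        try:
            L = scipy.linalg.cholesky(Sigma, lower=True)
        except scipy.linalg.LinAlgError as exc:
            raise ValueError("covariance must be positive definite") from exc
        W = scipy.linalg.solve_triangular(L, np.eye(Sigma.shape[0]), lower=True)
        return cls(m=Sigma.shape[0], covariance=Sigma, whitener=W)

    @property
    def trace(self) -> float:
        if self.covariance is not None:
            return float(np.trace(self.covariance))
        return self.m * self.sigma**2

    def whiten(self, x: np.ndarray) -> np.ndarray:
        """Apply W to sensor-space vectors/matrices (first axis = channels)."""
        if self.whitener is not None:
            return self.whitener @ x
        return x / self.sigma

    def whiten_T(self, x: np.ndarray) -> np.ndarray:
        """Apply W^T (adjoint of :meth:`whiten`)."""
        if self.whitener is not None:
            return self.whitener.T @ x
        return x / self.sigma


@dataclass
class HyperModel:
    """Gamma-hyperprior scales and the scalings applied to the problem.

    Attributes
    ----------
    theta_star : (n,) array
        Sensitivity-weighted hyperprior scales (after optional truncation).
    eta : float
        Focality parameter, eta = beta - 5/2.  Small values (1e-4) favor
        focal reconstructions, larger values (0.1) distributed ones.
    beta : float
        Gamma shape parameter.
    snr : float
        User-supplied signal-to-noise ratio (> 1).
    signal_power : float
        Mean squared column norm of the (scaled) calibration data.
    cutoff_quantile : float
        Quantile used to clip the largest theta* values; 1.0 = no clipping.
    cutoff_value : float
        The clipping level actually applied (max of theta* when 1.0).
    scale_M : float
        Factor applied to the lead field (1 / max_j ||M_j||_F).
    scale_b : float
        Factor applied to the data (median scaled column norm = sqrt(m)).
    sigma_scaled : float
        Noise standard deviation per channel in scaled units.
    """

    theta_star: np.ndarray
    eta: float
    beta: float
    snr: float
    signal_power: float
    cutoff_quantile: float
    cutoff_value: float
    scale_M: float
    scale_b: float
    sigma_scaled: float


def estimate_signal_power(data_subset: np.ndarray) -> float:
    """Signal power P as the mean squared Euclidean column norm.

    ``data_subset`` is an m x k matrix of k time slices (a quiet or
    representative window of the recording); a 1-D vector is treated as a
    single column.
    """
    b = np.asarray(data_subset, dtype=float)
    if b.ndim == 1:
        b = b[:, None]
    if b.size == 0:
        raise ValueError("data subset is empty")
    return float(np.mean(np.sum(b**2, axis=0)))


def sensitivity(leadfield: np.ndarray, prior) -> np.ndarray:
    """Per-dipole lead-field energies s_j = ||M_j C_j^{1/2}||_F^2.

    Computed via the factor-free identity s_j = trace(M_j C_j M_j^T), so
    the result does not depend on which square root of C_j is used.
    """
    M = np.asarray(leadfield, dtype=float)
    n = prior.n
    if M.shape[1] != 3 * n:
        raise ValueError(
            f"lead field has {M.shape[1]} columns, expected 3n = {3 * n}"
        )
    Mb = M.reshape(M.shape[0], n, 3)
    return np.einsum("mni,nij,mnj->n", Mb, prior.blocks, Mb)


def compute_theta_star(
    leadfield: np.ndarray,
    prior,
    P: float,
    snr: float,
    beta: float,
) -> np.ndarray:
    """Exchangeable (depth-weighted) hyperprior scales theta*_j.

    theta*_j = P (1 - 1/SNR) / (beta * s_j) with s_j the sensitivity of
    dipole j.  The product theta*_j * s_j is constant across dipoles.
    """
    if snr <= 1.0:
        raise ValueError(
            f"SNR must exceed 1 (signal must exceed noise), got {snr}"
        )
    s = sensitivity(leadfield, prior)
    zero = np.flatnonzero(s <= 0.0)
    if zero.size:
        raise ValueError(
            f"dipole {int(zero[0])} has zero lead-field sensitivity; "
            "remove it from the source space"
        )
    return P * (1.0 - 1.0 / snr) / (beta * s)


def truncate_theta_star(
    theta_star: np.ndarray, cutoff_quantile: float
) -> tuple[np.ndarray, float]:
    """Clip the largest theta* values at an empirical quantile.

    The quantile uses linear interpolation between order statistics
    (numpy's default), so the cutoff is bit-reproducible.  Returns the
    clipped vector (same length) and the cutoff value;
    ``cutoff_quantile = 1`` leaves the vector unchanged and returns its
    maximum.
    """
    if not (0.0 < cutoff_quantile <= 1.0):
        raise ValueError(
            f"cutoff quantile must be in (0, 1], got {cutoff_quantile}"
        )
    theta_star = np.asarray(theta_star, dtype=float)
    cutoff = float(np.quantile(theta_star, cutoff_quantile))
    return np.minimum(theta_star, cutoff), cutoff


def build_noise_and_scaling(
    leadfield: np.ndarray,
    data_subset: np.ndarray,
    snr: float,
    Sigma: Optional[np.ndarray] = None,
) -> tuple[NoiseModel, float, float, float]:
    """Derive the problem scalings and the noise model.

    The lead field is scaled so its largest per-dipole block has unit
    Frobenius norm (scale_M = 1 / max_j ||M_j||_F); the data are scaled so
    the median column norm equals sqrt(m).  If no covariance is supplied,
    homoscedastic noise Sigma = sigma^2 I is assumed with
    sigma^2 = P_scaled / (SNR * m), so that trace(Sigma) = P_scaled / SNR
    matches the SNR definition.

    Returns
    -------
    (noise, scale_M, scale_b, P_scaled)
    """
    M = np.asarray(leadfield, dtype=float)
    b = np.asarray(data_subset, dtype=float)
    if b.ndim == 1:
        b = b[:, None]
    m = M.shape[0]
    if b.shape[0] != m:
        raise ValueError(
            f"data has {b.shape[0]} rows but lead field has {m} rows"
        )
    n = M.shape[1] // 3
    block_norms = np.linalg.norm(M.reshape(m, n, 3), axis=(0, 2))
    max_norm = block_norms.max()
    if max_norm == 0.0:
        raise ValueError("lead field is identically zero")
    scale_M = 1.0 / max_norm

    col_norms = np.linalg.norm(b, axis=0)
    med = float(np.median(col_norms))
    if med == 0.0:
        raise ValueError("median data column norm is zero; cannot scale data")
    scale_b = np.sqrt(m) / med

    P_scaled = estimate_signal_power(scale_b * b)
    if Sigma is not None:
        noise = NoiseModel.from_covariance(scale_b**2 * np.asarray(Sigma, dtype=float))
    else:
        sigma2 = P_scaled / (snr * m)
        noise = NoiseModel.isotropic(np.sqrt(sigma2), m)
    return noise, scale_M, scale_b, P_scaled


def set_parameters(
    leadfield: np.ndarray,
    prior,
    data_subset: np.ndarray,
    snr: float,
    eta: float = 0.01,
    cutoff_quantile: float = 1.0,
    Sigma: Optional[np.ndarray] = None,
) -> tuple[HyperModel, NoiseModel]:
    """Prepare all solver parameters from an SNR estimate.

    Scales the problem, builds the noise model, and computes the
    sensitivity-weighted hyperprior scales from the *scaled* lead field and
    data (so theta* lives on the same scale the solver works on).  The
    caller is responsible for applying ``scale_M`` / ``scale_b`` to the
    arrays passed to the solver; :func:`iasmeeg.pipeline.run_pipeline`
    does this automatically.
    """
    if eta <= 0:
        raise ValueError(f"focality parameter eta must be positive, got {eta}")
    noise, scale_M, scale_b, P_scaled = build_noise_and_scaling(
        leadfield, data_subset, snr, Sigma
    )
    beta = eta + 2.5
    theta_star = compute_theta_star(scale_M * leadfield, prior, P_scaled, snr, beta)
    theta_star, cutoff = truncate_theta_star(theta_star, cutoff_quantile)
    sigma_scaled = float(np.sqrt(noise.trace / noise.m))
    hyper = HyperModel(
        theta_star=theta_star,
        eta=float(eta),
        beta=float(beta),
        snr=float(snr),
        signal_power=P_scaled,
        cutoff_quantile=float(cutoff_quantile),
        cutoff_value=cutoff,
        scale_M=scale_M,
        scale_b=scale_b,
        sigma_scaled=sigma_scaled,
    )
    return hyper, noise
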