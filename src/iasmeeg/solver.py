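"""The iterative alternating-sequential (IAS) MAP solver.

The joint MAP estimate of the dipole moments Q and their variances Theta
minimizes the Gibbs energy

    E(Q, Theta) = 1/2 ||b - M Q||^2_Sigma
                + 1/2 sum_j ||q_j||^2_{C_j} / theta_j
                - eta * sum_j log theta_j
                + sum_j theta_j / theta*_j,

with ||v||^2_A = v^T A^{-1} v and eta = beta - 5/2.  The energy is
globally convex, so alternating exact minimization over Q (a quadratic
least-squares problem) and Theta (a closed form) converges to the unique
minimizer.

The Q-update is carried out in priorconditioned coordinates: with
C_theta = diag(theta_j C_j) = D_theta^T D_theta and the noise whitener W,
substituting Q = D_theta^T w turns the quadratic problem into an ordinary
least-squares problem  min_w ||y - A w||  with A = W M D_theta^T and
y = W b.  At run time the problem is solved by CGLS started from w = 0
and terminated early by the discrepancy principle; the Krylov iteration
explores prior-plausible directions first and the early stop supplies the
regularization, so only a few tens of lead-field products are needed.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Optional

import numpy as np

logger = logging.getLogger(__name__)

__all__ = [
    "DipoleField",
    "VarianceField",
    "IASConfig",
    "IASResult",
    "energy",
    "update_theta",
    "cgls",
    "solve_Q",
    "ias_solve",
    "ias_time_series",
]


@dataclass
class DipoleField:
    """Current dipole moments at one time slice."""

    moments: np.ndarray  # (n, 3)

    def __post_init__(self) -> None:
        self.moments = np.asarray(self.moments, dtype=float)
        if self.moments.ndim != 2 or self.moments.shape[1] != 3:
            raise ValueError(f"moments must be (n, 3), got {self.moments.shape}")

    @property
    def intensities(self) -> np.ndarray:
        """Per-dipole intensities a_j = ||q_j||."""
        return np.linalg.norm(self.moments, axis=1)


@dataclass
class VarianceField:
    """Per-dipole prior variances Theta at one time slice."""

    theta: np.ndarray  # (n,), positive

    def __post_init__(self) -> None:
        self.theta = np.asarray(self.theta, dtype=float)
        if np.any(self.theta <= 0) or not np.all(np.isfinite(self.theta)):
            raise ValueError("variances must be positive and finite")


@dataclass
class IASConfig:
    """Solver configuration.

    tau : outer-loop tolerance on the relative Euclidean change of Theta.
    n_outer : maximum outer (alternating) iterations.
    max_it : maximum inner CGLS iterations.
    inner_stop : "discrepancy" stops the inner iteration when the whitened
        residual reaches the noise level; "max-only" runs CGLS to max_it
        (or stagnation).
    explicit_penalty : include the prior penalty 1/2||w||^2 in the inner
        solve (damped CGLS).  The run-time default is False — early
        stopping plays the regularizing role — but exact energy
        minimization (e.g. for convergence checks) requires True together
        with inner_stop="max-only".
    """

    tau: float = 0.01
    n_outer: int = 30
    max_it: int = 120
    inner_stop: str = "discrepancy"
    explicit_penalty: bool = False

    def __post_init__(self) -> None:
        if self.tau <= 0:
            raise ValueError("tau must be positive")
        if self.n_outer < 1 or self.max_it < 1:
            raise ValueError("iteration limits must be at least 1")
        if self.inner_stop not in ("discrepancy", "max-only"):
            raise ValueError(
                f"inner_stop must be 'discrepancy' or 'max-only', got {self.inner_stop!r}"
            )


@dataclass
class IASResult:
    """Reconstruction over a data set of t time slices."""

    Q_hat: np.ndarray  # (t, n, 3)
    theta_hat: np.ndarray  # (t, n)
    diagnostics: list  # per slice: list of (inner_iterations, rel_theta_change)
    converged: np.ndarray  # (t,) bool
    errors: dict = field(default_factory=dict)  # slice index -> message

    @property
    def intensities(self) -> np.ndarray:
        """(t, n) dipole intensities a_j(t) = ||q_j(t)||."""
        return np.linalg.norm(self.Q_hat, axis=2)


def energy(
    Q: DipoleField,
    Theta: VarianceField,
    b: np.ndarray,
    leadfield: np.ndarray,
    prior,
    hyper,
    noise,
) -> float:
    """Gibbs energy of a (Q, Theta) pair for one data slice."""
    theta = Theta.theta
    if np.any(theta <= 0):
        raise ValueError("variances must be positive")
    q = Q.moments
    r = b - leadfield @ q.reshape(-1)
    misfit = 0.5 * float(np.sum(noise.whiten(r) ** 2))
    w2 = prior.mahalanobis_sq(q)
    prior_term = 0.5 * float(np.sum(w2 / theta))
    hyper_term = float(
        -hyper.eta * np.sum(np.log(theta)) + np.sum(theta / hyper.theta_star)
    )
    return misfit + prior_term + hyper_term


def update_theta(Q: DipoleField, prior, hyper) -> VarianceField:
    """Closed-form variance update.

    Minimizes the Theta-part of the Gibbs energy for fixed Q:

        theta_j = theta*_j * ( eta/2 + sqrt(eta^2/4 + ||q_j||^2_{C_j} / (2 theta*_j)) ).

    The floor theta_j >= eta * theta*_j is attained exactly when q_j = 0.
    """
    w2 = prior.mahalanobis_sq(Q.moments)
    ts = hyper.theta_star
    eta = hyper.eta
    theta = ts * (eta / 2.0 + np.sqrt(eta**2 / 4.0 + w2 / (2.0 * ts)))
    return VarianceField(theta=theta)


def cgls(
    A: np.ndarray,
    y: np.ndarray,
    max_it: int,
    discrepancy: Optional[float] = None,
    damp: float = 0.0,
    stag_tol: float = 1e-12,
) -> tuple[np.ndarray, int, np.ndarray]:
    """Conjugate-gradient least squares, optionally damped.

    Minimizes ||y - A w||^2 + damp^2 ||w||^2 starting from w = 0 without
    forming normal equations.  Stops at the first iteration where
    ``||y - A w||^2 <= discrepancy`` (if given), on stagnation (relative
    residual decrease below ``stag_tol``), or after ``max_it`` iterations.

    Returns ``(w, iterations, residual_norms)`` where ``residual_norms``
    holds ||y - A w_k|| for k = 0..iterations (non-increasing).
    """
    w = np.zeros(A.shape[1])
    r = y.astype(float).copy()
    s = A.T @ r
    p = s.copy()
    gamma = float(s @ s)
    res = [float(np.linalg.norm(r))]
    it = 0
    if discrepancy is not None and res[0] ** 2 <= discrepancy:
        return w, 0, np.asarray(res)
    for it in range(1, max_it + 1):
        if gamma == 0.0:
            it -= 1
            break
        q = A @ p
        denom = float(q @ q) + damp**2 * float(p @ p)
        if denom == 0.0:
            it -= 1
            break
        alpha = gamma / denom
        w += alpha * p
        r -= alpha * q
        res.append(float(np.linalg.norm(r)))
        if discrepancy is not None and res[-1] ** 2 <= discrepancy:
            break
        if res[-2] > 0 and (res[-2] - res[-1]) / res[-2] < stag_tol:
            break
        s = A.T @ r - damp**2 * w
        gamma_new = float(s @ s)
        p = s + (gamma_new / gamma) * p
        gamma = gamma_new
    return w, it, np.asarray(res)


def _priorconditioned_matrix(leadfield, prior, theta, noise) -> np.ndarray:
    """Dense A = W M D_theta^T with D_theta block j = sqrt(theta_j) D_j."""
    m = leadfield.shape[0]
    n = prior.n
    Mb = leadfield.reshape(m, n, 3)
    # (W M D_theta^T) columns: for block j, M_j @ (sqrt(theta_j) D_j^T)
    MD = np.einsum("mnj,nij->mni", Mb, np.sqrt(theta)[:, None, None] * prior.factor)
    A = MD.reshape(m, 3 * n)
    return noise.whiten(A)


def solve_Q(
    b: np.ndarray,
    leadfield: np.ndarray,
    prior,
    Theta: VarianceField,
    noise,
    cfg: IASConfig,
) -> tuple[DipoleField, int]:
    """Dipole-moment update: priorconditioned CGLS for one data slice.

    Solves min_w ||y - A w|| (plus 1/2||w||^2 when ``cfg.explicit_penalty``)
    with A = W M D_theta^T, y = W b, from w = 0, and maps back
    Q = D_theta^T w.  With ``inner_stop="discrepancy"`` the iteration
    stops once the whitened residual reaches the noise level
    ||y - A w||^2 <= m (the expected energy of whitened noise).
    """
    if not np.all(np.isfinite(leadfield)):
        raise ValueError("lead field contains non-finite entries")
    theta = Theta.theta
    n = prior.n
    if leadfield.shape[1] != 3 * n or theta.shape[0] != n:
        raise ValueError("inconsistent dimensions between lead field, prior and Theta")
    if b.shape[0] != leadfield.shape[0]:
        raise ValueError(
            f"data slice has {b.shape[0]} channels, lead field has {leadfield.shape[0]}"
        )
    A = _priorconditioned_matrix(leadfield, prior, theta, noise)
    y = noise.whiten(np.asarray(b, dtype=float))
    disc = float(leadfield.shape[0]) if cfg.inner_stop == "discrepancy" else None
    damp = 1.0 if cfg.explicit_penalty else 0.0
    w, iters, _ = cgls(A, y, cfg.max_it, discrepancy=disc, damp=damp)
    wq = w.reshape(n, 3)
    Qm = np.einsum("nji,nj->ni", np.sqrt(theta)[:, None, None] * prior.factor, wq)
    return DipoleField(moments=Qm), iters


def ias_solve(
    b: np.ndarray,
    leadfield: np.ndarray,
    prior,
    hyper,
    noise,
    cfg: Optional[IASConfig] = None,
    theta_init: Optional[np.ndarray] = None,
) -> tuple[DipoleField, VarianceField, list, bool]:
    """IAS alternating minimization for a single time slice.

    Alternates the CGLS dipole update and the closed-form variance update
    until the relative Euclidean change of Theta drops below ``cfg.tau``
    or ``cfg.n_outer`` iterations are exhausted.  Theta is initialized at
    ``theta_init`` if supplied, otherwise at Theta*.

    Returns (Q, Theta, diagnostics, converged); diagnostics rows are
    (inner_iteration_count, relative_theta_change).
    """
    cfg = cfg or IASConfig()
    theta = np.array(
        hyper.theta_star if theta_init is None else theta_init, dtype=float
    )
    if theta.shape != hyper.theta_star.shape:
        raise ValueError("theta_init has wrong length")
    diagnostics = []
    converged = False
    Q = DipoleField(moments=np.zeros((prior.n, 3)))
    for k in range(cfg.n_outer):
        Q, inner = solve_Q(b, leadfield, prior, VarianceField(theta), noise, cfg)
        theta_new = update_theta(Q, prior, hyper).theta
        rel = float(np.linalg.norm(theta_new - theta) / np.linalg.norm(theta))
        diagnostics.append((inner, rel))
        theta = theta_new
        if rel < cfg.tau:
            converged = True
            break
    return Q, VarianceField(theta), diagnostics, converged


def ias_time_series(
    B: np.ndarray,
    leadfield: np.ndarray,
    prior,
    hyper,
    noise,
    cfg: Optional[IASConfig] = None,
    warm_start: bool = True,
) -> IASResult:
    """Apply IAS to each column of an m x t data matrix.

    With ``warm_start`` the variance vector of slice s > 1 is initialized
    at the estimate from slice s-1 (activity, hence its variance, changes
    little between adjacent samples), which typically cuts the number of
    outer iterations to a few; otherwise every slice starts from Theta*.
    Slices with non-finite data are recorded in ``result.errors`` (NaN
    output) and processing continues.
    """
    cfg = cfg or IASConfig()
    B = np.asarray(B, dtype=float)
    if B.ndim == 1:
        B = B[:, None]
    m, t = B.shape
    n = prior.n
    Q_hat = np.zeros((t, n, 3))
    theta_hat = np.zeros((t, n))
    diagnostics: list = []
    converged = np.zeros(t, dtype=bool)
    errors: dict = {}
    theta_prev: Optional[np.ndarray] = None
    for s in range(t):
        if not np.all(np.isfinite(B[:, s])):
            errors[s] = "non-finite data column"
            Q_hat[s] = np.nan
            theta_hat[s] = np.nan
            diagnostics.append([])
            theta_prev = None
            continue
        init = theta_prev if (warm_start and theta_prev is not None) else None
        Q, Th, diag, ok = ias_solve(
            B[:, s], leadfield, prior, hyper, noise, cfg, theta_init=init
        )
        Q_hat[s] = Q.moments
        theta_hat[s] = Th.theta
        diagnostics.append(diag)
        converged[s] = ok
        theta_prev = Th.theta
        logger.info(
            "slice %d: %d outer iterations, converged=%s", s, len(diag), ok
        )
    return IASResult(
        Q_hat=Q_hat,
        theta_hat=theta_hat,
        diagnostics=diagnostics,
        converged=converged,
        errors=errors,
    )
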