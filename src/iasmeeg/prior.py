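"""Anatomical prior construction for distributed dipole source models.

Each source point carries a preferred current direction (the cortical
normal).  The anatomical prior encodes this preference as a per-dipole
3x3 covariance block

    C_j = nu_j nu_j^T + delta * (xi_j xi_j^T + zeta_j zeta_j^T),

where (xi_j, zeta_j, nu_j) is a local orthonormal frame and ``delta`` in
(0, 1] is the relative variance allowed transversally to the preferred
direction.  Since xi xi^T + zeta zeta^T = I - nu nu^T for any orthonormal
completion, C_j = delta*I + (1-delta) nu nu^T regardless of how the
tangent frame is chosen; the frame is still constructed deterministically
so that factorizations are reproducible across runs.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "SourceSpace",
    "LocalFrame",
    "AnatomicalPrior",
    "build_local_frame",
    "build_anatomical_prior",
]


class InvalidOrientationError(ValueError):
    """Raised for zero-length or non-finite dipole orientations."""


@dataclass
class SourceSpace:
    """Discretized set of candidate dipole locations with orientations.

    Parameters
    ----------
    positions : (n, 3) float array
        Dipole coordinates in meters; right-handed axes with x = right,
        y = front, z = crown.
    orientations : (n, 3) float array
        Preferred current directions; renormalized to unit length on
        construction.  Zero or non-finite rows are rejected.
    """

    positions: np.ndarray
    orientations: np.ndarray

    def __post_init__(self) -> None:
        self.positions = np.atleast_2d(np.asarray(self.positions, dtype=float))
        self.orientations = np.atleast_2d(np.asarray(self.orientations, dtype=float))
        if self.positions.ndim != 2 or self.positions.shape[1] != 3:
            raise ValueError(
                f"positions must be (n, 3), got {self.positions.shape}"
            )
        if self.orientations.shape != self.positions.shape:
            raise ValueError(
                "orientations shape "
                f"{self.orientations.shape} != positions shape {self.positions.shape}"
            )
        if self.positions.shape[0] < 1:
            raise ValueError("source space must contain at least one dipole")
        if not np.all(np.isfinite(self.positions)):
            raise ValueError("positions contain non-finite values")
        if not np.all(np.isfinite(self.orientations)):
            raise InvalidOrientationError("orientations contain non-finite values")
        norms = np.linalg.norm(self.orientations, axis=1)
        if np.any(norms == 0.0):
            bad = int(np.flatnonzero(norms == 0.0)[0])
            raise InvalidOrientationError(
                f"orientation {bad} has zero norm; supply a valid unit vector"
            )
        self.orientations = self.orientations / norms[:, None]

    @property
    def n(self) -> int:
        """Number of dipoles."""
        return self.positions.shape[0]


@dataclass(frozen=True)
class LocalFrame:
    """Right-handed orthonormal frame (xi, zeta, nu) at a source point."""

    xi: np.ndarray
    zeta: np.ndarray
    nu: np.ndarray


def build_local_frame(nu: np.ndarray) -> LocalFrame:
    """Deterministically complete a unit vector ``nu`` to a right-handed frame.

    The coordinate axis least parallel to ``nu`` is orthogonalized against
    it to give ``xi``; ``zeta = nu x xi`` closes the frame so that
    ``xi x zeta = nu``.  The same ``nu`` always yields the same frame.
    """
    nu = np.asarray(nu, dtype=float).reshape(3)
    if not np.all(np.isfinite(nu)):
        raise InvalidOrientationError("orientation is non-finite")
    norm = np.linalg.norm(nu)
    if norm == 0.0:
        raise InvalidOrientationError("orientation has zero norm")
    if abs(norm - 1.0) > 1e-6:
        raise InvalidOrientationError(
            f"orientation must be unit length, got norm {norm:.6g}"
        )
    nu = nu / norm
    axis = int(np.argmin(np.abs(nu)))
    e = np.zeros(3)
    e[axis] = 1.0
    xi = e - nu[axis] * nu
    xi /= np.linalg.norm(xi)
    zeta = np.cross(nu, xi)
    return LocalFrame(xi=xi, zeta=zeta, nu=nu)


@dataclass
class AnatomicalPrior:
    """Block-diagonal anatomical prior covariance C = diag(C_1, ..., C_n).

    Attributes
    ----------
    blocks : (n, 3, 3) array
        The per-dipole covariance blocks C_j, each SPD with eigenvalues
        {1, delta, delta}.
    factor : (n, 3, 3) array
        Per-block upper-triangular Cholesky factors D_j with
        D_j^T D_j = C_j.
    delta : float
        Transversal relative variance, in (0, 1].
    """

    blocks: np.ndarray
    factor: np.ndarray
    delta: float
    _inv_blocks: np.ndarray = field(init=False, repr=False)

    def __post_init__(self) -> None:
        self._inv_blocks = np.linalg.inv(self.blocks)

    @property
    def n(self) -> int:
        return self.blocks.shape[0]

    def sqrt_blocks(self) -> np.ndarray:
        """Symmetric square roots C_j^{1/2} (closed form from the spectrum)."""
        # C = delta*I + (1-delta) nu nu^T  =>  C^{1/2} = sqrt(delta)*I + (1-sqrt(delta)) nu nu^T
        # recover nu nu^T from the block itself so the routine also works for delta=1
        s = np.sqrt(self.delta)
        eye = np.eye(3)
        if self.delta == 1.0:
            return np.broadcast_to(eye, self.blocks.shape).copy()
        nnT = (self.blocks - self.delta * eye) / (1.0 - self.delta)
        return s * eye + (1.0 - s) * nnT

    def mahalanobis_sq(self, moments: np.ndarray) -> np.ndarray:
        """Per-dipole quadratic forms q_j^T C_j^{-1} q_j for an (n, 3) array."""
        q = np.asarray(moments, dtype=float)
        return np.einsum("ni,nij,nj->n", q, self._inv_blocks, q)

    def apply_factor_T(self, w: np.ndarray) -> np.ndarray:
        """Blockwise D^T w for w of shape (n, 3)."""
        return np.einsum("nji,nj->ni", self.factor, w)

    def apply_factor(self, v: np.ndarray) -> np.ndarray:
        """Blockwise D v for v of shape (n, 3)."""
        return np.einsum("nij,nj->ni", self.factor, v)


def build_anatomical_prior(space: SourceSpace, delta: float = 0.05) -> AnatomicalPrior:
    """Build the anatomical prior covariance blocks and their Cholesky factor.

    Parameters
    ----------
    space : SourceSpace
        Source points with unit preferred orientations.
    delta : float, default 0.05
        Transversal relative variance.  ``delta = 1`` gives the isotropic
        prior C_j = I (no orientation preference).

    Returns
    -------
    AnatomicalPrior
        Blocks with eigenvalues {1, delta, delta}, eigenvector nu_j for
        eigenvalue 1, and per-block upper-triangular factors.
    """
    if not (0.0 < delta <= 1.0):
        raise ValueError(f"delta must be in (0, 1], got {delta}")
    nu = space.orientations
    nnT = np.einsum("ni,nj->nij", nu, nu)
    blocks = delta * np.eye(3) + (1.0 - delta) * nnT
    # stacked lower Cholesky L with C = L L^T; store D = L^T (upper, C = D^T D)
    lower = np.linalg.cholesky(blocks)
    factor = np.transpose(lower, (0, 2, 1))
    return AnatomicalPrior(blocks=blocks, factor=factor, delta=float(delta))
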