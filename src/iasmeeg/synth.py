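"""Synthetic source spaces, spherical-MEG lead fields and noisy data.

A quasi-spherical source space (Fibonacci lattice) stands in for a
cortical mesh, a concentric shell of magnetometers for an MEG array, and
the closed-form spherically symmetric conductor model (the classical
analytic solution for the magnetic field of a current dipole in a
conducting sphere) supplies the forward operator without any numerical
head modeling.  In this geometry dipoles oriented along the radius
produce no external magnetic field, so tangentially oriented sources are
used for recovery experiments.

All randomness flows through a single integer seed, so a scenario is
fully reproducible.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional

import numpy as np

from .prior import SourceSpace

MU0_OVER_4PI = 1e-7  # T·m/A

__all__ = [
    "SyntheticScenario",
    "fibonacci_sphere",
    "make_sphere_source_space",
    "make_sensor_array",
    "make_meg_leadfield",
    "make_random_leadfield",
    "simulate_patch",
    "add_noise",
    "add_brain_noise",
    "make_scenario",
    "smooth_timecourse",
]


def fibonacci_sphere(n: int) -> np.ndarray:
    """n quasi-uniform unit vectors on the sphere (golden-angle lattice)."""
    if n < 1:
        raise ValueError("need at least one point")
    i = np.arange(n, dtype=float)
    z = 1.0 - (2.0 * i + 1.0) / n
    phi = i * np.pi * (3.0 - np.sqrt(5.0))
    rho = np.sqrt(np.maximum(0.0, 1.0 - z**2))
    return np.column_stack([rho * np.cos(phi), rho * np.sin(phi), z])


def _random_rotation(rng: np.random.Generator) -> np.ndarray:
    """Haar-ish random rotation via QR of a Gaussian matrix."""
    q, r = np.linalg.qr(rng.standard_normal((3, 3)))
    q *= np.sign(np.diag(r))
    if np.linalg.det(q) < 0:
        q[:, 0] *= -1.0
    return q


def _tangent_east(points: np.ndarray) -> np.ndarray:
    """Unit tangent vectors z_hat x r_hat, with a fallback near the poles."""
    r_hat = points / np.linalg.norm(points, axis=1, keepdims=True)
    z = np.array([0.0, 0.0, 1.0])
    t = np.cross(z, r_hat)
    norms = np.linalg.norm(t, axis=1)
    polar = norms < 1e-8
    if np.any(polar):
        t[polar] = np.cross(np.array([1.0, 0.0, 0.0]), r_hat[polar])
        norms = np.linalg.norm(t, axis=1)
    return t / norms[:, None]


def make_sphere_source_space(
    n: int,
    radius: float = 0.07,
    seed: int = 0,
    orientation: str = "radial",
) -> SourceSpace:
    """Quasi-uniform spherical source space.

    Points lie on a Fibonacci lattice of the given radius (meters),
    rotated by a seed-dependent random rotation so different seeds give
    different geometries.  ``orientation="radial"`` mimics outward
    cortical normals; ``"tangential"`` gives unit tangents (useful for
    MEG, where radial dipoles are silent).
    """
    if radius <= 0:
        raise ValueError("radius must be positive")
    rng = np.random.default_rng(seed)
    pts = fibonacci_sphere(n) @ _random_rotation(rng).T
    positions = radius * pts
    if orientation == "radial":
        ori = pts.copy()
    elif orientation == "tangential":
        ori = _tangent_east(positions)
    else:
        raise ValueError(f"unknown orientation {orientation!r}")
    return SourceSpace(positions=positions, orientations=ori)


def make_sensor_array(
    m: int, radius: float = 0.1, seed: int = 0
) -> tuple[np.ndarray, np.ndarray]:
    """m radial magnetometers on a sphere of the given radius.

    Returns (positions, orientations); orientations point outward, the
    usual pickup direction of an MEG helmet magnetometer.
    """
    rng = np.random.default_rng(seed)
    pts = fibonacci_sphere(m) @ _random_rotation(rng).T
    return radius * pts, pts.copy()


def dipole_field_sphere(
    r0: np.ndarray, q: np.ndarray, sensors: np.ndarray
) -> np.ndarray:
    """Magnetic field of a current dipole in a conducting sphere.

    Closed-form solution for a spherically symmetric conductor centered
    at the origin: the field outside the sphere depends only on the
    dipole position r0 and moment q, not on the conductivity profile.
    ``sensors`` is (m, 3); returns the (m, 3) field in tesla for q in A·m.
    """
    r0 = np.asarray(r0, dtype=float).reshape(3)
    q = np.asarray(q, dtype=float).reshape(3)
    r = np.asarray(sensors, dtype=float)
    a_vec = r - r0
    a = np.linalg.norm(a_vec, axis=1)
    R = np.linalg.norm(r, axis=1)
    ar = np.einsum("mi,mi->m", a_vec, r)
    F = a * (R * a + R**2 - r @ r0)
    gradF = (
        (a**2 / R + ar / a + 2.0 * a + 2.0 * R)[:, None] * r
        - (a + 2.0 * R + ar / a)[:, None] * r0
    )
    qxr0 = np.cross(q, r0)
    return MU0_OVER_4PI / F[:, None] ** 2 * (
        F[:, None] * qxr0 - (r @ qxr0)[:, None] * gradF
    )


def make_meg_leadfield(
    space: SourceSpace,
    sensor_pos: np.ndarray,
    sensor_ori: np.ndarray,
) -> np.ndarray:
    """Lead field of the spherical-conductor magnetometer model.

    Entry (i, 3j+k) is the field at sensor i, projected on its pickup
    orientation, produced by a unit dipole along axis k at source j.
    Columns corresponding to the radial component of any dipole vanish
    (radial dipoles are magnetically silent in a sphere).
    """
    sensor_pos = np.atleast_2d(np.asarray(sensor_pos, dtype=float))
    sensor_ori = np.atleast_2d(np.asarray(sensor_ori, dtype=float))
    m = sensor_pos.shape[0]
    src_r = np.linalg.norm(space.positions, axis=1)
    sens_r = np.linalg.norm(sensor_pos, axis=1)
    if sens_r.min() <= src_r.max():
        raise ValueError(
            f"sensors must lie strictly outside the source sphere "
            f"(min sensor radius {sens_r.min():.4g} m <= max source radius "
            f"{src_r.max():.4g} m)"
        )
    n = space.n
    M = np.empty((m, 3 * n))
    eye = np.eye(3)
    for j in range(n):
        for k in range(3):
            B = dipole_field_sphere(space.positions[j], eye[k], sensor_pos)
            M[:, 3 * j + k] = np.einsum("mi,mi->m", B, sensor_ori)
    return M


def make_random_leadfield(m: int, n: int, seed: int = 0) -> np.ndarray:
    """i.i.d. standard-normal m x 3n lead field (unit-test fixture)."""
    rng = np.random.default_rng(seed)
    return rng.standard_normal((m, 3 * n))


def simulate_patch(
    space: SourceSpace,
    center: np.ndarray,
    radius: float,
    amplitude: float,
    timecourse: np.ndarray,
) -> tuple[np.ndarray, np.ndarray]:
    """Activate the dipoles within ``radius`` of ``center``.

    Each dipole j with ||r_j - center|| <= radius carries
    q_j(s) = amplitude * timecourse[s] * nu_j; all others are zero.

    Returns (Q_true, support): Q_true has shape (t, n, 3) and ``support``
    the indices of the active dipoles.
    """
    if radius <= 0:
        raise ValueError("patch radius must be positive")
    center = np.asarray(center, dtype=float).reshape(3)
    tc = np.atleast_1d(np.asarray(timecourse, dtype=float))
    d = np.linalg.norm(space.positions - center, axis=1)
    support = np.flatnonzero(d <= radius)
    if support.size == 0:
        raise ValueError(
            f"no dipole within {radius:.4g} m of the patch center; "
            f"nearest dipole is {d.min():.4g} m away"
        )
    Q = np.zeros((tc.size, space.n, 3))
    Q[:, support, :] = (
        amplitude
        * tc[:, None, None]
        * space.orientations[support][None, :, :]
    )
    return Q, support


def add_noise(
    clean: np.ndarray,
    snr_target: float,
    seed: int = 0,
    Sigma: Optional[np.ndarray] = None,
) -> np.ndarray:
    """Add Gaussian noise calibrated so signal power / noise power = SNR.

    With P the mean squared column norm of ``clean``, the noise covariance
    satisfies trace(Sigma) = P / snr_target (homoscedastic sigma^2 I by
    default; a supplied Sigma is rescaled to that trace).  An infinite SNR
    returns the clean data unchanged.
    """
    clean = np.asarray(clean, dtype=float)
    B = clean if clean.ndim == 2 else clean[:, None]
    if snr_target <= 0:
        raise ValueError("target SNR must be positive")
    if np.isinf(snr_target):
        return clean.copy()
    P = float(np.mean(np.sum(B**2, axis=0)))
    if P == 0.0:
        raise ValueError("clean data is all zero; SNR is undefined")
    m = B.shape[0]
    rng = np.random.default_rng(seed)
    if Sigma is None:
        sigma = np.sqrt(P / (snr_target * m))
        noise = sigma * rng.standard_normal(B.shape)
    else:
        Sigma = np.asarray(Sigma, dtype=float) * (
            P / snr_target / float(np.trace(Sigma))
        )
        L = np.linalg.cholesky(Sigma)
        noise = L @ rng.standard_normal(B.shape)
    out = B + noise
    return out if clean.ndim == 2 else out[:, 0]


def add_brain_noise(
    clean: np.ndarray,
    leadfield: np.ndarray,
    brain_snr: float,
    seed: int = 0,
) -> np.ndarray:
    """Add background neural activity: random dipoles everywhere.

    Gaussian dipole moments are projected through the lead field and
    scaled so that signal power / background power equals ``brain_snr``.
    A crude stand-in for spatially correlated physiological noise.
    """
    clean = np.asarray(clean, dtype=float)
    B = clean if clean.ndim == 2 else clean[:, None]
    rng = np.random.default_rng(seed)
    bg = leadfield @ rng.standard_normal((leadfield.shape[1], B.shape[1]))
    P = float(np.mean(np.sum(B**2, axis=0)))
    Pbg = float(np.mean(np.sum(bg**2, axis=0)))
    if P == 0.0 or Pbg == 0.0:
        raise ValueError("signal or background power is zero")
    out = B + np.sqrt(P / (brain_snr * Pbg)) * bg
    return out if clean.ndim == 2 else out[:, 0]


def smooth_timecourse(t: int, peak: float = 1.0) -> np.ndarray:
    """Smooth evoked-response-like bump (Hann window) of length t."""
    if t == 1:
        return np.array([peak])
    return peak * np.sin(np.pi * np.arange(t) / (t - 1)) ** 2


@dataclass
class SyntheticScenario:
    """A complete simulated MEG experiment with ground truth."""

    space: SourceSpace
    leadfield: np.ndarray  # (m, 3n)
    sensor_pos: np.ndarray  # (m, 3)
    sensor_ori: np.ndarray  # (m, 3)
    Q_true: np.ndarray  # (t, n, 3)
    support: np.ndarray  # active dipole indices
    clean: np.ndarray  # (m, t)
    noisy: np.ndarray  # (m, t)
    snr_target: float
    seed: int
    patch_center: np.ndarray
    nn_spacing: float  # median nearest-neighbor distance in the source space


def _nearest_neighbor_spacing(positions: np.ndarray) -> float:
    from scipy.spatial import cKDTree

    d, _ = cKDTree(positions).query(positions, k=2)
    return float(np.median(d[:, 1]))


def make_scenario(
    n: int = 400,
    m: int = 60,
    snr: float = 15.0,
    seed: int = 0,
    patch_size: int = 5,
    t: int = 1,
    source_radius: float = 0.07,
    sensor_radius: float = 0.1,
    amplitude: float = 1e-8,
) -> SyntheticScenario:
    """Build a tangential-patch MEG scenario with SNR-calibrated noise.

    A source sphere of ``n`` tangentially oriented dipoles, ``m`` radial
    magnetometers, a contiguous patch of ``patch_size`` active dipoles
    (a seed-chosen dipole and its nearest neighbors) with a smooth time
    course, and additive sensor noise at the target SNR.
    """
    rng = np.random.default_rng(seed)
    space = make_sphere_source_space(
        n, radius=source_radius, seed=seed, orientation="tangential"
    )
    sensor_pos, sensor_ori = make_sensor_array(m, radius=sensor_radius, seed=seed)
    M = make_meg_leadfield(space, sensor_pos, sensor_ori)
    center_idx = int(rng.integers(n))
    center = space.positions[center_idx]
    d = np.sort(np.linalg.norm(space.positions - center, axis=1))
    radius = d[min(patch_size, n) - 1] * (1.0 + 1e-9) if patch_size > 1 else d[0] + 1e-12
    tc = smooth_timecourse(t)
    Q_true, support = simulate_patch(space, center, radius, amplitude, tc)
    clean = M @ Q_true.reshape(t, -1).T
    noisy = add_noise(clean, snr, seed=seed + 1)
    return SyntheticScenario(
        space=space,
        leadfield=M,
        sensor_pos=sensor_pos,
        sensor_ori=sensor_ori,
        Q_true=Q_true,
        support=support,
        clean=clean,
        noisy=noisy,
        snr_target=snr,
        seed=seed,
        patch_center=center,
        nn_spacing=_nearest_neighbor_spacing(space.positions),
    )
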