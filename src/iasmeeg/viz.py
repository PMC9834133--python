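"""Sliced visualization of reconstructed activity maps.

The source space is subdivided along a chosen anatomical direction into
ten layers of equal thickness; each layer is shown as a 2-D scatter of
the in-plane dipole coordinates colored by the intensity a_j = ||q_j||.
Axes follow the right-handed convention x = right, y = front, z = crown,
so "axial" slices along z, "coronal" along y and "sagittal" along x.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from pathlib import Path
from typing import Optional, Sequence

import matplotlib

matplotlib.use("Agg", force=False)
import matplotlib.pyplot as plt
import numpy as np

__all__ = [
    "SliceParcellation",
    "parcel_slices",
    "render_activity_map",
    "render_single_slice",
    "extract_peak_timecourses",
]

_AXES = {"sagittal": 0, "coronal": 1, "axial": 2}
# in-plane coordinate indices and labels for each slicing direction
_PLANES = {
    "axial": ((0, 1), ("x (right)", "y (front)")),
    "coronal": ((0, 2), ("x (right)", "z (crown)")),
    "sagittal": ((1, 2), ("y (front)", "z (crown)")),
}


@dataclass
class SliceParcellation:
    """Assignment of every dipole to one of ``n_layers`` slabs."""

    axis: str
    boundaries: np.ndarray  # (n_layers + 1,)
    assignment: np.ndarray  # (n,) layer indices in 1..n_layers

    @property
    def n_layers(self) -> int:
        return self.boundaries.size - 1

    def counts(self) -> np.ndarray:
        return np.bincount(self.assignment, minlength=self.n_layers + 1)[1:]


def parcel_slices(space, axis: str, n_layers: int = 10) -> SliceParcellation:
    """Partition the source space into equal-thickness layers along an axis.

    Layer boundaries are c_min + l*(c_max - c_min)/n_layers, l = 0..n_layers.
    Intervals are half-open [c_{l-1}, c_l); the maximal coordinate is
    closed into the top layer so every dipole is assigned.  A degenerate
    extent (c_max = c_min) puts all points in layer 1.
    """
    if axis not in _AXES:
        raise ValueError(f"axis must be one of {sorted(_AXES)}, got {axis!r}")
    c = np.asarray(space.positions[:, _AXES[axis]], dtype=float)
    lo, hi = float(c.min()), float(c.max())
    boundaries = lo + np.arange(n_layers + 1) * (hi - lo) / n_layers
    if hi == lo:
        assignment = np.ones(c.size, dtype=int)
    else:
        assignment = np.searchsorted(boundaries[1:-1], c, side="right") + 1
    return SliceParcellation(axis=axis, boundaries=boundaries, assignment=assignment)


def _check_intensities(space, intensities) -> np.ndarray:
    a = np.asarray(intensities, dtype=float)
    if a.shape != (space.n,):
        raise ValueError(
            f"intensities length {a.shape} does not match source space ({space.n},)"
        )
    if np.any(a < 0):
        raise ValueError("intensities must be non-negative")
    return a


def render_activity_map(
    space,
    intensities: np.ndarray,
    out_dir,
    axes: Sequence[str] = ("axial", "coronal", "sagittal"),
    n_layers: int = 10,
    cmap: str = "hot",
) -> dict:
    """Render one multi-panel figure per view (ten layers each).

    Returns a dict mapping view name to ``{"path": ..., "counts": ...}``
    with the per-panel point counts, all panels sharing one color scale.
    """
    a = _check_intensities(space, intensities)
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    vmax = float(a.max()) if a.max() > 0 else 1.0
    result = {}
    for axis in axes:
        parc = parcel_slices(space, axis, n_layers=n_layers)
        (ix, iy), (lx, ly) = _PLANES[axis]
        ncols = 5
        nrows = int(np.ceil(n_layers / ncols))
        fig, ax_arr = plt.subplots(
            nrows, ncols, figsize=(3 * ncols, 3 * nrows), squeeze=False
        )
        counts = []
        sc = None
        for layer in range(1, n_layers + 1):
            ax = ax_arr[(layer - 1) // ncols][(layer - 1) % ncols]
            sel = parc.assignment == layer
            counts.append(int(sel.sum()))
            if sel.any():
                sc = ax.scatter(
                    space.positions[sel, ix],
                    space.positions[sel, iy],
                    c=a[sel],
                    cmap=cmap,
                    vmin=0.0,
                    vmax=vmax,
                    s=8,
                )
            ax.set_title(f"layer {layer}", fontsize=8)
            ax.set_xlabel(lx, fontsize=7)
            ax.set_ylabel(ly, fontsize=7)
            ax.set_aspect("equal")
        fig.suptitle(f"{axis} view — dipole intensity")
        if sc is not None:
            fig.colorbar(sc, ax=ax_arr.ravel().tolist(), shrink=0.6)
        path = out_dir / f"activity_{axis}.png"
        fig.savefig(path, dpi=100)
        plt.close(fig)
        result[axis] = {"path": str(path), "counts": counts}
    return result


def render_single_slice(
    space,
    intensities: np.ndarray,
    point: np.ndarray,
    out_path,
    marker: str = "x",
    n_layers: int = 10,
    cmap: str = "hot",
    coordinate_note: Optional[str] = None,
) -> dict:
    """Three panels (axial/coronal/sagittal) through a chosen point.

    The layer containing the point (half-open layer rule) is shown for
    each view, with a marker at the point's in-plane projection.  A point
    outside the source-space bounding box raises a warning and the
    nearest layer is used.
    """
    a = _check_intensities(space, intensities)
    point = np.asarray(point, dtype=float).reshape(3)
    if not np.all(np.isfinite(point)):
        raise ValueError("point must be finite")
    vmax = float(a.max()) if a.max() > 0 else 1.0
    fig, ax_arr = plt.subplots(1, 3, figsize=(12, 4))
    layers = {}
    sc = None
    for ax_plot, axis in zip(ax_arr, ("axial", "coronal", "sagittal")):
        parc = parcel_slices(space, axis, n_layers=n_layers)
        c = point[_AXES[axis]]
        lo, hi = parc.boundaries[0], parc.boundaries[-1]
        if c < lo or c > hi:
            warnings.warn(
                f"point coordinate {c:.4g} outside source space along {axis}; "
                "using nearest layer",
                stacklevel=2,
            )
        if hi == lo:
            layer = 1
        else:
            layer = int(
                np.clip(
                    np.searchsorted(parc.boundaries[1:-1], c, side="right") + 1,
                    1,
                    n_layers,
                )
            )
        layers[axis] = layer
        (ix, iy), (lx, ly) = _PLANES[axis]
        sel = parc.assignment == layer
        if sel.any():
            sc = ax_plot.scatter(
                space.positions[sel, ix],
                space.positions[sel, iy],
                c=a[sel],
                cmap=cmap,
                vmin=0.0,
                vmax=vmax,
                s=10,
            )
        ax_plot.plot(point[ix], point[iy], marker, color="cyan", markersize=10)
        ax_plot.set_title(f"{axis} layer {layer}", fontsize=9)
        ax_plot.set_xlabel(lx, fontsize=8)
        ax_plot.set_ylabel(ly, fontsize=8)
        ax_plot.set_aspect("equal")
    if coordinate_note:
        fig.suptitle(coordinate_note)
    if sc is not None:
        fig.colorbar(sc, ax=list(ax_arr), shrink=0.7)
    out_path = Path(out_path)
    out_path.parent.mkdir(parents=True, exist_ok=True)
    fig.savefig(out_path, dpi=100)
    plt.close(fig)
    return {"path": str(out_path), "layers": layers}


def extract_peak_timecourses(result, k: int) -> tuple[np.ndarray, np.ndarray]:
    """The k dipoles with largest peak intensity and their time traces.

    ``result`` is an :class:`~iasmeeg.solver.IASResult`; traces are the
    row norms a_j(t) = ||q_j(t)||.  ``k`` larger than the dipole count is
    clipped with a warning.  Indices are ordered by decreasing peak.
    """
    if k < 1:
        raise ValueError("k must be at least 1")
    a = result.intensities  # (t, n)
    n = a.shape[1]
    if k > n:
        warnings.warn(f"k={k} exceeds dipole count {n}; returning all", stacklevel=2)
        k = n
    peaks = np.nanmax(a, axis=0)
    order = np.argsort(peaks)[::-1][:k]
    return order, a[:, order].T
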