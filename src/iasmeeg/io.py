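"""Readers and writers for source spaces, lead fields, data and results.

Canonical on-disk layout is a single HDF5 file (or one per object) with
row-major 2-D datasets named

    positions      (n, 3)   source coordinates, meters
    orientations   (n, 3)   unit preferred directions
    leadfield      (m, 3n)
    data           (m, t)

MAT files are accepted read-only for interoperability: pre-7.3 files via
scipy.io, v7.3 files (HDF5 layout) via h5py with 2-D datasets transposed,
matching MATLAB's column-major storage.  Delimited text (.txt/.csv/.tsv)
holds a single matrix per file.
"""

from __future__ import annotations

from pathlib import Path
from typing import Optional

import h5py
import numpy as np

from .prior import SourceSpace

__all__ = [
    "load_matrix",
    "save_arrays",
    "read_source_space",
    "write_source_space",
    "read_inputs",
    "write_result",
    "read_result",
    "write_scenario",
]

_TEXT_SUFFIXES = {".txt", ".csv", ".tsv", ".dat"}
_HDF5_SUFFIXES = {".h5", ".hdf5"}

_CANONICAL_DATASETS = ("positions", "orientations", "leadfield", "data")


def _load_container(path: Path) -> dict:
    """Load all 2-D arrays from an HDF5/MAT container."""
    if path.suffix in _HDF5_SUFFIXES or (path.suffix == ".mat" and h5py.is_hdf5(path)):
        transpose = path.suffix == ".mat"  # MATLAB v7.3 stores column-major
        out = {}
        with h5py.File(path, "r") as f:
            def visit(name, obj):
                if isinstance(obj, h5py.Dataset) and obj.dtype.kind in "fiu":
                    arr = np.asarray(obj[()], dtype=float)
                    if transpose and arr.ndim == 2:
                        arr = arr.T
                    out[name.split("/")[-1]] = arr
            f.visititems(visit)
        return out
    if path.suffix == ".mat":
        import scipy.io

        raw = scipy.io.loadmat(path)
        return {
            k: np.asarray(v, dtype=float)
            for k, v in raw.items()
            if not k.startswith("__") and np.asarray(v).dtype.kind in "fiu"
        }
    raise ValueError(
        f"unknown container format {path.suffix!r}; supported: "
        f"{sorted(_HDF5_SUFFIXES)} and .mat"
    )


def load_matrix(path, name: Optional[str] = None) -> np.ndarray:
    """Load one matrix from HDF5/MAT (dataset ``name``) or delimited text."""
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    if path.suffix in _TEXT_SUFFIXES:
        delim = "," if path.suffix == ".csv" else None
        return np.atleast_2d(np.loadtxt(path, delimiter=delim))
    data = _load_container(path)
    if name is not None:
        if name not in data:
            raise KeyError(
                f"dataset {name!r} not found in {path}; available: {sorted(data)}"
            )
        return data[name]
    if len(data) == 1:
        return next(iter(data.values()))
    raise ValueError(
        f"{path} holds several datasets {sorted(data)}; specify which by name"
    )


def save_arrays(path, **arrays) -> None:
    """Write named arrays to an HDF5 file (or one matrix to text)."""
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    if path.suffix in _TEXT_SUFFIXES:
        if len(arrays) != 1:
            raise ValueError("text files hold exactly one matrix")
        (arr,) = arrays.values()
        np.savetxt(path, np.atleast_2d(arr))
        return
    with h5py.File(path, "w") as f:
        for k, v in arrays.items():
            f.create_dataset(k, data=np.asarray(v))


def read_source_space(path, orientations_path=None) -> SourceSpace:
    """Read a source space from a container or a pair of text files."""
    path = Path(path)
    if orientations_path is not None:
        pos = load_matrix(path)
        ori = load_matrix(orientations_path)
    else:
        data = _load_container(path)
        for key in ("positions", "orientations"):
            if key not in data:
                raise KeyError(f"{path} has no dataset {key!r}; found {sorted(data)}")
        pos, ori = data["positions"], data["orientations"]
    if pos.shape[1] != 3 and pos.shape[0] == 3:
        raise ValueError(
            f"positions are {pos.shape}; expected (n, 3) — transpose the input"
        )
    return SourceSpace(positions=pos, orientations=ori)


def write_source_space(path, space: SourceSpace) -> None:
    save_arrays(path, positions=space.positions, orientations=space.orientations)


def read_inputs(
    leadfield_path, sourcespace_path, data_path
) -> tuple[SourceSpace, np.ndarray, np.ndarray]:
    """Load and shape-check the three solver inputs.

    The lead field must be m x 3n for the n source points and the data
    must have m rows; violations raise errors naming the expected and
    found dimensions.
    """
    space = read_source_space(sourcespace_path)
    M = _load_named(leadfield_path, "leadfield")
    B = _load_named(data_path, "data")
    if M.shape[1] != 3 * space.n:
        raise ValueError(
            f"lead field has {M.shape[1]} columns but the source space implies "
            f"3n = {3 * space.n}; found shape {M.shape}"
            + (" — the matrix looks transposed" if M.shape[0] == 3 * space.n else "")
        )
    if B.shape[0] != M.shape[0]:
        raise ValueError(
            f"data has {B.shape[0]} rows (channels) but the lead field has "
            f"{M.shape[0]} rows"
        )
    return space, M, B


def _load_named(path, name: str) -> np.ndarray:
    """Load dataset ``name`` if the container has it, else its sole matrix."""
    path = Path(path)
    if path.suffix in _TEXT_SUFFIXES:
        return load_matrix(path)
    data = _load_container(path)
    if name in data:
        return data[name]
    if len(data) == 1:
        return next(iter(data.values()))
    raise KeyError(
        f"dataset {name!r} not found in {path}; available: {sorted(data)}"
    )


def write_result(path, result, config: Optional[dict] = None) -> None:
    """Persist an IASResult (Q_hat, theta_hat, diagnostics, config echo)."""
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    with h5py.File(path, "w") as f:
        f.create_dataset("Q_hat", data=result.Q_hat)
        f.create_dataset("theta_hat", data=result.theta_hat)
        f.create_dataset("converged", data=result.converged.astype(np.int8))
        g = f.create_group("diagnostics")
        for s, diag in enumerate(result.diagnostics):
            g.create_dataset(
                f"slice{s:05d}", data=np.asarray(diag, dtype=float).reshape(-1, 2)
            )
        if result.errors:
            e = f.create_group("errors")
            for s, msg in result.errors.items():
                e.attrs[str(s)] = msg
        if config:
            c = f.create_group("config")
            for k, v in config.items():
                if v is not None:
                    c.attrs[k] = v


def read_result(path):
    """Read back a result container written by :func:`write_result`."""
    from .solver import IASResult

    with h5py.File(path, "r") as f:
        diagnostics = []
        g = f["diagnostics"]
        for key in sorted(g):
            diagnostics.append([tuple(row) for row in np.asarray(g[key])])
        errors = {}
        if "errors" in f:
            errors = {int(k): v for k, v in f["errors"].attrs.items()}
        return IASResult(
            Q_hat=np.asarray(f["Q_hat"]),
            theta_hat=np.asarray(f["theta_hat"]),
            diagnostics=diagnostics,
            converged=np.asarray(f["converged"]).astype(bool),
            errors=errors,
        )


def write_scenario(path, scenario) -> None:
    """Write a synthetic scenario in the layout `read_inputs` expects,
    plus ground truth (Q_true, support) for tests."""
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    with h5py.File(path, "w") as f:
        f.create_dataset("positions", data=scenario.space.positions)
        f.create_dataset("orientations", data=scenario.space.orientations)
        f.create_dataset("leadfield", data=scenario.leadfield)
        f.create_dataset("data", data=scenario.noisy)
        f.create_dataset("clean", data=scenario.clean)
        f.create_dataset("Q_true", data=scenario.Q_true)
        f.create_dataset("support", data=scenario.support)
        f.create_dataset("sensor_pos", data=scenario.sensor_pos)
        f.create_dataset("sensor_ori", data=scenario.sensor_ori)
        f.create_dataset("patch_center", data=scenario.patch_center)
        f.attrs["snr_target"] = scenario.snr_target
        f.attrs["seed"] = scenario.seed
        f.attrs["n"] = scenario.space.n
        f.attrs["m"] = scenario.leadfield.shape[0]
        f.attrs["nn_spacing"] = scenario.nn_spacing
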