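"""End-to-end reconstruction pipeline: prior -> parameters -> solver -> figures."""

from __future__ import annotations

import dataclasses
import logging
from dataclasses import dataclass
from pathlib import Path
from typing import Optional

import numpy as np

from . import io as ias_io
from .hyper import set_parameters
from .prior import build_anatomical_prior
from .solver import IASConfig, IASResult, ias_time_series
from .viz import render_activity_map

logger = logging.getLogger(__name__)

__all__ = ["RunConfig", "run_pipeline"]


@dataclass
class RunConfig:
    """Configuration of one reconstruction run.

    Defaults: delta=0.05, eta=0.01, tau=0.01, n_outer=30, max_it=120,
    cutoff_quantile=1.0 (no truncation of the hyperprior scales).
    """

    leadfield: str
    sourcespace: str
    data: str
    output: str
    snr: float
    eta: float = 0.01
    delta: float = 0.05
    cutoff_quantile: float = 1.0
    tau: float = 0.01
    n_outer: int = 30
    max_it: int = 120
    warm_start: bool = True
    power_window: Optional[int] = None  # leading columns used for signal power
    figures: bool = True
    figure_dir: Optional[str] = None
    log_level: str = "INFO"

    @classmethod
    def from_yaml(cls, path, **overrides) -> "RunConfig":
        import yaml

        with open(path) as f:
            cfg = yaml.safe_load(f) or {}
        cfg.update({k: v for k, v in overrides.items() if v is not None})
        return cls(**cfg)

    def asdict(self) -> dict:
        return dataclasses.asdict(self)


def run_pipeline(cfg: RunConfig) -> IASResult:
    """Run the full reconstruction: read inputs, build the anatomical
    prior, set the hyperprior scales and noise model from the SNR, solve
    every time slice, undo the internal scalings, persist the result and
    optionally render the activity maps.

    Returns the :class:`IASResult` with moments in the input units.
    """
    logging.basicConfig(level=getattr(logging, cfg.log_level.upper(), logging.INFO))
    space, M, B = ias_io.read_inputs(cfg.leadfield, cfg.sourcespace, cfg.data)
    logger.info("inputs: n=%d dipoles, m=%d channels, t=%d slices",
                space.n, M.shape[0], B.shape[1])

    prior = build_anatomical_prior(space, delta=cfg.delta)
    window = B[:, : cfg.power_window] if cfg.power_window else B
    hyper, noise = set_parameters(
        M, prior, window, cfg.snr, eta=cfg.eta, cutoff_quantile=cfg.cutoff_quantile
    )
    M_s = hyper.scale_M * M
    B_s = hyper.scale_b * B

    solver_cfg = IASConfig(tau=cfg.tau, n_outer=cfg.n_outer, max_it=cfg.max_it)
    result = ias_time_series(
        B_s, M_s, prior, hyper, noise, solver_cfg, warm_start=cfg.warm_start
    )
    # b_s = M_s Q_s  =>  Q = (scale_M / scale_b) Q_s in the original units
    result.Q_hat *= hyper.scale_M / hyper.scale_b

    ias_io.write_result(cfg.output, result, config=cfg.asdict())
    logger.info("result written to %s", cfg.output)

    if cfg.figures:
        fig_dir = cfg.figure_dir or str(Path(cfg.output).with_suffix("")) + "_figures"
        peak_slice = int(np.argmax(np.nan_to_num(result.intensities).max(axis=1)))
        render_activity_map(space, np.nan_to_num(result.intensities[peak_slice]), fig_dir)
        logger.info("figures written to %s (peak slice %d)", fig_dir, peak_slice)
    return result
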