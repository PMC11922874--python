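"""Synthetic pseudo-experimental observations.

Calibration and sensitivity need measured time-series; this module
emulates a batch-fermentation dataset (time, glucose, biomass and the
three acids in g/L) by simulating the calibrated model at the experiment
conditions, sampling the observables at assay-like times, and applying
multiplicative Gaussian measurement noise.  Multiplicative noise reflects
that HPLC/OD-style assays have roughly constant relative error while the
observables span orders of magnitude within a run; a fixed coefficient of
variation of 5% is a typical instrument-level figure and the default.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Mapping, Optional, Sequence, Union

import numpy as np
import pandas as pd

from .calibrate import OBSERVATION_COLUMNS, ObservationSet, write_observations
from .model import ModelOptions
from .params import CalibratedParams, FixedParams, ParamError
from .simulate import ExperimentConfig, SolverOptions, simulate

__all__ = ["NoiseModel", "default_sampling", "generate_dataset", "write_dataset"]


@dataclass(frozen=True)
class NoiseModel:
    """Multiplicative Gaussian measurement noise.

    Each sampled value becomes ``value * (1 + cv * z)`` with z standard
    normal.  Values driven negative by noise are reported at the
    detection ``floor`` (g/L) rather than resampled — a small, documented
    bias confined to near-zero measurements.  ``seed`` makes the dataset
    reproducible.
    """

    cv: float = 0.05
    floor: float = 0.01
    seed: int = 0

    def __post_init__(self) -> None:
        if self.cv < 0:
            raise ParamError(f"noise cv must be >= 0, got {self.cv}")


def default_sampling(config: ExperimentConfig) -> np.ndarray:
    """Assay-like sampling times: every 2 h to 24 h, every 4 h thereafter."""
    dense = np.arange(0.0, min(24.0, config.t_end) + 1e-9, 2.0)
    if config.t_end <= 24.0:
        return dense
    sparse = np.arange(28.0, config.t_end + 1e-9, 4.0)
    return np.concatenate([dense, sparse])


def generate_dataset(
    params: Optional[CalibratedParams] = None,
    fixed: Optional[FixedParams] = None,
    configs: Optional[Mapping[str, ExperimentConfig]] = None,
    sampling: Optional[Mapping[str, Sequence[float]]] = None,
    noise: NoiseModel = NoiseModel(),
    solver_opts: Optional[SolverOptions] = None,
    model_opts: Optional[ModelOptions] = None,
) -> list[ObservationSet]:
    """Simulate each experiment and emit noisy observation sets.

    ``sampling`` maps experiment name to sampling times (defaulting to
    :func:`default_sampling`); all times must lie within the horizon.
    With ``cv = 0`` the dataset equals the simulated observables exactly.
    """
    params = params if params is not None else CalibratedParams()
    fixed = fixed if fixed is not None else FixedParams()
    if configs is None:
        from .simulate import experiment_configs

        configs = experiment_configs()

    rng = np.random.default_rng(noise.seed)
    out = []
    for name, config in configs.items():
        times = np.asarray(
            sampling[name] if sampling is not None and name in sampling
            else default_sampling(config),
            dtype=float,
        )
        if times.min() < 0 or times.max() > config.t_end + 1e-9:
            raise ParamError(f"{name}: sampling times outside [0, {config.t_end}]")
        traj = simulate(config, params, fixed, solver_opts, model_opts)
        obs = traj.observables_at(times)
        frame = pd.DataFrame({"time_h": times})
        for col in OBSERVATION_COLUMNS:
            values = obs[col].to_numpy(dtype=float)
            if noise.cv > 0:
                values = values * (1.0 + noise.cv * rng.standard_normal(values.shape))
                values = np.where(values < 0, noise.floor, values)
            frame[col] = values
        out.append(ObservationSet(experiment=name, data=frame))
    return out


def write_dataset(datasets: Sequence[ObservationSet], out_dir: Union[str, Path]) -> list[Path]:
    """Write one CSV per experiment into ``out_dir``; returns the paths."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    paths = []
    for obs in datasets:
        path = out_dir / f"{obs.experiment}.csv"
        write_observations(obs, path)
        paths.append(path)
    return paths
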