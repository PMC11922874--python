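"""Least-squares calibration of the kinetic parameters.

The objective is a max-normalised sum of squared errors between measured
and simulated g/L observables,

    SSE = sum_experiments sum_variables sum_times
          (C_data - C_sim)^2 / C_data_max,

where ``C_data_max`` is the per-variable, per-experiment maximum of the
measured values (first power, as the objective is defined) and simulated
values are evaluated from the integrator's dense output at each
observation time.  Missing observations (blank cells) contribute nothing.

Minimisation uses the Nelder–Mead simplex over the logarithms of a chosen
free-parameter subset: log-space makes every proposal strictly positive,
which negative rate constants would otherwise violate (and crash the
integrator).  The full 38-parameter joint fit is expressible but small
free subsets are the intended (and testable) use.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Optional, Sequence, Union

import numpy as np
import pandas as pd
from scipy.optimize import minimize

from .model import ModelOptions
from .params import CalibratedParams, FixedParams, ParamError
from .simulate import (
    ExperimentConfig,
    IntegrationError,
    SolverOptions,
    simulate,
)

__all__ = [
    "ObservationSet",
    "CalibrationResult",
    "OBSERVATION_COLUMNS",
    "sse",
    "calibrate",
    "read_observations",
    "write_observations",
]

#: variables entering the objective, in file-header order
OBSERVATION_COLUMNS = ("glucose_gL", "biomass_gL", "SA_gL", "AA_gL", "FA_gL")


@dataclass
class ObservationSet:
    """Measured time-series for one batch experiment.

    ``data`` has a strictly increasing ``time_h`` column plus the five g/L
    observable columns; NaN marks a missing measurement.
    """

    experiment: str
    data: pd.DataFrame

    def __post_init__(self) -> None:
        missing = {"time_h", *OBSERVATION_COLUMNS} - set(self.data.columns)
        if missing:
            raise ParamError(f"{self.experiment}: observation columns missing {sorted(missing)}")
        t = self.data["time_h"].to_numpy(dtype=float)
        if len(t) and not np.all(np.diff(t) > 0):
            raise ParamError(f"{self.experiment}: observation times must be strictly increasing")

    @property
    def times(self) -> np.ndarray:
        return self.data["time_h"].to_numpy(dtype=float)


def read_observations(path: Union[str, Path], experiment: Optional[str] = None) -> ObservationSet:
    """Read one delimited observation file (blank cells = missing)."""
    path = Path(path)
    frame = pd.read_csv(path)
    name = experiment if experiment is not None else path.stem
    return ObservationSet(experiment=name, data=frame)


def write_observations(obs: ObservationSet, path: Union[str, Path]) -> None:
    cols = ["time_h", *OBSERVATION_COLUMNS]
    obs.data.loc[:, cols].to_csv(path, index=False)


def sse(
    params: CalibratedParams,
    data: Sequence[ObservationSet],
    fixed: Optional[FixedParams] = None,
    configs: Optional[Mapping[str, ExperimentConfig]] = None,
    solver_opts: Optional[SolverOptions] = None,
    model_opts: Optional[ModelOptions] = None,
) -> float:
    """Max-normalised sum of squared errors of ``params`` against ``data``.

    Returns ``+inf`` (a penalty, not an exception) when the simulation
    fails at the proposed parameter set.  Experiments whose observations
    are all missing contribute zero.
    """
    fixed = fixed if fixed is not None else FixedParams()
    if configs is None:
        from .simulate import experiment_configs

        configs = experiment_configs()

    total = 0.0
    for obs in data:
        if obs.experiment not in configs:
            raise ParamError(f"no experiment config named {obs.experiment!r}")
        config = configs[obs.experiment]
        times = obs.times
        if len(times) == 0:
            continue
        if times[-1] > config.t_end + 1e-9:
            raise ParamError(
                f"{obs.experiment}: observation at t={times[-1]} beyond horizon {config.t_end}"
            )
        try:
            traj = simulate(config, params, fixed, solver_opts, model_opts)
        except IntegrationError:
            return float("inf")
        sim = traj.observables_at(times)
        for col in OBSERVATION_COLUMNS:
            measured = obs.data[col].to_numpy(dtype=float)
            mask = np.isfinite(measured)
            if not mask.any():
                continue
            c_max = measured[mask].max()
            if c_max <= 0:
                continue
            resid = measured[mask] - sim[col].to_numpy(dtype=float)[mask]
            total += float(np.sum(resid**2) / c_max)
    return total


@dataclass
class CalibrationResult:
    """Outcome of a Nelder–Mead run.

    ``params`` is the best point seen (never worse than the start);
    ``report`` carries iterations, function evaluations, convergence flag
    and the final simplex spread.
    """

    params: CalibratedParams
    sse: float
    report: dict = field(default_factory=dict)


def calibrate(
    initial: CalibratedParams,
    data: Sequence[ObservationSet],
    fixed: Optional[FixedParams] = None,
    configs: Optional[Mapping[str, ExperimentConfig]] = None,
    free: Optional[Sequence[str]] = None,
    max_iter: int = 400,
    fatol: float = 1e-8,
    xatol: float = 1e-6,
    solver_opts: Optional[SolverOptions] = None,
    model_opts: Optional[ModelOptions] = None,
) -> CalibrationResult:
    """Minimise :func:`sse` over ``free`` parameters by Nelder–Mead.

    ``free`` names the parameters allowed to move (default: all).  The
    search runs in log-parameter space.  Non-convergence is reported in
    the result, not raised; only an infeasible starting point (infinite
    SSE) is a hard error.
    """
    fixed = fixed if fixed is not None else FixedParams()
    free = list(free) if free is not None else list(initial.names)
    unknown = set(free) - set(initial.names)
    if unknown:
        raise ParamError(f"unknown free parameter(s) {sorted(unknown)}")

    def with_values(log_values: np.ndarray) -> CalibratedParams:
        return initial.replace(**{n: float(np.exp(v)) for n, v in zip(free, log_values)})

    def objective(log_values: np.ndarray) -> float:
        try:
            candidate = with_values(log_values)
        except ParamError:
            return float("inf")
        return sse(candidate, data, fixed, configs, solver_opts, model_opts)

    x0 = np.log([getattr(initial, n) for n in free])
    f0 = objective(x0)
    if not np.isfinite(f0):
        raise IntegrationError("initial parameter set is infeasible (SSE = inf)")

    result = minimize(
        objective,
        x0,
        method="Nelder-Mead",
        options={"maxiter": max_iter, "fatol": fatol, "xatol": xatol},
    )
    final_simplex = getattr(result, "final_simplex", None)
    spread = float(np.ptp(final_simplex[1])) if final_simplex is not None else float("nan")

    if np.isfinite(result.fun) and result.fun <= f0:
        best_params, best_sse = with_values(result.x), float(result.fun)
    else:  # simplex wandered; keep the start (descent property)
        best_params, best_sse = initial, f0
    return CalibrationResult(
        params=best_params,
        sse=best_sse,
        report={
            "start_sse": f0,
            "iterations": int(result.nit),
            "function_evaluations": int(result.nfev),
            "converged": bool(result.success),
            "simplex_spread": spread,
            "message": str(result.message),
            "free": free,
        },
    )
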