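"""Parameter sets for the A. succinogenes batch fermentation model.

Two immutable parameter bundles drive the model:

* :class:`FixedParams` — molecular weights and stoichiometric mole ratios of
  the lumped reaction network.  These are physical/compositional constants
  and are never fitted.
* :class:`CalibratedParams` — kinetic maximum rates, half-saturation
  constants, intracellular pool caps, ATP-cost coefficients and the logistic
  response-curve shape parameters.  These are the quantities adjusted during
  calibration.

Both ship with packaged defaults (YAML under ``succdyn/data``): the fixed
constants, the calibrated values of the published fit, and the pre-fit
starting guesses.  ``load_params``/``save_params`` round-trip either bundle
through flat key–value YAML.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass
from importlib import resources
from pathlib import Path
from typing import Union

import yaml

__all__ = [
    "FixedParams",
    "CalibratedParams",
    "ParamError",
    "load_params",
    "save_params",
    "default_fixed_params",
    "default_calibrated_params",
    "precalibration_params",
]


class ParamError(ValueError):
    """Raised when a parameter file is malformed or a value is inadmissible."""


@dataclass(frozen=True)
class FixedParams:
    """Molecular weights (g/mol), biomass ATP content and stoichiometry.

    ``MW_X`` is the formula weight of the biomass monomer CH2O0.5N0.18.
    ``s_ATP`` is the total adenylate pool per gram of biomass (gX^-1); the
    ``nu_*`` entries are mole ratios of the lumped reactions (product per
    substrate), and ``nu_ATP1..5`` the ATP yields/costs of each step.
    """

    MW_X: float = 24.55
    MW_G: float = 180.16
    MW_G3P: float = 170.06
    MW_PEP: float = 168.04
    MW_P: float = 88.06
    MW_SA: float = 118.09
    MW_AA: float = 60.05
    MW_FA: float = 46.03
    s_ATP: float = 1.00
    nu_G3P: float = 2.00
    nu_P: float = 1.00
    nu_Pyr: float = 1.00
    nu_X: float = 3.00
    nu_SA: float = 1.00
    nu_AA: float = 1.00
    nu_FA: float = 1.00
    nu_ATP1: float = 2.00
    nu_ATP2: float = 1.00
    nu_ATP3: float = 1.00
    nu_ATP4: float = 1.00
    nu_ATP5: float = 1.00

    def __post_init__(self) -> None:
        for name, value in dataclasses.asdict(self).items():
            if not value > 0:
                raise ParamError(f"fixed parameter {name!r} must be > 0, got {value}")


@dataclass(frozen=True)
class CalibratedParams:
    """The fitted kinetic and regulatory parameters.

    Units follow the lumped-network convention: maximum rates ``v_*`` in
    mol (molX)^-1 h^-1, half-saturations ``k_Gly1`` in mol/L and the
    intracellular ones in mol (molX)^-1, pool caps ``*_max`` in g gX^-1,
    logistic midpoints ``G_mid*``/``*_mid`` in grams (divided by the matching
    molecular weight inside the response curves), slopes ``k1..k7`` per mol.
    ``a1`` is the depth of the glucose-uptake down-throttle (uptake tends to
    ``1 - a1`` at saturating glucose); ``a2`` the floor of the G/X-ratio
    gate.  Defaults are the published calibrated fit.
    """

    v_Gly1: float = 2.32
    k_Gly1: float = 39.99
    v_Gly2: float = 1.78
    k_Gly2: float = 1.24e-10
    v_Gly3: float = 1.08
    k_Gly3: float = 9.90e-5
    v_P1: float = 0.27
    k_P1: float = 2.65e-5
    v_P2: float = 0.12
    k_P2: float = 6.71e-4
    v_P3: float = 0.20
    k_P3: float = 3.70e-4
    v_G: float = 8.61e-2
    k_G: float = 1.89e-4
    G3P_max: float = 4.97e-4
    PEP_max: float = 4.70e-4
    P_max: float = 4.54e-4
    eta_X: float = 0.83
    n_X: float = 1.57
    n_SA: float = 1.49
    n_AA: float = 6.15
    n_FA: float = 3.01
    a1: float = 0.88
    k1: float = 53.39
    G_mid1: float = 51.49
    a2: float = 0.18
    k2: float = 10.13
    R_mid: float = 1.20
    k3: float = 22.06
    ATP_mid: float = 0.36
    k4: float = 4.10e2
    G_mid2: float = 2.02
    k5: float = 13.84
    SA_mid: float = 23.05
    k6: float = 11.04
    AA_mid: float = 0.45
    k7: float = 8.67
    FA_mid: float = 1.08

    def __post_init__(self) -> None:
        for name, value in dataclasses.asdict(self).items():
            if not value > 0:
                raise ParamError(
                    f"calibrated parameter {name!r} must be > 0, got {value}"
                )
        if not self.a1 <= 1:
            raise ParamError(f"a1 must lie in (0, 1], got {self.a1}")
        if not self.a2 <= 1:
            raise ParamError(f"a2 must lie in (0, 1], got {self.a2}")

    def replace(self, **changes: float) -> "CalibratedParams":
        """Return a copy with the given parameters replaced."""
        return dataclasses.replace(self, **changes)

    @property
    def names(self) -> tuple[str, ...]:
        return tuple(f.name for f in dataclasses.fields(self))


ParamSet = Union[FixedParams, CalibratedParams]

_KIND_TO_CLS = {"fixed": FixedParams, "calibrated": CalibratedParams}


def _data_path(name: str) -> Path:
    return Path(str(resources.files("succdyn").joinpath("data", name)))


def default_fixed_params() -> FixedParams:
    """The packaged fixed constants (network stoichiometry and weights)."""
    return load_params(_data_path("fixed_params.yaml"))  # type: ignore[return-value]


def default_calibrated_params() -> CalibratedParams:
    """The packaged calibrated fit."""
    return load_params(_data_path("calibrated_params.yaml"))  # type: ignore[return-value]


def precalibration_params() -> CalibratedParams:
    """The packaged pre-fit starting guesses used to seed calibration.

    Note the starting guess sets ``a2 = 1``, which degenerates the G/X-ratio
    gate to a constant 1; this is an admissible (if inert) configuration.
    """
    return load_params(_data_path("calibrated_params_start.yaml"))  # type: ignore[return-value]


def load_params(path: Union[str, Path]) -> ParamSet:
    """Load a parameter bundle from flat key–value YAML.

    The file must carry ``kind: fixed`` or ``kind: calibrated`` and exactly
    the declared field names of the corresponding bundle; unknown or missing
    keys and non-positive values raise :class:`ParamError` naming the key.
    """
    path = Path(path)
    try:
        raw = yaml.safe_load(path.read_text())
    except yaml.YAMLError as exc:  # pragma: no cover - parser detail
        raise ParamError(f"cannot parse {path}: {exc}") from exc
    if not isinstance(raw, dict):
        raise ParamError(f"{path}: expected a mapping of parameter names to values")
    kind = raw.pop("kind", None)
    if kind not in _KIND_TO_CLS:
        raise ParamError(
            f"{path}: missing or invalid 'kind' (expected 'fixed' or 'calibrated', got {kind!r})"
        )
    cls = _KIND_TO_CLS[kind]
    declared = {f.name for f in dataclasses.fields(cls)}
    unknown = set(raw) - declared
    if unknown:
        raise ParamError(f"{path}: unknown parameter(s) {sorted(unknown)}")
    missing = declared - set(raw)
    if missing:
        raise ParamError(f"{path}: missing parameter(s) {sorted(missing)}")
    values = {}
    for key, value in raw.items():
        try:
            values[key] = float(value)
        except (TypeError, ValueError) as exc:
            raise ParamError(f"{path}: parameter {key!r} is not a number: {value!r}") from exc
    return cls(**values)


def save_params(params: ParamSet, path: Union[str, Path]) -> None:
    """Write a parameter bundle as flat key–value YAML (lossless round-trip)."""
    kind = "fixed" if isinstance(params, FixedParams) else "calibrated"
    payload = {"kind": kind, **dataclasses.asdict(params)}
    Path(path).write_text(
        yaml.safe_dump(payload, sort_keys=False, default_flow_style=False)
    )
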