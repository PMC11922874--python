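"""Core kinetics: response curves, process rates and the ODE right-hand side.

The model tracks ten state variables of an anaerobic *A. succinogenes* batch
culture: extracellular glucose ``G`` (mol/L), the intracellular glycolytic
intermediates ``G3P``, ``PEP`` and ``P`` (mol per molX of biomass), biomass
``X`` (molX/L), the extracellular fermentation acids ``SA``, ``AA`` and
``FA`` (mol/L), and the dimensionless adenylate pools ``ATP`` and ``ADP``.

Seven lumped processes move mass through the network — three glycolytic
steps (glucose -> G3P -> PEP -> pyruvate), three fermentative productions
(PEP -> succinate; pyruvate -> acetate; pyruvate -> acetate + formate) and
growth (pyruvate -> biomass).  Each is a Michaelis–Menten rate, first order
in biomass, throttled by logistic "response curves" that encode the model's
regulatory premise: the cell guards its ATP/ADP balance.  ATP-consuming
steps are gated by ``RC_ATP`` (high when energy charge is high),
ATP-producing steps by its complement ``RC_ADP``; glucose uptake is
up-regulated when glucose is scarce (``RC_v1``) and throttled when the
glucose-to-biomass ratio is high (``RC_v2``); growth shuts down when
glucose runs out (``RC_G``); and exporting each acid against its external
gradient costs ATP at a rate gated by ``RC_SA``/``RC_AA``/``RC_FA``.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Callable, Optional

import numpy as np
from scipy.special import expit

from .params import CalibratedParams, FixedParams

__all__ = [
    "StateVector",
    "RateBundle",
    "ModelOptions",
    "InvalidStateError",
    "STATE_NAMES",
    "rc_v1",
    "rc_v2",
    "rc_atp",
    "rc_adp",
    "rc_g",
    "rc_acid",
    "process_rates",
    "ode_rhs",
    "effective_molar_constants",
    "initial_energy",
]

STATE_NAMES = ("G", "G3P", "PEP", "P", "X", "SA", "AA", "FA", "ATP", "ADP")


class InvalidStateError(ValueError):
    """A state violates the model's admissibility conditions (e.g. X <= 0)."""


@dataclass(frozen=True)
class StateVector:
    """One point of the ten-dimensional state.

    Extracellular species (G, SA, AA, FA) in mol/L, intracellular pools
    (G3P, PEP, P) in mol per molX, biomass X in molX/L, ATP/ADP
    dimensionless.
    """

    G: float
    G3P: float
    PEP: float
    P: float
    X: float
    SA: float
    AA: float
    FA: float
    ATP: float
    ADP: float

    def to_array(self) -> np.ndarray:
        return np.array(
            [self.G, self.G3P, self.PEP, self.P, self.X,
             self.SA, self.AA, self.FA, self.ATP, self.ADP],
            dtype=float,
        )

    @classmethod
    def from_array(cls, y: np.ndarray) -> "StateVector":
        return cls(*(float(v) for v in y))


@dataclass(frozen=True)
class RateBundle:
    """The seven extensive process rates, mol/L/h (already multiplied by X)."""

    glycolysis1: float
    glycolysis2: float
    glycolysis3: float
    production1: float
    production2: float
    production3: float
    growth: float

    def to_array(self) -> np.ndarray:
        return np.array(
            [self.glycolysis1, self.glycolysis2, self.glycolysis3,
             self.production1, self.production2, self.production3, self.growth],
            dtype=float,
        )


@dataclass(frozen=True)
class ModelOptions:
    """Switches for structural points the model description leaves open.

    ``dilution_factor`` — coefficient on the growth correction term of the
    adenylate balances.  The default 1.0 keeps the total adenylate pool
    proportional to biomass, so the per-gram pool stays at its assumed
    constant ``s_ATP``; with any other value c the total pool grows as
    X**c and the per-gram energy charge drifts with growth (c = 3 shuts
    the ADP-gated chain down entirely once biomass roughly doubles).
    ``log_base`` — base of the logarithm in the glucose/biomass-ratio gate
    (natural log by default).  ``secretion`` — optional biomass loss term
    (molX/L/h as a function of the state); the model assumes no cell death
    and the default keeps it at zero.
    """

    dilution_factor: float = 1.0
    log_base: float = float(np.e)
    secretion: Optional[Callable[[np.ndarray], float]] = field(default=None)


_DEFAULT_OPTS = ModelOptions()


def rc_v1(G: float, params: CalibratedParams, fixed: FixedParams) -> float:
    """Glucose-uptake up-regulation gate, in [1 - a1, 1].

    Near 1 when glucose is scarce (uptake machinery fully up-regulated),
    dropping to ``1 - a1`` at saturating glucose.  The midpoint ``G_mid1``
    is stored in grams and converted through MW_G.
    """
    return 1.0 - params.a1 * float(
        expit(params.k1 * (G - params.G_mid1 / fixed.MW_G))
    )


def rc_v2(
    G: float,
    X: float,
    params: CalibratedParams,
    opts: ModelOptions = _DEFAULT_OPTS,
) -> float:
    """Glucose/biomass-ratio gate on uptake, in [a2, 1].

    A logistic in log(G/X) that *slows uptake when glucose is abundant
    relative to the population*: near 1 once the population has caught up
    with its substrate (log ratio below ``R_mid``), dropping to the floor
    ``a2`` while glucose is in large excess.  The log compresses the orders
    of magnitude this ratio spans across a batch.  At ``G <= 0`` the
    analytic limit 1 is returned rather than evaluating log(0).
    """
    if X <= 0:
        raise InvalidStateError(f"rc_v2 requires X > 0, got X={X}")
    if G <= 0:
        return 1.0
    log_ratio = np.log(G / X) / np.log(opts.log_base)
    return params.a2 + (1.0 - params.a2) * float(
        expit(params.k2 * (params.R_mid - log_ratio))
    )


def rc_atp(ATP: float, X: float, params: CalibratedParams, fixed: FixedParams) -> float:
    """Energy-charge gate for ATP-consuming processes, in (0, 1).

    Driven by the adenylate pool per gram of biomass, ATP/(X * MW_X);
    crosses 1/2 at ``ATP_mid``.
    """
    if X <= 0:
        raise InvalidStateError(f"rc_atp requires X > 0, got X={X}")
    return float(expit(params.k3 * (ATP / (X * fixed.MW_X) - params.ATP_mid)))


def rc_adp(ATP: float, X: float, params: CalibratedParams, fixed: FixedParams) -> float:
    """Complement gate for ATP-producing processes: 1 - rc_atp."""
    return 1.0 - rc_atp(ATP, X, params, fixed)


def rc_g(G: float, params: CalibratedParams, fixed: FixedParams) -> float:
    """Growth nutrient gate: shuts growth down as glucose is exhausted."""
    return float(expit(params.k4 * (G - params.G_mid2 / fixed.MW_G)))


def rc_acid(acid_conc: float, k_acid: float, acid_mid: float, MW_acid: float) -> float:
    """Acid-extrusion resistance gate, shared by SA/AA/FA.

    Rises with the external acid concentration: exporting against a steeper
    gradient costs more ATP.  ``acid_mid`` is in grams, converted through
    the acid's molecular weight.
    """
    return float(expit(k_acid * (acid_conc - acid_mid / MW_acid)))


def _saturation_brake(pool: float, cap_g_per_gX: float, MW_pool: float, MW_X: float) -> float:
    # Product-saturation factor 1 - (pool/cap)*(MW_pool/MW_X), clamped at 0:
    # the cap is a brake on the forward rate, never a reverse flux.
    return max(0.0, 1.0 - (pool / cap_g_per_gX) * (MW_pool / MW_X))


def effective_molar_constants(params: CalibratedParams, fixed: FixedParams) -> dict[str, float]:
    """Half-saturation constants converted to the molar state units.

    The calibrated table stores half-saturations in the mixed mass/mole
    conventions of the source material; the state vector is molar
    (mol/L extracellular, mol/molX intracellular).  ``k_Gly1`` is carried
    in grams of glucose (like the logistic midpoints) and is divided by
    MW_G; ``k_P1``, ``k_P2``, ``k_P3`` and ``k_G`` are carried in grams of
    substrate per gram of biomass and are multiplied by MW_X/MW_substrate;
    ``k_Gly2`` and ``k_Gly3`` are already in mol per molX.  These
    assignments are fixed properties of the parameter set (documented in
    the methods note), not tuning knobs.
    """
    return {
        "k_Gly1": params.k_Gly1 / fixed.MW_G,
        "k_Gly2": params.k_Gly2,
        "k_Gly3": params.k_Gly3,
        "k_P1": params.k_P1 * fixed.MW_X / fixed.MW_PEP,
        "k_P2": params.k_P2 * fixed.MW_X / fixed.MW_P,
        "k_P3": params.k_P3 * fixed.MW_X / fixed.MW_P,
        "k_G": params.k_G * fixed.MW_X / fixed.MW_P,
    }


def process_rates(
    state: StateVector,
    params: CalibratedParams,
    fixed: FixedParams,
    opts: ModelOptions = _DEFAULT_OPTS,
) -> RateBundle:
    """Evaluate the seven process rates at one state (all clamped >= 0)."""
    G, G3P, PEP, P, X = state.G, state.G3P, state.PEP, state.P, state.X
    if X <= 0:
        raise InvalidStateError(f"process_rates requires X > 0, got X={X}")

    f_atp = rc_atp(state.ATP, X, params, fixed)
    f_adp = 1.0 - f_atp
    k = effective_molar_constants(params, fixed)

    gly1 = (
        params.v_Gly1
        * rc_v1(G, params, fixed)
        * rc_v2(G, X, params, opts)
        * _mm(G, k["k_Gly1"])
        * X
        * _saturation_brake(G3P, params.G3P_max, fixed.MW_G3P, fixed.MW_X)
        * f_atp
    )
    gly2 = (
        params.v_Gly2
        * _mm(G3P, k["k_Gly2"])
        * X
        * _saturation_brake(PEP, params.PEP_max, fixed.MW_PEP, fixed.MW_X)
        * f_adp
    )
    gly3 = (
        params.v_Gly3
        * _mm(PEP, k["k_Gly3"])
        * X
        * _saturation_brake(P, params.P_max, fixed.MW_P, fixed.MW_X)
        * f_adp
    )
    prod1 = params.v_P1 * _mm(PEP, k["k_P1"]) * X * f_adp
    prod2 = params.v_P2 * _mm(P, k["k_P2"]) * X * f_adp
    prod3 = params.v_P3 * _mm(P, k["k_P3"]) * X * f_adp
    growth = params.v_G * _mm(P, k["k_G"]) * X * f_atp * rc_g(G, params, fixed)

    return RateBundle(
        glycolysis1=max(0.0, gly1),
        glycolysis2=max(0.0, gly2),
        glycolysis3=max(0.0, gly3),
        production1=max(0.0, prod1),
        production2=max(0.0, prod2),
        production3=max(0.0, prod3),
        growth=max(0.0, growth),
    )


def _mm(substrate: float, half_sat: float) -> float:
    # Michaelis–Menten saturation; negative integrator undershoot is treated
    # as an empty pool.
    if substrate <= 0:
        return 0.0
    return substrate / (half_sat + substrate)


def ode_rhs(
    t: float,
    y: np.ndarray,
    params: CalibratedParams,
    fixed: FixedParams,
    opts: ModelOptions = _DEFAULT_OPTS,
) -> np.ndarray:
    """Time derivative of the ten-dimensional state (order ``STATE_NAMES``).

    Extracellular balances are extensive (mol/L/h); the intracellular pools
    are per-molX, so their flux balances are divided by X.  The adenylate
    balances collect the ATP yields and costs of every process, the
    acid-extrusion costs gated by the extrusion-resistance curves, and a
    growth correction term ``dilution_factor * (pool/X) * dX/dt`` that keeps
    the per-biomass adenylate level from being diluted by growth.  Summing
    the two balances, every stoichiometric term cancels:
    d(ATP+ADP)/dt = dilution_factor * ((ATP+ADP)/X) * dX/dt, so the total
    pool grows as X**dilution_factor (proportional to biomass at the
    default factor 1).
    """
    if not np.all(np.isfinite(y)):
        raise InvalidStateError(f"non-finite state at t={t}: {y}")
    state = StateVector.from_array(y)
    if state.X <= 0:
        raise InvalidStateError(f"X must stay > 0 along a trajectory, got {state.X} at t={t}")

    r = process_rates(state, params, fixed, opts)
    gly1, gly2, gly3 = r.glycolysis1, r.glycolysis2, r.glycolysis3
    prod1, prod2, prod3, growth = r.production1, r.production2, r.production3, r.growth
    X = state.X

    secretion = opts.secretion(y) if opts.secretion is not None else 0.0
    dX = fixed.nu_X * params.eta_X * growth - secretion

    dG = -gly1
    dG3P = (fixed.nu_G3P * gly1 - gly2) / X
    dPEP = (fixed.nu_P * gly2 - gly3 - prod1) / X
    dP = (fixed.nu_Pyr * gly3 - prod2 - prod3 - growth) / X
    dSA = fixed.nu_SA * prod1
    dAA = fixed.nu_AA * (prod2 + prod3)
    dFA = fixed.nu_FA * prod3

    extrusion_cost = (
        params.n_SA * fixed.nu_SA * prod1
        * rc_acid(state.SA, params.k5, params.SA_mid, fixed.MW_SA)
        + params.n_AA * fixed.nu_AA * (prod2 + prod3)
        * rc_acid(state.AA, params.k6, params.AA_mid, fixed.MW_AA)
        + params.n_FA * fixed.nu_FA * prod3
        * rc_acid(state.FA, params.k7, params.FA_mid, fixed.MW_FA)
    )
    atp_turnover = (
        -fixed.nu_ATP1 * gly1
        + fixed.nu_ATP2 * gly2
        + fixed.nu_ATP3 * gly3
        + fixed.nu_ATP4 * fixed.nu_SA * prod1
        + fixed.nu_ATP5 * fixed.nu_AA * (prod2 + prod3)
        - params.eta_X * params.n_X * fixed.nu_X * growth
        - extrusion_cost
    )
    dATP = atp_turnover + opts.dilution_factor * (state.ATP / X) * dX
    dADP = -atp_turnover + opts.dilution_factor * (state.ADP / X) * dX

    return np.array([dG, dG3P, dPEP, dP, dX, dSA, dAA, dFA, dATP, dADP])


def initial_energy(X0: float, fixed: FixedParams) -> tuple[float, float]:
    """Initial adenylate pools for an inoculum of X0 molX/L.

    The total pool is ``s_ATP`` per gram of biomass and is split evenly
    between ATP and ADP at t0: ATP0 = ADP0 = s_ATP * X0 * MW_X / 2.
    """
    if X0 <= 0:
        raise InvalidStateError(f"initial_energy requires X0 > 0, got {X0}")
    half = fixed.s_ATP * X0 * fixed.MW_X / 2.0
    return half, half
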