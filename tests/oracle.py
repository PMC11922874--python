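"""Independent scalar re-implementation of the model equations.

Written as a straight, naive transcription of the rate laws and mass
balances — plain ``math`` calls, no vectorisation, no code shared with
``succdyn.model`` — so it can serve as an oracle for the packaged
right-hand side.  Structural conventions (half-saturation unit readings,
ratio-gate orientation, adenylate growth-correction factor) are written
out longhand here on purpose: agreement between two independently typed
versions of the same conventions is the property under test.
"""

import math


def _logistic(x: float) -> float:
    # saturating logistic, safe against overflow of exp
    if x >= 700.0:
        return 1.0
    if x <= -700.0:
        return 0.0
    return 1.0 / (1.0 + math.exp(-x))


def oracle_rhs(t, y, p, f, dilution_factor=1.0):
    """Time derivative of the ten states; mirrors the printed balances."""
    G, G3P, PEP, P, X, SA, AA, FA, ATP, ADP = [float(v) for v in y]
    if X <= 0:
        raise ValueError("X must be positive")

    # response curves
    rc1 = 1.0 - p.a1 * _logistic(p.k1 * (G - p.G_mid1 / f.MW_G))
    if G <= 0:
        rc2 = 1.0
    else:
        rc2 = p.a2 + (1.0 - p.a2) * _logistic(p.k2 * (p.R_mid - math.log(G / X)))
    rc_atp = _logistic(p.k3 * (ATP / (X * f.MW_X) - p.ATP_mid))
    rc_adp = 1.0 - rc_atp
    rc_g = _logistic(p.k4 * (G - p.G_mid2 / f.MW_G))
    rc_sa = _logistic(p.k5 * (SA - p.SA_mid / f.MW_SA))
    rc_aa = _logistic(p.k6 * (AA - p.AA_mid / f.MW_AA))
    rc_fa = _logistic(p.k7 * (FA - p.FA_mid / f.MW_FA))

    # half-saturations brought to molar state units
    kg1 = p.k_Gly1 / f.MW_G
    kg2 = p.k_Gly2
    kg3 = p.k_Gly3
    kp1 = p.k_P1 * f.MW_X / f.MW_PEP
    kp2 = p.k_P2 * f.MW_X / f.MW_P
    kp3 = p.k_P3 * f.MW_X / f.MW_P
    kgr = p.k_G * f.MW_X / f.MW_P

    def mm(s, k):
        return 0.0 if s <= 0 else s / (k + s)

    def brake(pool, cap, mw):
        v = 1.0 - (pool / cap) * (mw / f.MW_X)
        return v if v > 0 else 0.0

    gly1 = (p.v_Gly1 * rc1 * rc2 * mm(G, kg1) * X
            * brake(G3P, p.G3P_max, f.MW_G3P) * rc_atp)
    gly2 = p.v_Gly2 * mm(G3P, kg2) * X * brake(PEP, p.PEP_max, f.MW_PEP) * rc_adp
    gly3 = p.v_Gly3 * mm(PEP, kg3) * X * brake(P, p.P_max, f.MW_P) * rc_adp
    prod1 = p.v_P1 * mm(PEP, kp1) * X * rc_adp
    prod2 = p.v_P2 * mm(P, kp2) * X * rc_adp
    prod3 = p.v_P3 * mm(P, kp3) * X * rc_adp
    growth = p.v_G * mm(P, kgr) * X * rc_atp * rc_g
    gly1, gly2, gly3 = max(gly1, 0.0), max(gly2, 0.0), max(gly3, 0.0)
    prod1, prod2, prod3, growth = (max(prod1, 0.0), max(prod2, 0.0),
                                   max(prod3, 0.0), max(growth, 0.0))

    dX = f.nu_X * p.eta_X * growth
    dG = -gly1
    dG3P = (f.nu_G3P * gly1 - gly2) / X
    dPEP = (f.nu_P * gly2 - gly3 - prod1) / X
    dP = (f.nu_Pyr * gly3 - prod2 - prod3 - growth) / X
    dSA = f.nu_SA * prod1
    dAA = f.nu_AA * (prod2 + prod3)
    dFA = f.nu_FA * prod3

    extrusion = (p.n_SA * f.nu_SA * prod1 * rc_sa
                 + p.n_AA * f.nu_AA * (prod2 + prod3) * rc_aa
                 + p.n_FA * f.nu_FA * prod3 * rc_fa)
    turnover = (-f.nu_ATP1 * gly1
                + f.nu_ATP2 * gly2
                + f.nu_ATP3 * gly3
                + f.nu_ATP4 * f.nu_SA * prod1
                + f.nu_ATP5 * f.nu_AA * (prod2 + prod3)
                - p.eta_X * p.n_X * f.nu_X * growth
                - extrusion)
    dATP = turnover + dilution_factor * (ATP / X) * dX
    dADP = -turnover + dilution_factor * (ADP / X) * dX
    return [dG, dG3P, dPEP, dP, dX, dSA, dAA, dFA, dATP, dADP]


def oracle_elemental_effect(param_name, delta, params, fixed, config, n_times, n_params,
                            simulate_fn):
    """Two-simulation hand computation of the standardised elemental effect.

    Uses the package's integrator (``simulate_fn``) but performs the
    perturbation, sampling and summation explicitly outside the
    sensitivity module.
    """
    import numpy as np

    times = np.linspace(0.0, config.t_end, n_times)
    base = simulate_fn(config, params, fixed).observables_at(times)
    pert_params = params.replace(**{param_name: getattr(params, param_name) * (1 + delta)})
    pert = simulate_fn(config, pert_params, fixed).observables_at(times)
    total = 0.0
    for col in ("biomass_gL", "SA_gL"):
        ref = base[col].to_numpy()
        diff = pert[col].to_numpy() - ref
        total += float((diff ** 2).mean() / (ref.max() - ref.min()))
    return total / n_params
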