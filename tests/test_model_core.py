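"""Process rates, mass balances and the initial energy split."""

import numpy as np
import pytest

from succdyn import (
    CalibratedParams,
    FixedParams,
    InvalidStateError,
    ModelOptions,
    StateVector,
    effective_molar_constants,
    initial_energy,
    ode_rhs,
    process_rates,
)

from .conftest import random_admissible_states
from .oracle import oracle_rhs

P = CalibratedParams()
F = FixedParams()


def g1_initial_state():
    atp0, _ = initial_energy(1.05e-3, F)
    return StateVector(G=0.03, G3P=0, PEP=0, P=0, X=1.05e-3,
                       SA=0, AA=0, FA=0, ATP=atp0, ADP=atp0)


class TestProcessRates:
    def test_empty_intracellular_pools_silence_downstream_processes(self):
        r = process_rates(g1_initial_state(), P, F)
        assert r.glycolysis2 == r.glycolysis3 == 0
        assert r.production1 == r.production2 == r.production3 == r.growth == 0
        assert r.glycolysis1 > 0

    def test_half_saturation_with_gates_forced_open(self):
        # a2 = 1 degenerates the ratio gate to 1; a1 -> 0 opens the
        # up-regulation gate; a huge ATP pool pushes the energy gate to 1
        open_params = P.replace(a1=1e-12, a2=1.0)
        k = effective_molar_constants(open_params, F)
        X = 2e-3
        s = StateVector(G=k["k_Gly1"], G3P=0, PEP=0, P=0, X=X,
                        SA=0, AA=0, FA=0, ATP=1e3, ADP=0)
        r = process_rates(s, open_params, F)
        assert r.glycolysis1 == pytest.approx(0.5 * open_params.v_Gly1 * X, rel=1e-9)

    def test_rates_at_inoculum_match_independent_evaluation(self):
        # dG/dt of the oracle is -glycolysis1 by construction
        r = process_rates(g1_initial_state(), P, F)
        d = oracle_rhs(0.0, g1_initial_state().to_array(), P, F)
        assert r.glycolysis1 == pytest.approx(-d[0], rel=1e-12)
        assert r.glycolysis1 == pytest.approx(4.9930710823490344e-05, rel=1e-12)

    def test_rates_nonnegative_on_random_admissible_states(self):
        rng = np.random.default_rng(20260927)
        for y in random_admissible_states(rng, 200):
            r = process_rates(StateVector.from_array(y), P, F)
            assert np.all(r.to_array() >= 0)

    def test_rejects_nonpositive_biomass(self):
        s = StateVector(G=0.1, G3P=0, PEP=0, P=0, X=0.0,
                        SA=0, AA=0, FA=0, ATP=0.01, ADP=0.01)
        with pytest.raises(InvalidStateError):
            process_rates(s, P, F)


class TestMassBalances:
    def test_matches_independent_scalar_oracle(self):
        """Packaged RHS vs a naive independent transcription, 1e-12 relative."""
        rng = np.random.default_rng(42)
        for dil in (1.0, 3.0):
            opts = ModelOptions(dilution_factor=dil)
            for y in random_admissible_states(rng, 100):
                ours = ode_rhs(0.0, y, P, F, opts)
                ref = np.array(oracle_rhs(0.0, y, P, F, dilution_factor=dil))
                np.testing.assert_allclose(ours, ref, rtol=1e-12, atol=1e-300)

    def test_adenylate_stoichiometry_cancels_in_the_sum(self):
        """d(ATP+ADP)/dt reduces to the growth correction term alone."""
        rng = np.random.default_rng(7)
        for dil in (1.0, 3.0):
            opts = ModelOptions(dilution_factor=dil)
            for y in random_admissible_states(rng, 50):
                d = ode_rhs(0.0, y, P, F, opts)
                total, X = y[8] + y[9], y[4]
                expected = dil * (total / X) * d[4]
                assert d[8] + d[9] == pytest.approx(expected, rel=1e-9, abs=1e-18)

    def test_uptake_is_the_only_glucose_sink(self):
        s = g1_initial_state()
        d = ode_rhs(0.0, s.to_array(), P, F)
        assert d[0] == -process_rates(s, P, F).glycolysis1

    def test_resting_state_has_zero_derivatives(self):
        # biomass with no substrate, no intermediates and no ATP does nothing
        y = StateVector(G=0, G3P=0, PEP=0, P=0, X=1e-3,
                        SA=0, AA=0, FA=0, ATP=0, ADP=0).to_array()
        np.testing.assert_array_equal(ode_rhs(0.0, y, P, F), np.zeros(10))

    def test_rejects_nonfinite_and_nonpositive_biomass_states(self):
        y = g1_initial_state().to_array()
        y_bad = y.copy()
        y_bad[4] = -1e-9
        with pytest.raises(InvalidStateError):
            ode_rhs(0.0, y_bad, P, F)
        y_nan = y.copy()
        y_nan[0] = np.nan
        with pytest.raises(InvalidStateError):
            ode_rhs(0.0, y_nan, P, F)

    def test_secretion_hook_reduces_biomass_derivative(self):
        y = g1_initial_state().to_array()
        leak = 1e-6
        opts = ModelOptions(secretion=lambda state: leak)
        base = ode_rhs(0.0, y, P, F)
        with_leak = ode_rhs(0.0, y, P, F, opts)
        assert with_leak[4] == pytest.approx(base[4] - leak, rel=1e-12)


class TestInitialEnergy:
    @pytest.mark.parametrize(
        "X0, printed",
        [(1.05e-3, 1.29e-2), (1.93e-3, 2.37e-2), (7.25e-4, 8.90e-3),
         (1.07e-3, 1.31e-2), (5.64e-4, 6.92e-3)],
    )
    def test_matches_published_initial_values_at_print_precision(self, X0, printed):
        atp0, adp0 = initial_energy(X0, F)
        assert atp0 == adp0
        assert atp0 == pytest.approx(printed, abs=0.005 * 10 ** np.floor(np.log10(printed)))

    def test_inversion(self):
        X0 = 2.0 / (F.s_ATP * F.MW_X)
        assert initial_energy(X0, F)[0] == pytest.approx(1.0, rel=1e-15)

    def test_rejects_nonpositive_inoculum(self):
        with pytest.raises(InvalidStateError):
            initial_energy(0.0, F)
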