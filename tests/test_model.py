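"""Flux laws, right-hand side structure, and steady states."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from caspulse import (
    InvalidArgumentError,
    KineticParameters,
    NumericalFailureError,
    SystemState,
    caspase9_active,
    disc_occupancy,
    flux_direct_cleavage,
    flux_disc_activation,
    flux_mito_cleavage,
    pre_stimulus_steady_state,
    receptor_equilibrium,
    steady_state_at_dose,
    system_rhs,
)


class TestDiscOccupancy:
    @pytest.mark.parametrize(
        "pro_c8, K1, K2, expected",
        [
            (0.0, 50.0, 50.0, 0.0),                 # no zymogen, no loaded DISC
            (1e9, 50.0, 50.0, 1.0),                 # saturation limit
            (50.0, 50.0, 50.0, 1.0 / 3.0),          # equal Boltzmann weights
            # 33.33^2 / (2500 + 50*33.33 + 33.33^2), the three-state equilibrium
            (33.33, 50.0, 50.0, 0.210501),
        ],
    )
    def test_equilibrium_fraction(self, pro_c8, K1, K2, expected):
        assert disc_occupancy(pro_c8, K1, K2) == pytest.approx(expected, rel=1e-4, abs=1e-9)

    def test_matches_three_state_linear_system(self):
        # independent oracle: solve the quasi-equilibrium balance as a linear
        # system in the state weights instead of using the closed form
        c, K1, K2 = 33.33, 50.0, 50.0
        w = np.array([1.0, c / K1, (c / K1) * (c / K2)])
        assert disc_occupancy(c, K1, K2) == pytest.approx(w[2] / w.sum(), rel=1e-12)

    @given(c=st.floats(0, 1e4), K1=st.floats(0.1, 1e3), K2=st.floats(0.1, 1e3))
    @settings(max_examples=50, derandomize=True, deadline=None)
    def test_fraction_bounded_and_monotone_in_substrate(self, c, K1, K2):
        f = disc_occupancy(c, K1, K2)
        assert 0.0 <= f <= 1.0
        assert disc_occupancy(c * 2 + 1e-9, K1, K2) >= f

    def test_invalid_arguments(self):
        with pytest.raises(InvalidArgumentError):
            disc_occupancy(-1.0, 50, 50)
        with pytest.raises(InvalidArgumentError):
            disc_occupancy(1.0, 0.0, 50)


class TestReceptorAndFluxes:
    def test_receptor_equilibrium(self, params):
        assert receptor_equilibrium(0.0, params) == 0.0
        # asymptote is the total receptor pool
        assert receptor_equilibrium(1e9, params) == pytest.approx(params.tnfr_total, rel=1e-6)
        # K0 = 0.909/nM: 10 * 1.818/2.818
        assert receptor_equilibrium(2.0, params) == pytest.approx(6.4514, rel=1e-4)

    def test_disc_activation_flux(self, params):
        assert flux_disc_activation(0.0, 33.33, params) == 0.0
        assert flux_disc_activation(5.0, 0.0, params) == 0.0
        # v1 * R * occupancy = 2.65e-3 * 6.451 * 0.21050
        assert flux_disc_activation(6.451, 33.33, params) == pytest.approx(3.599e-3, rel=1e-3)

    def test_direct_cleavage_flux(self, params):
        assert flux_direct_cleavage(0.0, 200.0, params) == 0.0
        assert flux_direct_cleavage(1.0, 200.0, params) == pytest.approx(1.2e-2, rel=1e-12)
        assert flux_direct_cleavage(0.93, 180.0, params) == pytest.approx(1.0044e-2, rel=1e-6)

    def test_caspase9_activation(self, params):
        assert caspase9_active(0.0, params) == 0.0
        # half-saturation at K3 = 8 nM of the caspase-8 signal
        assert caspase9_active(8.0, params) == pytest.approx(10.0, rel=1e-12)
        assert caspase9_active(0.93, params) == pytest.approx(2.0829, rel=1e-4)

    def test_mito_cleavage_flux(self, params):
        assert flux_mito_cleavage(200.0, 0.0, params) == 0.0
        # saturation: v3 * pro_c3 * casp9_total
        assert flux_mito_cleavage(200.0, 1e9, params) == pytest.approx(
            params.v3 * 200.0 * params.casp9_total, rel=1e-6)
        # v3 * 180 * caspase9_active(0.93) = 2.6e-4 * 180 * 2.0829
        assert flux_mito_cleavage(180.0, 0.93, params) == pytest.approx(9.748e-2, rel=1e-4)


class TestSystemRhs:
    def test_fixed_point_has_zero_derivative(self, params):
        rest = pre_stimulus_steady_state(params)
        dy = system_rhs(0.0, rest.as_array(), 0.0, 0.0, params)
        assert np.max(np.abs(dy)) < 1e-12

    def test_all_processes_off_gives_zero_vector(self):
        # flux/synthesis/degradation rates cannot be zero by invariant, so
        # use vanishingly small values and a tight bound instead
        tiny = dict(v1=1e-30, v2=1e-30, v3=1e-30, v_syn_c8=1e-30, v_syn_c3=1e-30,
                    d_c8=1e-30, d_c3=1e-32, d_c8a=1e-28, d_c3a=1e-29)
        import warnings

        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            p = KineticParameters().with_overrides(**tiny)
        y = np.array([0.0, 30.0, 150.0, 1.0, 5.0])
        assert np.max(np.abs(system_rhs(0.0, y, 1.0, 0.0, p))) < 1e-25

    @pytest.mark.parametrize("state", [
        np.array([3.0, 20.0, 150.0, 0.5, 10.0]),
        np.array([9.0, 1.0, 5.0, 2.0, 80.0]),
    ])
    def test_caspase8_stoichiometric_conservation(self, params, state):
        # with synthesis and degradation off, d(pro_c8 + 2 act_c8)/dt = 0
        # exactly: the -2 V1 consumption cancels the dimer production
        import warnings

        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            p = params.with_overrides(v_syn_c8=1e-300, v_syn_c3=1e-300,
                                      d_c8=1e-300, d_c3=1e-300,
                                      d_c8a=1e-297, d_c3a=1e-297)
        dy = system_rhs(0.0, state, state[3], 2.0, p)
        assert dy[1] + 2.0 * dy[3] == pytest.approx(0.0, abs=1e-18)
        assert dy[2] + dy[4] == pytest.approx(0.0, abs=1e-18)


class TestSteadyStates:
    def test_pre_stimulus_pools(self, params):
        rest = pre_stimulus_steady_state(params)
        assert rest.pro_c8 == pytest.approx(33.35, rel=1e-10)     # v_syn_c8/d_c8
        assert rest.pro_c3 == pytest.approx(200.0, rel=1e-10)     # v_syn_c3/d_c3
        assert rest.act_c8 == 0.0 and rest.act_c3 == 0.0 and rest.tnfr_bound == 0.0

    def test_zero_dose_equals_rest(self, params):
        ss = steady_state_at_dose(0.0, params)
        rest = pre_stimulus_steady_state(params)
        assert np.allclose(ss.as_array(), rest.as_array(), rtol=1e-9, atol=1e-12)

    def test_receptor_component_decouples(self, params):
        ss = steady_state_at_dose(2.0, params)
        assert ss.tnfr_bound == pytest.approx(receptor_equilibrium(2.0, params), rel=1e-9)

    def test_low_dose_linearity_of_act_c8(self, params):
        # act_c8 ~ eps * v1 * tnfr_total * K0 * occ(rest) / d_c8a as eps -> 0
        rest = pre_stimulus_steady_state(params)
        slope = (params.v1 * params.tnfr_total * params.K0
                 * disc_occupancy(rest.pro_c8, params.K1, params.K2) / params.d_c8a)
        # the linear regime narrows as eps grows (pro-caspase-8 depletion
        # enters at second order), so the tolerance tracks the step size
        for eps, rel in ((1e-4, 5e-3), (1e-5, 5e-4)):
            ss = steady_state_at_dose(eps, params)
            assert ss.act_c8 / eps == pytest.approx(slope, rel=rel)

    def test_reached_from_arbitrary_positive_state(self, params):
        x0 = SystemState(5.0, 300.0, 2.0, 4.0, 150.0)
        ss = steady_state_at_dose(0.5, params, x0=x0)
        ref = steady_state_at_dose(0.5, params)
        assert np.allclose(ss.as_array(), ref.as_array(), rtol=1e-8, atol=1e-12)
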