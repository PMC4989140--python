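"""Pennes bioheat stepping: closed forms, conservation, pulse structure."""

import numpy as np
import pytest

import endostim as es
from endostim import materials as mat
from endostim.bioheat import BioheatSystem, joule_source
from endostim.fixtures import lumped_pennes_temperature, make_box_domain

from conftest import COARSE

T0 = mat.BODY_TEMPERATURE_K


class TestPulseTrain:
    def test_duty_cycle_arithmetic(self):
        assert es.PulseTrain(repetition_rate=50.0).duty_cycle == \
            pytest.approx(0.5)
        assert es.PulseTrain(repetition_rate=1.0).duty_cycle == \
            pytest.approx(0.01)

    def test_duty_over_100pct_rejected(self):
        with pytest.raises(es.ConfigurationError):
            es.PulseTrain(pulse_duration=0.05, repetition_rate=50.0)

    @pytest.mark.parametrize("bad", [dict(amplitude=0.0),
                                     dict(session_duration=-1.0)])
    def test_non_positive_parameters_rejected(self, bad):
        with pytest.raises(es.ConfigurationError):
            es.PulseTrain(**bad)


class TestJouleSource:
    def test_joule_heating_is_sigma_e_squared(self, uniform_solution):
        p = joule_source(uniform_solution)
        domain = uniform_solution.domain
        wall = domain.material == mat.WALL
        assert np.allclose(p[wall], 0.25 * 100.0 ** 2)
        blood = domain.material == mat.BLOOD
        assert np.allclose(p[blood], 0.7 * 100.0 ** 2)

    def test_zero_potential_gives_zero_source(self):
        domain = es.build_domain(**COARSE)
        solution = es.FieldSolution(domain, np.zeros(domain.shape),
                                    np.zeros(domain.shape),
                                    np.zeros(domain.shape), 0.0)
        assert np.all(joule_source(solution) == 0.0)

    def test_deposited_power_matches_terminal_power(self, default_solution):
        # domain integral of sigma |E|^2 vs sum_k V_k I_k at the electrodes
        p = joule_source(default_solution)
        deposited = float((p * default_solution.domain.cell_areas).sum())
        currents = es.electrode_currents(default_solution)
        terminal = sum(v * i for v, i in currents.items())
        assert deposited == pytest.approx(terminal, rel=0.02)


class TestStepping:
    def test_steady_state_preserved_without_source(self):
        domain = make_box_domain(0.01, 0.01, 8, 8, mat.MUSCLE)
        system = BioheatSystem(domain, perfusion_factor=1.0)
        temp = np.full(domain.shape, T0)
        for _ in range(5):
            temp = system.step(temp, 0.01)
        assert np.allclose(temp, T0, atol=1e-9)

    def test_lumped_ramp_without_perfusion(self):
        # k has no effect in a single cell; wall tissue has no perfusion
        fixture = es.make_lumped_thermal(p=5e5, perfusion_factor=0.0,
                                         material="wall", t_end=0.02)
        props = mat.MATERIALS["wall"]
        analytic = 5e5 * 0.02 / (props.density * props.heat_capacity)
        assert fixture.expected == pytest.approx(analytic, rel=1e-12)
        assert fixture.run() == pytest.approx(analytic, rel=1e-6)

    def test_lumped_saturation_with_perfusion(self):
        p = 5e5
        fixture = es.make_lumped_thermal(p=p, perfusion_factor=1.0,
                                         t_end=0.2)
        blood = mat.MATERIALS["blood"]
        sink = blood.perfusion_rate * blood.heat_capacity * blood.density
        # 0.2 s is ~12 time constants: the step response has saturated
        assert fixture.expected == pytest.approx(p / sink, rel=1e-4)
        assert fixture.run() == pytest.approx(fixture.expected, rel=5e-3)

    def test_doubling_power_doubles_steady_rise(self):
        t1 = lumped_pennes_temperature(1.0, 2e5, 1.0) - T0
        t2 = lumped_pennes_temperature(1.0, 4e5, 1.0) - T0
        assert t2 == pytest.approx(2 * t1, rel=1e-12)

    def test_energy_conservation_in_insulated_box(self):
        # no perfusion, no metabolic heat: enthalpy gain = integrated Joule
        domain = make_box_domain(0.02, 0.02, 10, 10, mat.MUSCLE)
        system = BioheatSystem(domain, perfusion_factor=1.0)
        power = np.zeros(domain.shape)
        power[3:6, 2:8] = 1e6
        temp = np.full(domain.shape, T0)
        dt, n = 0.05, 40
        for _ in range(n):
            temp = system.step(temp, dt, power)
        rho_c = domain.property_map("density") * \
            domain.property_map("heat_capacity")
        enthalpy = float((rho_c * domain.cell_areas * (temp - T0)).sum())
        injected = float((power * domain.cell_areas).sum()) * dt * n
        assert enthalpy == pytest.approx(injected, rel=0.01)

    def test_invalid_timestep_rejected(self):
        domain = make_box_domain(0.01, 0.01, 4, 4)
        system = BioheatSystem(domain)
        with pytest.raises(es.TimeStepError):
            system.step(np.full(domain.shape, T0), 0.0)


@pytest.fixture(scope="module")
def coarse_session_solution(config_n4):
    return es.solve(es.domain_for(config_n4, **COARSE))


class TestSessions:
    def test_pulse_gated_heating_modulates_wall_temperature(
            self, coarse_session_solution):
        """Wall warms faster during pulses than between them (sawtooth)."""
        train = es.PulseTrain(repetition_rate=10.0, session_duration=0.5)
        result = es.run_session(coarse_session_solution, train,
                                perfusion_factor=0.01)
        # 10 on-steps (1 ms) + 9 off-steps (10 ms) per 100 ms period
        per = 10 + 9
        probe = result.probe_history[:, 0]
        peaks = probe[9::per]                     # end of each pulse
        troughs = probe[per - 1::per]             # end of each off interval
        n = min(len(peaks), len(troughs))
        rate_on = (peaks[1:n] - troughs[:n - 1]) / 0.010
        rate_off = (troughs[:n - 1] - peaks[:n - 1]) / 0.090
        assert np.all(rate_on > rate_off)
        assert np.all(np.diff(peaks[:n]) > 0)     # envelope still rising

    def test_rise_monotone_in_repetition_rate(self, coarse_session_solution):
        rises = []
        for rate in (1.0, 10.0, 50.0):
            train = es.PulseTrain(repetition_rate=rate, session_duration=2.0)
            rises.append(es.run_session(coarse_session_solution, train,
                                        perfusion_factor=0.01).max_wall_rise)
        assert rises[0] < rises[1] < rises[2]

    def test_rise_anti_monotone_in_perfusion(self, coarse_session_solution):
        train = es.PulseTrain(repetition_rate=50.0, session_duration=2.0)
        rises = [es.run_session(coarse_session_solution, train,
                                perfusion_factor=f).max_wall_rise
                 for f in (1.0, 0.1, 0.01)]
        assert rises[0] <= rises[1] <= rises[2]
        assert rises[0] < rises[2]

    def test_temperature_never_below_baseline(self, coarse_session_solution):
        train = es.PulseTrain(repetition_rate=10.0, session_duration=0.3)
        result = es.run_session(coarse_session_solution, train,
                                perfusion_factor=1.0)
        assert result.final_temperature_map.min() >= T0 - 1e-9
        assert result.max_wall_rise >= 0

    def test_halving_dt_changes_rise_below_2pct(self,
                                                coarse_session_solution):
        train = es.PulseTrain(repetition_rate=50.0, session_duration=1.0)
        rises = [es.run_session(coarse_session_solution, train,
                                perfusion_factor=0.01, dt_on=dt,
                                dt_off_max=dt * 10).max_wall_rise
                 for dt in (1e-3, 0.5e-3)]
        assert abs(rises[1] / rises[0] - 1) < 0.02
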