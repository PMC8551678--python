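import dataclasses
import math

import numpy as np
import pytest

from leafhydraulics import (
    ContinuousLeaf,
    EventSchedule,
    ExciseSource,
    HydraulicNetwork,
    NodeSpec,
    SetAtmosphere,
    SourceAttachment,
    UniformLeafParams,
    apply_excision,
    assemble_transient_system,
    build_uniform_chain,
    derive_state,
    excised_decay,
    fit_exponential,
    set_source_waveform,
    simulate,
    solve_steady,
    step_euler,
    time_constant_excised,
)
from leafhydraulics.transient import StabilityWarning, UnsupportedNodeError


def storage_chain(N=100, C=30.0, Rc=1.0, psi_a=-100.0):
    return build_uniform_chain(
        UniformLeafParams(N=N, R=2.0, Ra=50.0, psi0=0.0, psi_a=psi_a, Rc=Rc, C=C)
    )


class TestAssembly:
    def test_single_sourced_node_hand_assembly(self):
        net = HydraulicNetwork(
            [NodeSpec(1, Ra=2.0, Rc=4.0, C=10.0)],
            [],
            [SourceAttachment(1, 0.0, 1.0)],
            -8.0,
        )
        psi = np.array([-1.0])
        A, b = assemble_transient_system(net, psi)
        # diagonal collects source, stomatal and storage conductances
        assert A == pytest.approx(np.array([[1.0 + 0.5 + 0.25]]))
        # rhs: conservation imbalance scaled by 1/(C·Rc)
        imbalance = (0.0 - (-1.0)) / 1.0 + (-8.0 - (-1.0)) / 2.0
        assert b == pytest.approx(np.array([imbalance / (10.0 * 4.0)]))

    def test_matrix_symmetric_on_fixtures(self):
        for net in (storage_chain(N=7), storage_chain(N=30, C=120.0, Rc=50.0)):
            A, _ = assemble_transient_system(net, np.zeros(net.n))
            assert np.linalg.norm(A - A.T) == 0.0

    def test_rhs_vanishes_at_steady_state(self):
        net = storage_chain(N=20)
        psi = solve_steady(net).psi
        _, b = assemble_transient_system(net, psi)
        assert np.max(np.abs(b)) < 1e-12

    def test_storage_free_node_rejected_with_hint(self):
        net = build_uniform_chain(
            UniformLeafParams(N=4, R=2.0, Ra=50.0, psi0=0.0, psi_a=-100.0)
        )
        with pytest.raises(UnsupportedNodeError, match="small C"):
            assemble_transient_system(net, np.zeros(4))


class TestStepEuler:
    def test_steady_state_is_fixed_point(self):
        net = storage_chain(N=25)
        state = solve_steady(net)
        advanced = step_euler(net, state, 0.6)
        np.testing.assert_allclose(advanced.psi, state.psi, atol=1e-12)

    def test_single_node_relaxation_matches_rc_closed_form(self):
        # excised single node: psi relaxes to psi_a with tau = C(Rc+Ra)
        C, Rc, Ra, psi_a = 30.0, 1.0, 50.0, -100.0
        net = HydraulicNetwork([NodeSpec(1, Ra, Rc, C)], [], [], psi_a)
        tau = C * (Rc + Ra)
        dt = tau / 1000.0
        state = derive_state(net, np.array([0.0]))
        t_end = tau
        steps = int(round(t_end / dt))
        for _ in range(steps):
            state = step_euler(net, state, dt)
        expected = psi_a + (0.0 - psi_a) * math.exp(-t_end / tau)
        assert state.psi[0] == pytest.approx(expected, rel=1e-3)

    def test_transpiration_jumps_with_atmosphere_while_psi_continuous(self):
        net = storage_chain(N=50)
        state = solve_steady(net)
        stepped = net.copy()
        stepped.psi_a = -150.0
        after = derive_state(stepped, state.psi)
        np.testing.assert_allclose(after.psi, state.psi)
        jump = after.E - state.E
        assert jump == pytest.approx((-100.0 - (-150.0)) / 50.0, rel=1e-9)

    def test_stability_guard_warns_on_large_step(self):
        net = storage_chain(N=10)
        state = solve_steady(net)
        with pytest.warns(StabilityWarning):
            step_euler(net, state, 1e5)
        with pytest.raises(ValueError, match="unstable"):
            step_euler(net, state, 1e5, strict_stability=True)


class TestSimulate:
    def test_excision_follows_exponential_decay(self):
        C, Rc = 30.0, 1.0
        leaf = ContinuousLeaf(R=2.0, Ra=50.0, psi0=0.0, psi_a=-100.0, Rc=Rc, C=C)
        tau = time_constant_excised(leaf)
        net = storage_chain(C=C, Rc=Rc)
        res = simulate(
            net, "steady", [(0.0, ExciseSource())], T=3 * tau, dt=0.6, output_every=20
        )
        psi_ref, E_ref = excised_decay(leaf, res.times)
        assert np.max(np.abs(res.E - E_ref) / np.abs(E_ref)) < 0.01
        assert np.max(np.abs(res.psi_bar - psi_ref) / np.abs(psi_ref)) < 0.01

    def test_atmosphere_step_reaches_new_steady_state(self):
        net = storage_chain(N=100, C=60.0, Rc=25.0)
        res = simulate(
            net,
            "steady",
            [(0.0, SetAtmosphere(-150.0))],
            T=45000.0,
            dt=0.6,
            output_every=100,
        )
        assert res.psi_bar[-1] == pytest.approx(-1.97, abs=5e-3)

    def test_empty_schedule_stays_flat(self):
        net = storage_chain(N=30)
        res = simulate(net, "steady", None, T=600.0, dt=0.6, output_every=50)
        drift = np.max(np.abs(res.psi_bar - res.psi_bar[0]))
        assert drift < 1e-8 * abs(res.psi_bar[0])

    def test_event_beyond_horizon_rejected(self):
        net = storage_chain(N=10)
        with pytest.raises(ValueError, match="beyond"):
            simulate(net, "steady", [(100.0, ExciseSource())], T=10.0)

    def test_kirchhoff_influx_balance_every_output_step(self):
        net = storage_chain(N=40)
        res = simulate(
            net, "steady", [(60.0, SetAtmosphere(-120.0))], T=600.0, dt=0.6, output_every=25
        )
        for state in res.states:
            influx = float(state.I_source.sum())
            assert abs(state.E + state.I_c.sum() - influx) <= 1e-8 * max(1.0, abs(influx))

    def test_first_order_convergence_in_dt(self):
        # halving dt should roughly halve the trajectory error of Euler
        net = storage_chain(N=20, C=30.0, Rc=1.0)
        T = 1536.0  # ~tau, exactly divisible by all three step sizes
        ref = simulate(net, "steady", [(0.0, ExciseSource())], T=T, dt=0.15, output_every=64)
        errs = []
        for dt, every in ((2.4, 4), (1.2, 8)):
            res = simulate(net, "steady", [(0.0, ExciseSource())], T=T, dt=dt, output_every=every)
            errs.append(np.max(np.abs(res.psi_bar - ref.psi_bar)))
        ratio = errs[0] / errs[1]
        assert 1.5 < ratio < 3.0

    def test_fitted_excised_decay_constant_all_pairs(self):
        from conftest import EXCISED_PAIRS

        for C, Rc in EXCISED_PAIRS:
            leaf = ContinuousLeaf(R=2.0, Ra=50.0, psi0=0.0, psi_a=-100.0, Rc=Rc, C=C)
            tau = time_constant_excised(leaf)
            net = storage_chain(N=50, C=C, Rc=Rc)
            res = simulate(
                net, "steady", [(0.0, ExciseSource())], T=2.5 * tau, dt=0.6, output_every=50
            )
            tau_hat = fit_exponential(res.times, res.psi_bar, -100.0)
            assert tau_hat == pytest.approx(tau, rel=0.02)


class TestHumidityStepTimeConstants:
    @staticmethod
    def fitted_tau(C, Rc, psi_a_new, N=50):
        net = storage_chain(N=N, C=C, Rc=Rc)
        horizon = 2.5 * C * (Rc + 50.0)
        res = simulate(
            net, "steady", [(0.0, SetAtmosphere(psi_a_new))], T=horizon, dt=0.6, output_every=50
        )
        p = UniformLeafParams(N=N, R=2.0, Ra=50.0, psi0=0.0, psi_a=psi_a_new, Rc=Rc, C=C)
        final = solve_steady(build_uniform_chain(p))
        return fit_exponential(res.times, res.psi_bar, final.psi_bar)

    def test_up_and_down_steps_share_time_constant(self):
        tau_up = self.fitted_tau(60.0, 25.0, -50.0)
        tau_down = self.fitted_tau(60.0, 25.0, -150.0)
        assert tau_up == pytest.approx(tau_down, rel=0.01)

    def test_doubling_C_doubles_and_doubling_Rc_less_than_doubles(self):
        tau_base = self.fitted_tau(60.0, 25.0, -150.0)
        tau_2C = self.fitted_tau(120.0, 25.0, -150.0)
        tau_2Rc = self.fitted_tau(60.0, 50.0, -150.0)
        assert tau_2C == pytest.approx(2.0 * tau_base, rel=0.01)
        assert 1.0 < tau_2Rc / tau_base < 2.0


class TestExcisionAndWaveform:
    def test_excision_removes_all_sources_idempotently(self):
        net = storage_chain(N=10)
        cut = apply_excision(net)
        assert cut.sources == []
        with pytest.warns(UserWarning, match="no-op"):
            again = apply_excision(cut)
        assert again.sources == []

    def test_closed_system_conserves_stored_water(self):
        # excised with stomata closed: total capacitor charge is conserved
        net = storage_chain(N=20)
        net.nodes = [dataclasses.replace(n, Ra=math.inf) for n in net.nodes]
        net.psi_s = -110.0
        cut = apply_excision(net)
        init = derive_state(cut, np.linspace(0.0, -3.0, 20))
        res = simulate(cut, init, None, T=600.0, dt=0.3, output_every=200)
        totals = [float(np.sum(s.W)) for s in res.states]
        assert totals[-1] == pytest.approx(totals[0], rel=1e-8)

    def test_waveform_zero_amplitude_is_static(self):
        net = storage_chain(N=10)
        still = set_source_waveform(net, 0.0, 0.01)
        res = simulate(still, "steady", None, T=300.0, dt=0.6, output_every=100)
        assert np.max(np.abs(res.psi_bar - res.psi_bar[0])) < 1e-8

    def test_waveform_sets_long_run_frequency_and_attenuates_tipward(self):
        omega0 = 2.0 * math.pi / 600.0
        net = storage_chain(N=20, C=30.0, Rc=1.0)
        wavy = set_source_waveform(net, 5.0, omega0)
        res = simulate(wavy, "steady", None, T=3600.0, dt=0.5, output_every=4)
        M = res.psi_matrix()
        tail = res.times > 1800.0
        base = M[tail, 0] - M[tail, 0].mean()
        tip = M[tail, -1] - M[tail, -1].mean()
        crossings = np.where(np.diff(np.sign(base)))[0]
        period = 2.0 * np.mean(np.diff(res.times[tail][crossings]))
        assert period == pytest.approx(2.0 * math.pi / omega0, rel=0.02)
        assert np.ptp(tip) <= np.ptp(base)

    def test_waveform_requires_source(self):
        net = apply_excision(storage_chain(N=5))
        with pytest.raises(ValueError, match="no source"):
            set_source_waveform(net, 1.0, 0.1)

    def test_schedule_must_be_sorted(self):
        with pytest.raises(ValueError, match="sorted"):
            EventSchedule([(10.0, ExciseSource()), (0.0, SetAtmosphere(-50.0))])
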