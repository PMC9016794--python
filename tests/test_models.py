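"""Stand-in oscillator construction, calibration, coupling and forcing."""

import dataclasses
import math

import numpy as np
import pytest

import multisync as ms
from multisync.errors import ValidationError
from multisync.rhythm import classify_regime, estimate_period

from conftest import OMEGA_24, radial_basin_oracle


class TestNormalForm:
    @pytest.mark.parametrize("rho, expected_T", [
        (0.5, 2 * math.pi / (OMEGA_24 + 0.01 * 0.25)),
        (1.5, 2 * math.pi / (OMEGA_24 + 0.01 * 2.25)),
        (2.5, 2 * math.pi / (OMEGA_24 + 0.01 * 6.25)),
    ])
    def test_period_and_amplitude_match_closed_form(self, nf_tri, cfg, rho, expected_T):
        traj = ms.integrate(nf_tri, (rho, 0.0), 0.0, 400.0, cfg)
        est = estimate_period(traj, "x", discard=100.0)
        assert est.period_exact == pytest.approx(expected_T, rel=1e-3)
        x = traj["x"][traj.t >= 100.0]
        assert 0.5 * (x.max() - x.min()) == pytest.approx(rho, rel=1e-2)

    @pytest.mark.parametrize("r0", [0.15, 0.7, 1.2, 1.8, 2.2, 2.7])
    def test_attractor_selection_matches_radial_oracle(self, nf_tri, cfg, r0):
        """The attractor reached in 2-D agrees with 1-D radial sign analysis."""
        target = radial_basin_oracle((0.5, 1.0, 1.5, 2.0, 2.5), r0)
        traj = ms.integrate(nf_tri, (r0, 0.0), 0.0, 500.0, cfg)
        r = np.hypot(traj["x"], traj["y"])[traj.t >= 400.0]
        assert np.allclose(r, target, atol=5e-3)

    def test_basin_oracle_agrees_with_brute_force_radial_ode(self):
        """Cross-check the sign-analysis oracle against direct 1-D integration."""
        from scipy.integrate import solve_ivp

        radii = (0.5, 1.0, 1.5, 2.0, 2.5)

        def rdot(t, r):
            prod = 1.0
            for rho in radii:
                prod *= r[0] ** 2 - rho ** 2
            return [-0.01 * r[0] * prod]

        for r0 in (0.15, 0.7, 1.2, 1.8, 2.2, 2.7):
            sol = solve_ivp(rdot, (0, 3000), [r0], rtol=1e-9, atol=1e-12)
            assert sol.y[0, -1] == pytest.approx(
                radial_basin_oracle(radii, r0), abs=1e-3)

    def test_mid_basin_start_converges_to_enclosing_cycle(self, nf_tri, cfg):
        # r0 = 1.2 lies between the unstable radii 1.0 and 2.0
        traj = ms.integrate(nf_tri, (1.2, 0.0), 0.0, 500.0, cfg)
        r = np.hypot(traj["x"], traj["y"])[traj.t >= 400.0]
        assert np.allclose(r, 1.5, atol=5e-3)

    @pytest.mark.parametrize("kwargs", [
        {"radii": (1.0, 2.0)},                    # even count
        {"radii": (1.0, 1.0, 2.0)},               # not strictly increasing
        {"radii": (2.0, 1.0, 3.0)},               # decreasing
        {"radii": (1.0, 2.0, 3.0), "omega0": 0.0},
        {"radii": (1.0, 2.0, 3.0), "relax": -1.0},
    ])
    def test_invalid_construction_rejected(self, kwargs):
        kw = {"omega0": OMEGA_24, **kwargs}
        radii = kw.pop("radii")
        with pytest.raises(ValidationError):
            ms.make_normal_form(radii, **kw)


class TestGoodwinClock:
    def test_free_running_period_is_24h(self, clock_traj):
        est = estimate_period(clock_traj, "P", discard=400.0)
        assert est.period == pytest.approx(24.0, abs=0.1)
        assert classify_regime(clock_traj, 400.0, "P") == "periodic"

    def test_full_mitotic_repression_gives_steady_state(self, clock, cfg):
        clamped = dataclasses.replace(clock, input_ports={"mitotic_repression": 0.0})
        traj = ms.integrate(clamped, clock.default_state, 0.0, 800.0, cfg)
        assert classify_regime(traj, 500.0, "M") == "steady_state"
        assert traj["M"][-1] < 1e-3

    def test_doubling_tau_doubles_period(self, clock, cfg):
        slow = clock.with_time_scale(2.0 * clock.time_scale)
        traj = ms.integrate(slow, clock.default_state, 0.0, 1400.0, cfg)
        est = estimate_period(traj, "P", discard=800.0)
        assert est.period == pytest.approx(48.0, abs=0.2)

    def test_invalid_tau_rejected(self):
        with pytest.raises(ValidationError):
            ms.make_goodwin_clock(time_scale=-1.0)

    def test_ports_absent_equals_ports_at_neutral_default(self, clock):
        y = np.array([0.3, 0.5, 0.4])
        d_absent = clock.derivative(0.0, y)
        d_neutral = clock.derivative(0.0, y, {"mitotic_repression": 1.0})
        assert np.allclose(d_absent, d_neutral, rtol=0, atol=0)


class TestCdkCycle:
    def test_free_running_period_is_19_1h(self, cdk, cfg):
        traj = ms.integrate(cdk, cdk.default_state, 0.0, 700.0, cfg)
        est = estimate_period(traj, "A", discard=400.0)
        assert est.period == pytest.approx(19.1, abs=0.2)

    def test_saturating_wee1_drive_suppresses_oscillation(self, cdk, cfg):
        driven = dataclasses.replace(cdk, input_ports={"wee1_induction": 5.0})
        traj = ms.integrate(driven, cdk.default_state, 0.0, 1500.0, cfg)
        assert classify_regime(traj, 1200.0, "A") == "steady_state"

    def test_eps_scaling_scales_period(self, cdk, cfg):
        fast = cdk.with_time_scale(0.5 * cdk.time_scale)
        traj = ms.integrate(fast, cdk.default_state, 0.0, 400.0, cfg)
        est = estimate_period(traj, "A", discard=200.0)
        assert est.period == pytest.approx(19.1 / 2.0, abs=0.1)

    def test_invalid_eps_rejected(self):
        with pytest.raises(ValidationError):
            ms.make_cdk_cycle(eps=0.0)


class TestCoupling:
    def test_neutral_coupling_reproduces_uncoupled_runs(self, clock, cdk, cfg):
        spec = ms.CouplingSpec(v_sw=0.0, K_ICdk1=1e6, t_c=0.0)
        system = ms.make_coupled(clock, cdk, spec)
        traj = ms.integrate_with_onset(system, clock.default_state,
                                       cdk.default_state, 300.0, cfg)
        tc = ms.integrate(clock, clock.default_state, 0.0, 300.0, cfg)
        ty = ms.integrate(cdk, cdk.default_state, 0.0, 300.0, cfg)
        sep = np.hstack([tc.data, ty.data])
        # composed and separate integrations take different adaptive step
        # sequences; agreement is bounded by accumulated local error, a few
        # orders above rtol on the relaxation spikes
        assert np.allclose(traj.data, sep, rtol=1e-5, atol=5e-6)

    def test_repression_half_saturation_identity(self, clock, cdk):
        """R = 1/2 when the Cdk1 readout equals K_ICdk1, for any g_r."""
        for g_r in (1.0, 2.0, 4.0):
            spec = ms.CouplingSpec(v_sw=0.0, K_ICdk1=0.3, g_r=g_r)
            system = ms.make_coupled(clock, cdk, spec)
            y = np.array(list(clock.default_state) + [0.1, 0.3, 0.1, 0.1])
            d_active = system.derivative(0.0, y, active=True)
            d_half = clock.derivative(0.0, y[:3], {"mitotic_repression": 0.5})
            assert np.allclose(d_active[:3], d_half)

    def test_reference_coupling_point_echoed_in_manifest(self, clock, cdk):
        spec = ms.CouplingSpec(v_sw=2.3, K_ICdk1=0.65)
        system = ms.make_coupled(clock, cdk, spec)
        man = system.manifest()
        assert man["coupling"]["v_sw"] == 2.3
        assert man["coupling"]["K_ICdk1"] == 0.65

    def test_missing_port_rejected(self, clock, nf_bi):
        with pytest.raises(ValidationError):
            ms.make_coupled(clock, nf_bi, ms.CouplingSpec(v_sw=1.0, K_ICdk1=1.0))

    @pytest.mark.parametrize("kwargs", [
        {"v_sw": -1.0, "K_ICdk1": 1.0},
        {"v_sw": 1.0, "K_ICdk1": 0.0},
        {"v_sw": 1.0, "K_ICdk1": 1.0, "h_w": 0.5},
    ])
    def test_invalid_coupling_spec(self, kwargs):
        with pytest.raises(ValidationError):
            ms.CouplingSpec(**kwargs)


class TestForcing:
    def test_zero_amplitude_is_identity(self, clock, cfg):
        forced = ms.make_forced(clock, ms.ForcingSpec(
            target="v1", kind="sinusoid", period=24.0, amplitude=0.0))
        a = ms.integrate(forced, clock.default_state, 0.0, 200.0, cfg)
        b = ms.integrate(clock, clock.default_state, 0.0, 200.0, cfg)
        assert np.allclose(a.data[:, :3], b.data, rtol=1e-8, atol=1e-10)

    def test_square_wave_alternates_every_half_period(self, clock, cfg):
        forced = ms.make_forced(clock, ms.ForcingSpec(
            target="v1", kind="square", period=24.0, amplitude=0.2, duty=0.5))
        traj = ms.integrate(forced, clock.default_state, 0.0, 96.0, cfg)
        trace = traj["forcing"]
        t = traj.t
        high, low = 0.9, 0.5  # p0=0.7, amplitude 0.2, mean-preserving at duty 0.5
        assert np.allclose(trace[(t % 24.0) < 12.0 - 1e-9], high)
        assert np.allclose(trace[(t % 24.0) > 12.0 + 1e-9], low)
        # cycle-average preserved
        assert trace[(t >= 0) & (t < 24.0)].mean() == pytest.approx(0.7, abs=1e-2)

    def test_resonant_weak_forcing_locks_1_to_1(self, clock, cfg):
        forced = ms.make_forced(clock, ms.ForcingSpec(
            target="v1", kind="sinusoid", period=24.0, amplitude=0.1))
        traj = ms.integrate(forced, clock.default_state, 0.0, 900.0, cfg)
        res = ms.check_sync(traj, "P", "forcing", discard=600.0)
        assert res.locked and res.ratio == (1, 1)
        assert res.common_period == pytest.approx(24.0, abs=0.05)

    def test_overdriven_sinusoid_rejected_without_clip(self, clock):
        with pytest.raises(ValidationError):
            ms.make_forced(clock, ms.ForcingSpec(
                target="v1", kind="sinusoid", period=24.0, amplitude=1.5))

    def test_unknown_target_rejected(self, clock):
        with pytest.raises(ValidationError):
            ms.make_forced(clock, ms.ForcingSpec(
                target="nope", kind="sinusoid", period=24.0, amplitude=0.1))
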