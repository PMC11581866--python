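"""Tests for the adaptive resuscitation controller."""

import numpy as np
import pytest

from arcsim.arc import (
    ArcConfig,
    ArcController,
    ArcState,
    MAINTENANCE,
    compute_rate,
    estimate_responsiveness,
    filter_pressure,
    safety_update,
    volume_to_target,
)
from arcsim.autobleed import BloodBag, bag_update
from arcsim.protocol import ClosedLoopSim, ProtocolConfig
from arcsim.subject import CRYSTALLOID, WHOLE_BLOOD, VitalsSample, make_subject


class TestFilterPressure:
    def test_constant_input_identity(self):
        assert filter_pressure([50.0] * 5) == 50.0

    def test_single_artifact_rejected(self):
        assert filter_pressure([50, 50, 120, 50, 50]) == 50.0

    def test_empty_window_rejected(self):
        with pytest.raises(ValueError):
            filter_pressure([])

    def test_variance_reduction_under_noise(self):
        rng = np.random.default_rng(5)
        raw = 65.0 + 2.0 * rng.standard_normal(5000)
        filtered = [filter_pressure(raw[i : i + 10]) for i in range(len(raw) - 10)]
        assert np.std(filtered) < np.std(raw)


class TestEstimateResponsiveness:
    def test_exact_collinear_points(self):
        slope = estimate_responsiveness([0, 10, 20], [40, 40.5, 41])
        assert slope == pytest.approx(0.05)

    def test_matches_normal_equations_oracle(self):
        rng = np.random.default_rng(11)
        v = np.sort(rng.uniform(0, 500, 50))
        p = 40.0 + 0.03 * v + 0.5 * rng.standard_normal(50)
        # brute-force normal equations for y = a + b x
        x = np.column_stack([np.ones_like(v), v])
        beta = np.linalg.solve(x.T @ x, x.T @ p)
        assert estimate_responsiveness(v, p) == pytest.approx(beta[1], abs=1e-10)

    def test_single_point_returns_bootstrap(self):
        assert estimate_responsiveness([100.0], [50.0], fallback=0.03) == 0.03

    def test_small_volume_span_returns_bootstrap(self):
        slope = estimate_responsiveness([0.0, 2.0], [40.0, 60.0], fallback=0.03)
        assert slope == 0.03


class TestVolumeToTarget:
    def test_at_target_zero(self):
        assert volume_to_target(65.0, 65.0, 0.03) == 0.0

    def test_closed_form(self):
        assert volume_to_target(35.0, 65.0, 0.03) == pytest.approx(1000.0)

    def test_above_target_floored(self):
        assert volume_to_target(70.0, 65.0, 0.03) == 0.0

    def test_nonpositive_slope_rejected(self):
        with pytest.raises(ValueError):
            volume_to_target(35.0, 65.0, 0.0)


class TestComputeRate:
    def test_rate_law(self):
        cfg = ArcConfig()
        assert compute_rate(0.2, 35.0, 65.0, cfg) == pytest.approx(30.0)

    def test_floor_slope_clamps_to_qmax(self):
        cfg = ArcConfig()
        assert compute_rate(cfg.slope_floor, 35.0, 65.0, cfg) == cfg.q_max

    def test_deadband_silences_near_target(self):
        cfg = ArcConfig()
        assert compute_rate(0.03, 65.0, 65.0, cfg) == 0.0
        assert compute_rate(0.03, 63.0, 65.0, cfg) == 0.0
        assert compute_rate(0.03, 62.9, 65.0, cfg) > 0.0

    def test_remaining_volume_cap_shrinks_final_approach(self):
        cfg = ArcConfig()
        # 0.75 mmHg deficit: full pace would need 200 mL/min, the cap limits
        # the tick to the estimated remaining volume plus the margin
        rate = compute_rate(0.03, 64.25, 65.0, cfg, deadband=0.0)
        expected = (0.75 + cfg.overshoot_margin) / 0.03 / (cfg.control_interval / 60.0)
        assert rate == pytest.approx(expected)


class TestSafetyUpdate:
    def make_state(self, target=65.0, baseline=62.0):
        return ArcState(active_target=target, baseline_map_reference=baseline)

    def test_below_threshold_no_change(self):
        cfg = ArcConfig()
        st = self.make_state()
        safety_update(14.9, st, cfg, now=0.0)
        assert st.active_target == 65.0 and not st.safety_engaged

    def test_first_crossing_reduces_to_baseline(self):
        cfg = ArcConfig()
        st = self.make_state(baseline=62.0)
        safety_update(15.0, st, cfg, now=0.0)
        assert st.safety_engaged and st.active_target == 62.0

    def test_iterative_two_mmhg_reductions(self):
        cfg = ArcConfig()
        st = self.make_state(baseline=62.0)
        for now, expected in [(0.0, 62.0), (1.0, 62.0), (5.0, 60.0), (10.0, 58.0)]:
            safety_update(15.0, st, cfg, now=now)
            assert st.active_target == expected

    def test_immediate_decrement_when_already_at_baseline(self):
        cfg = ArcConfig()
        st = self.make_state(baseline=65.0)
        safety_update(15.0, st, cfg, now=0.0)
        assert st.active_target == 63.0

    def test_hard_floor(self):
        cfg = ArcConfig()
        st = self.make_state(baseline=42.0)
        for k in range(20):
            safety_update(18.0, st, cfg, now=5.0 * k)
        assert st.active_target == cfg.target_floor

    def test_monotone_while_engaged(self):
        cfg = ArcConfig()
        st = self.make_state()
        rng = np.random.default_rng(2)
        targets = []
        for k in range(200):
            safety_update(float(rng.uniform(10, 20)), st, cfg, now=0.5 * k)
            if st.safety_engaged:
                targets.append(st.active_target)
        assert all(a >= b for a, b in zip(targets, targets[1:]))


def _wb_session(params, cfg):
    """Hemorrhage to 35 mmHg, then one complete whole-blood ARC event."""
    from arcsim.protocol import run_arc_session

    trace, controller, event = run_arc_session(params, cfg, fluid=WHOLE_BLOOD)
    return trace, controller, event


class TestArcClosedLoop:
    def test_out_of_order_tick_rejected(self):
        controller = ArcController(ArcConfig())
        sample = VitalsSample(map=50.0, cvp=5.0)
        controller.tick(1.0, sample, 0.0)
        with pytest.raises(ValueError):
            controller.tick(0.5, sample, 0.0)

    def test_steady_state_commands_zero_at_target(self):
        params = make_subject({"noise_sd": 0.0})
        cfg = ArcConfig()
        sim = ClosedLoopSim(params, seed=0)  # subject already at 65 = target
        controller = ArcController(cfg, fluid=CRYSTALLOID, baseline_map_reference=65.0)
        event = sim.run_arc_event(controller, None, "steady")
        rates = [row[4] for row in controller.log]
        assert max(rates) == 0.0
        assert event.attained_time is not None

    def test_commands_within_pump_bounds_and_never_withdraw(self, protocol_result):
        for log in protocol_result.arc_logs.values():
            rates = log["commanded_rate_mL_min"]
            assert (rates >= 0.0).all()
            assert (rates <= ArcConfig().q_max).all()

    def test_rise_tracks_pace_on_linear_subject(self):
        """Noise-free linear subject: closed-loop MAP rise slope within 10%
        of the configured 6 mmHg/min pace, and the hold settles on target."""
        params = make_subject({"noise_sd": 0.0})
        cfg = ArcConfig()
        trace, controller, event = _wb_session(params, cfg)
        rise = trace[
            (trace.time_min >= event.start)
            & (trace.time_min <= controller.state.attained_time)
        ]
        slope = np.polyfit(rise.time_min, rise.map_mmHg, 1)[0]
        assert slope == pytest.approx(cfg.pace, rel=0.10)
        hold = trace[trace.time_min >= controller.state.attained_time]
        assert abs(hold.map_mmHg - cfg.target_map).max() < 2.0

    def test_settled_map_has_negligible_wobble(self):
        from arcsim.metrics import performance_error, varvel_metrics

        params = make_subject({"noise_sd": 0.0})
        trace, controller, event = _wb_session(params, ArcConfig())
        hold = trace[trace.time_min >= controller.state.attained_time]
        _, _, wobble = varvel_metrics(
            performance_error(hold.map_mmHg, hold.target_mmHg)
        )
        assert wobble < 2.0

    def test_fluid_switch_exactly_after_stabilization(self):
        params = make_subject({"noise_sd": 0.0})
        cfg = ArcConfig()
        trace, controller, event = _wb_session(params, cfg)
        log = controller.log
        attained = controller.state.attained_time
        switches = [
            row for row, prev in zip(log[1:], log)
            if row[5] == CRYSTALLOID and prev[5] == WHOLE_BLOOD
        ]
        assert len(switches) == 1
        assert switches[0][0] == pytest.approx(
            attained + cfg.stabilization_duration, abs=cfg.control_interval / 60.0
        )
        assert switches[0][1] == MAINTENANCE

    def test_responsiveness_recovery_under_noise(self):
        """Windowed slope estimate within 15% of truth in >=90% of active
        full-window control ticks, noise sd 2 mmHg, slopes across the
        responsive range."""
        for s in (0.01, 0.03, 0.1):
            params = make_subject({"noise_sd": 2.0, "wb_slope": s}, seed=7)
            pconfig = ProtocolConfig(max_rise_duration=15.0)
            sim = ClosedLoopSim(params, seed=11, config=pconfig)
            bag = bag_update(
                BloodBag(), withdrawn=6000.0, subject_hct=0.3, cpda=6000.0 / 7
            )
            cfg = ArcConfig(target_map=500.0, cvp_threshold=1e9)
            controller = ArcController(cfg, fluid=WHOLE_BLOOD, baseline_map_reference=65.0)
            sim.run_arc_event(controller, bag, "probe")
            log = np.array(
                [(row[0], row[3]) for row in controller.log if row[4] > 0.0]
            )
            window_min = cfg.regression_window / 60.0
            full = log[log[:, 0] >= log[0, 0] + window_min]
            assert len(full) >= 50
            frac = np.mean(np.abs(full[:, 1] - s) <= 0.15 * s)
            assert frac >= 0.90
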