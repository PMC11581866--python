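"""Unit and property tests for the synthetic hemodynamic model."""

import dataclasses
import math

import numpy as np
import pytest

from arcsim.subject import (
    CRYSTALLOID,
    WHOLE_BLOOD,
    PumpCommand,
    SubjectParams,
    crystalloid_retention,
    initial_state,
    make_subject,
    map_from_volume,
    rng_from_seed,
    sample_vitals,
    step,
)

DT = 1.0 / 60.0


class TestMakeSubject:
    def test_deterministic_under_fixed_seed(self):
        a = make_subject({}, seed=1, jitter=0.1)
        b = make_subject({}, seed=1, jitter=0.1)
        assert a == b

    def test_jitter_varies_with_seed(self):
        a = make_subject({}, seed=1, jitter=0.1)
        b = make_subject({}, seed=2, jitter=0.1)
        assert a != b

    @pytest.mark.parametrize(
        "anesthetic,rate", [("ketamine", 4.95), ("isoflurane", 2.49)]
    )
    def test_anesthetic_strata_set_lactate_rate(self, anesthetic, rate):
        params = make_subject({"anesthetic": anesthetic})
        assert params.lactate_accum_rate == rate

    def test_unknown_override_rejected_by_name(self):
        with pytest.raises(ValueError, match="wb_sloppe"):
            make_subject({"wb_sloppe": 0.1})

    def test_explicit_lactate_override_beats_stratum(self):
        params = make_subject({"anesthetic": "ketamine", "lactate_accum_rate": 3.0})
        assert params.lactate_accum_rate == 3.0

    def test_invalid_defaults_rejected(self):
        with pytest.raises(ValueError):
            make_subject({"baseline_hct": 1.5})
        with pytest.raises(ValueError):
            make_subject({"anesthetic": "ether"})


class TestMapVolumeLaw:
    def test_reference_volume_gives_baseline(self, quiet_subject):
        v0 = quiet_subject.reference_volume
        assert map_from_volume(quiet_subject, v0) == quiet_subject.baseline_map

    def test_one_litre_bleed_spans_baseline_to_shock_target(self, quiet_subject):
        v0 = quiet_subject.reference_volume
        assert map_from_volume(quiet_subject, v0 - 1000.0) == pytest.approx(35.0)

    def test_floored_at_zero(self, quiet_subject):
        assert map_from_volume(quiet_subject, 1e-6) == 0.0

    def test_nonpositive_volume_rejected(self, quiet_subject):
        with pytest.raises(ValueError):
            map_from_volume(quiet_subject, 0.0)


class TestCrystalloidRetention:
    @pytest.mark.parametrize(
        "map_mmHg,expected", [(45.0, 0.80), (65.0, 0.25), (55.0, 0.525), (20.0, 0.80), (90.0, 0.25)]
    )
    def test_knee_and_interpolation(self, quiet_subject, expected, map_mmHg):
        assert crystalloid_retention(quiet_subject, map_mmHg) == pytest.approx(expected)

    def test_monotone_non_increasing(self, quiet_subject):
        maps = np.linspace(0.0, 100.0, 201)
        vals = [crystalloid_retention(quiet_subject, m) for m in maps]
        assert all(a >= b for a, b in zip(vals, vals[1:]))


class TestStep:
    def test_equilibrium_at_rest(self, quiet_subject):
        state = initial_state(quiet_subject)
        out = step(quiet_subject, state, PumpCommand(0.0), DT)
        assert out.time == pytest.approx(state.time + DT)
        for name in ("intravascular_volume", "map", "cvp", "lactate", "hct"):
            assert getattr(out, name) == pytest.approx(getattr(state, name))

    def test_withdrawal_preserves_hematocrit(self, quiet_subject):
        state = initial_state(quiet_subject)
        for _ in range(600):
            state = step(quiet_subject, state, PumpCommand(-60.0), DT)
        assert state.hct == pytest.approx(quiet_subject.baseline_hct, abs=1e-12)

    def test_crystalloid_dilutes_hematocrit_monotonically(self, quiet_subject):
        state = initial_state(quiet_subject)
        hcts = []
        for _ in range(600):
            state = step(quiet_subject, state, PumpCommand(60.0, CRYSTALLOID), DT)
            hcts.append(state.hct)
        assert all(a >= b for a, b in zip(hcts, hcts[1:]))
        assert hcts[-1] < quiet_subject.baseline_hct

    def test_hct_equals_rbc_over_volume(self, quiet_subject):
        state = initial_state(quiet_subject)
        for _ in range(100):
            state = step(quiet_subject, state, PumpCommand(40.0, CRYSTALLOID), DT)
        assert state.hct == pytest.approx(
            state.rbc_volume / state.intravascular_volume, abs=1e-9
        )

    def test_lactate_nondecreasing_during_untreated_shock(self, quiet_subject):
        state = initial_state(quiet_subject)
        # hemorrhage below the ischemia threshold, then observe without commands
        while state.map > 35.0:
            state = step(quiet_subject, state, PumpCommand(-100.0), DT)
        lactates = []
        for _ in range(1200):
            state = step(quiet_subject, state, PumpCommand(0.0), DT)
            lactates.append(state.lactate)
        assert all(b >= a for a, b in zip(lactates, lactates[1:]))
        assert lactates[-1] > lactates[0]

    def test_lactate_clearance_lags_and_floors_at_baseline(self):
        params = make_subject({"noise_sd": 0.0, "clearance_lag": 5.0})
        state = initial_state(params)
        state = dataclasses.replace(state, lactate=5.0)
        # at baseline MAP (>= clearance threshold) nothing happens until the lag
        for _ in range(int(4.0 / DT)):
            state = step(params, state, PumpCommand(0.0), DT)
        assert state.lactate == pytest.approx(5.0)
        for _ in range(int(300.0 / DT)):
            state = step(params, state, PumpCommand(0.0), DT)
        assert state.lactate == pytest.approx(params.baseline_lactate)

    def test_wholeblood_linearity(self, quiet_subject):
        """(cumulative WB volume, MAP) pairs fall exactly on the wb_slope line."""
        state = initial_state(quiet_subject)
        vols, maps = [], []
        cum = 0.0
        for _ in range(600):
            state = step(quiet_subject, state, PumpCommand(50.0, WHOLE_BLOOD, 0.3), DT)
            cum += 50.0 * DT
            vols.append(cum)
            maps.append(state.map)
        coeffs = np.polyfit(vols, maps, 1)
        pred = np.polyval(coeffs, vols)
        ss_res = np.sum((np.array(maps) - pred) ** 2)
        ss_tot = np.sum((np.array(maps) - np.mean(maps)) ** 2)
        assert coeffs[0] == pytest.approx(quiet_subject.wb_slope, rel=1e-9)
        assert 1.0 - ss_res / ss_tot == pytest.approx(1.0, abs=1e-12)

    def test_crystalloid_equilibrates_below_wholeblood(self, quiet_subject):
        """Same infused volume: crystalloid MAP strictly below whole-blood MAP."""
        wb = initial_state(quiet_subject)
        cr = initial_state(quiet_subject)
        for _ in range(3600):
            wb = step(quiet_subject, wb, PumpCommand(20.0, WHOLE_BLOOD, 0.3), DT)
            cr = step(quiet_subject, cr, PumpCommand(20.0, CRYSTALLOID), DT)
        assert cr.map < wb.map

    def test_exhausted_volume_flags_death(self, quiet_subject):
        state = initial_state(quiet_subject)
        for _ in range(20000):
            state = step(quiet_subject, state, PumpCommand(-250.0), DT)
            if not state.alive:
                break
        assert not state.alive

    def test_volume_conservation_against_independent_integration(self, quiet_subject):
        """Audit counters reproduce an hour of random commands integrated
        independently (withdrawals and whole blood at face value, crystalloid
        through the public retention curve at the pre-step MAP)."""
        rng = rng_from_seed(42)
        state = initial_state(quiet_subject)
        oracle_in = oracle_out = 0.0
        for _ in range(3600):
            u = rng.uniform()
            if u < 0.3:
                cmd = PumpCommand(-float(rng.uniform(0, 60)))
            elif u < 0.6:
                cmd = PumpCommand(float(rng.uniform(0, 100)), WHOLE_BLOOD, 0.25)
            elif u < 0.9:
                cmd = PumpCommand(float(rng.uniform(0, 100)), CRYSTALLOID)
            else:
                cmd = PumpCommand(0.0)
            map_before = state.map
            state = step(quiet_subject, state, cmd, DT)
            if cmd.rate < 0:
                oracle_out += -cmd.rate * DT
            elif cmd.rate > 0 and cmd.fluid == WHOLE_BLOOD:
                oracle_in += cmd.rate * DT
            elif cmd.rate > 0:
                oracle_in += crystalloid_retention(quiet_subject, map_before) * cmd.rate * DT
        assert state.cum_withdrawn == pytest.approx(oracle_out, abs=1e-6)
        assert state.cum_retained_infused == pytest.approx(oracle_in, abs=1e-6)
        net = state.intravascular_volume - quiet_subject.reference_volume
        assert (
            state.cum_retained_infused - state.cum_withdrawn - state.cum_leaked
            == pytest.approx(net, abs=1e-6)
        )


class TestPumpCommand:
    def test_crystalloid_withdrawal_rejected(self):
        with pytest.raises(ValueError):
            PumpCommand(-10.0, CRYSTALLOID)

    def test_pump_maximum_enforced(self):
        with pytest.raises(ValueError):
            PumpCommand(400.0)


class TestSampleVitals:
    def test_zero_noise_is_identity(self, quiet_subject):
        state = initial_state(quiet_subject)
        s = sample_vitals(state, quiet_subject, rng_from_seed(0))
        assert s.map == state.map and s.cvp == state.cvp

    def test_noise_mean_obeys_clt_bound(self):
        params = make_subject({"noise_sd": 2.0})
        state = initial_state(params)
        rng = rng_from_seed(3)
        n = 10_000
        maps = [sample_vitals(state, params, rng).map for _ in range(n)]
        assert abs(np.mean(maps) - state.map) < 3 * 2.0 / math.sqrt(n)

    def test_lactate_only_on_scheduled_draws(self, quiet_subject):
        state = initial_state(quiet_subject)
        rng = rng_from_seed(0)
        assert sample_vitals(state, quiet_subject, rng).lactate is None
        drawn = sample_vitals(state, quiet_subject, rng, include_lactate=True)
        assert drawn.lactate == state.lactate
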