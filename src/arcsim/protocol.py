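"""Protocol orchestration: the full two-event hemorrhage/resuscitation study.

Per subject the timeline is:

1. 30-min baseline stabilization (no fluid commands);
2. AutoBleed-controlled hemorrhage to the hypotensive target (35 mmHg),
   then a hypovolemic hold with lactate drawn every 10 min until the
   shock criterion fires (lactate >= 4 mmol/L or 90 min, whichever first);
3. ARC whole-blood resuscitation from the blood bag to 65 mmHg, 10-min
   stabilization, then 120-min crystalloid maintenance;
4. a second hemorrhage and a hold matched to the realized first-hold
   duration (shortened if lactate reaches 6 mmol/L);
5. ARC crystalloid-only resuscitation and a second 120-min maintenance.

The module also exposes smaller closed-loop sessions (a pure AutoBleed
hold, a single ARC event from a hemorrhaged state) reused by the tests and
the reproduction script, and a cohort driver aggregating per-subject
lactate-accumulation slopes and event metrics.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .arc import MAINTENANCE, RESUSCITATION, ArcConfig, ArcController
from .autobleed import AutoBleedConfig, AutoBleedController, BloodBag, bag_update
from .metrics import MetricsReport, compute_report
from .subject import (
    CRYSTALLOID,
    WHOLE_BLOOD,
    PumpCommand,
    SubjectParams,
    initial_state,
    make_subject,
    rng_from_seed,
    sample_vitals,
    step,
)

PHASE_ORDER = (
    "baseline",
    "hemorrhage1",
    "hold1",
    "event1",
    "hemorrhage2",
    "hold2",
    "event2",
)

TRACE_COLUMNS = (
    "time_min",
    "map_mmHg",
    "cvp_mmHg",
    "lactate_mmol_L",
    "hct_frac",
    "infusion_mL_min",
    "fluid",
    "bag_volume_mL",
    "target_mmHg",
    "phase",
)


@dataclass
class ProtocolConfig:
    """Study-timeline settings (all times minutes, lactate mmol/L)."""

    hold_lactate_threshold_1: float = 4.0
    hold_max_duration: float = 90.0
    hold_lactate_cap_2: float = 6.0
    lactate_sampling_interval: float = 10.0
    maintenance_lactate_interval: float = 60.0
    baseline_duration: float = 30.0
    target_met_band: float = 2.0        # mmHg band defining "target met" for the hold
    max_hemorrhage_duration: float = 120.0
    max_rise_duration: float = 120.0
    dt: float = 1.0 / 60.0              # min; one vitals sample per step

    def __post_init__(self) -> None:
        if self.hold_lactate_threshold_1 <= 0 or self.hold_lactate_cap_2 <= 0:
            raise ValueError("lactate thresholds must be positive")
        if self.hold_lactate_cap_2 <= self.hold_lactate_threshold_1:
            raise ValueError("second-event lactate cap must exceed the first threshold")
        if self.dt <= 0 or self.dt > 1.0 / 60.0 + 1e-12:
            raise ValueError("dt must be positive and at most one second")
        if self.lactate_sampling_interval <= 0:
            raise ValueError("lactate_sampling_interval must be positive")


@dataclass
class HoldResult:
    start: float
    end: float
    duration: float
    readings: list          # (time_min, lactate) pairs
    reason: str             # "lactate" | "timeout" | "matched" | "cap" | "death"


@dataclass
class EventResult:
    start: float
    end: float
    attained_time: float | None
    target_reached: bool
    safety_engaged: bool
    infused_volume: dict    # fluid -> mL commanded into the subject


@dataclass
class ProtocolResult:
    """Everything one protocol run produces."""

    trace: pd.DataFrame                 # full 1-Hz multichannel log, phase-labelled
    boundaries: dict                    # phase -> (start_min, end_min)
    hold1: HoldResult | None
    hold2: HoldResult | None
    hold2_planned_duration: float | None
    events: dict                        # "event1"/"event2" -> EventResult
    reports: dict                       # "event1"/"event2" -> MetricsReport
    arc_logs: dict                      # event -> DataFrame of controller decisions
    autobleed_logs: dict                # event -> DataFrame
    final_state: object
    flags: dict                         # alive / target_reached_* / safety_engaged_*
    params: SubjectParams
    seed: int

    def phase_trace(self, phase: str) -> pd.DataFrame:
        return self.trace[self.trace["phase"] == phase].reset_index(drop=True)

    @property
    def hold1_lactate_slope(self) -> float:
        """Hold-1 lactate accumulation slope (mmol/L/hr) by OLS on the draws."""
        return lactate_slope(self.hold1.readings) if self.hold1 else math.nan


def lactate_slope(readings) -> float:
    """OLS slope of lactate (mmol/L) against draw time, converted to per hour."""
    if len(readings) < 2:
        return math.nan
    t = np.array([r[0] for r in readings], dtype=float)
    v = np.array([r[1] for r in readings], dtype=float)
    return float(np.polyfit(t, v, 1)[0] * 60.0)


def shock_criterion(
    readings,
    threshold: float,
    max_duration: float,
    hold_start: float,
    now: float | None = None,
) -> tuple[bool, str | None, float | None]:
    """First-passage shock rule: lactate at/above threshold, or hold timeout.

    ``readings`` are (time, lactate) pairs on the sampling cadence.
    Returns (met, reason, time); reason is ``"lactate"`` or ``"timeout"``.
    """
    for t, value in readings:
        if value >= threshold:
            return True, "lactate", float(t)
    latest = now if now is not None else (readings[-1][0] if readings else hold_start)
    if latest - hold_start >= max_duration:
        return True, "timeout", float(hold_start + max_duration)
    return False, None, None


class ClosedLoopSim:
    """1-Hz closed-loop engine joining subject model, controllers and logging."""

    def __init__(
        self,
        params: SubjectParams,
        seed: int = 0,
        config: ProtocolConfig | None = None,
        state=None,
    ):
        self.params = params
        self.pconfig = config or ProtocolConfig()
        self.rng = rng_from_seed(seed)
        self.state = state if state is not None else initial_state(params)
        self.dt = self.pconfig.dt
        self.rows: list[tuple] = []
        self.boundaries: dict[str, tuple[float, float]] = {}

    # -- internals ---------------------------------------------------------

    @property
    def now(self) -> float:
        return self.state.time

    def _record(self, phase, sample, rate, fluid, bag, target, lactate=math.nan):
        self.rows.append(
            (
                self.state.time,
                sample.map,
                sample.cvp,
                lactate,
                self.state.hct,
                rate,
                fluid,
                bag.total_volume if bag is not None else math.nan,
                target,
                phase,
            )
        )

    def _mark(self, phase: str, start: float) -> None:
        self.boundaries[phase] = (start, self.now)

    def trace(self) -> pd.DataFrame:
        return pd.DataFrame(self.rows, columns=list(TRACE_COLUMNS))

    # -- phases ------------------------------------------------------------

    def run_idle(self, duration: float, phase: str = "baseline") -> None:
        """Advance with no fluid commands (baseline stabilization)."""
        start = self.now
        idle = PumpCommand(0.0, WHOLE_BLOOD)
        n = int(round(duration / self.dt))
        for _ in range(n):
            self.state = step(self.params, self.state, idle, self.dt)
            sample = sample_vitals(self.state, self.params, self.rng)
            self._record(phase, sample, 0.0, WHOLE_BLOOD, None, math.nan)
        self._mark(phase, start)

    def run_autobleed(
        self,
        controller: AutoBleedController,
        bag: BloodBag,
        phase: str,
        stop,
        lactate_times=None,
        readings=None,
        max_duration: float = math.inf,
    ) -> BloodBag:
        """Run AutoBleed until ``stop(elapsed, readings)`` or ``max_duration``.

        ``lactate_times`` is an iterator of absolute draw times; draws are
        appended to ``readings`` and logged in the trace's sparse lactate
        column.
        """
        start = self.now
        cfg = controller.config
        ticks_per = max(1, int(round(cfg.control_interval / (self.dt * 60.0))))
        next_draw = next(lactate_times, None) if lactate_times is not None else None
        command = PumpCommand(0.0, WHOLE_BLOOD)
        i = 0
        while self.now - start < max_duration - self.dt / 2:
            sample = sample_vitals(self.state, self.params, self.rng)
            controller.observe(self.now, sample.map)
            if i % ticks_per == 0:
                command, _ = controller.tick(self.now, bag)
            hct_before = self.state.hct
            vol = command.rate * self.dt
            if vol > 0:
                available = bag.total_volume
                vol = min(vol, available)
                eff = PumpCommand(vol / self.dt, WHOLE_BLOOD, source_hct=bag.hct)
            else:
                eff = command
            self.state = step(self.params, self.state, eff, self.dt)
            if vol < 0:
                w = -vol
                bag = bag_update(
                    bag, withdrawn=w, subject_hct=hct_before, cpda=w / cfg.cpda_ratio
                )
            elif vol > 0:
                bag = bag_update(bag, reinfused=vol)
            lactate_val = math.nan
            if next_draw is not None and self.now >= next_draw - self.dt / 2:
                lactate_val = self.state.lactate
                if readings is not None:
                    readings.append((self.now, lactate_val))
                next_draw = next(lactate_times, None)
            self._record(phase, sample, eff.rate, WHOLE_BLOOD, bag, cfg.target_map, lactate_val)
            if not self.state.alive:
                break
            if stop is not None and stop(self.now - start, readings):
                break
            i += 1
        self._mark(phase, start)
        return bag

    def run_arc_event(
        self,
        controller: ArcController,
        bag: BloodBag | None,
        phase: str,
    ) -> EventResult:
        """One full ARC event: rise, stabilization, maintenance.

        Whole blood is drawn from ``bag`` (rate-limited by its content);
        crystalloid comes from an unlimited stock.  The event ends when the
        maintenance window completes, the subject dies, or the rise exceeds
        the protocol's cap without attainment.
        """
        start = self.now
        cfg = controller.config
        ticks_per = max(1, int(round(cfg.control_interval / (self.dt * 60.0))))
        command = PumpCommand(0.0, controller.state.fluid)
        infused = {WHOLE_BLOOD: 0.0, CRYSTALLOID: 0.0}
        cum_volume = 0.0
        maintenance_deadline = math.inf
        next_draw = math.inf
        i = 0
        while True:
            sample = sample_vitals(self.state, self.params, self.rng)
            if i % ticks_per == 0:
                command = controller.tick(self.now, sample, cum_volume)
                if controller.state.phase == MAINTENANCE and math.isinf(
                    maintenance_deadline
                ):
                    maintenance_deadline = (
                        controller.maintenance_start + cfg.maintenance_duration
                    )
                    next_draw = self.now  # first maintenance draw right away
            else:
                controller.observe(self.now, sample.map, cum_volume)
            vol = command.rate * self.dt
            fluid = command.fluid
            if fluid == WHOLE_BLOOD and vol > 0:
                if bag is None:
                    raise ValueError("whole-blood event requires a blood bag")
                vol = min(vol, bag.total_volume)
                eff = PumpCommand(vol / self.dt, WHOLE_BLOOD, source_hct=bag.hct)
            elif vol > 0:
                eff = PumpCommand(vol / self.dt, CRYSTALLOID)
            else:
                eff = PumpCommand(0.0, fluid)
            self.state = step(self.params, self.state, eff, self.dt)
            if vol > 0:
                infused[fluid] += vol
                cum_volume += vol
                if fluid == WHOLE_BLOOD:
                    bag = bag_update(bag, reinfused=vol)
            lactate_val = math.nan
            if self.now >= next_draw - self.dt / 2:
                lactate_val = self.state.lactate
                next_draw = self.now + self.pconfig.maintenance_lactate_interval
            self._record(
                phase,
                sample,
                eff.rate,
                fluid,
                bag,
                controller.state.active_target,
                lactate_val,
            )
            if not self.state.alive:
                break
            if self.now >= maintenance_deadline - self.dt / 2:
                break
            if (
                controller.state.phase == RESUSCITATION
                and self.now - start > self.pconfig.max_rise_duration
            ):
                break
            i += 1
        self._mark(phase, start)
        return EventResult(
            start=start,
            end=self.now,
            attained_time=controller.state.attained_time,
            target_reached=controller.state.attained_time is not None,
            safety_engaged=controller.state.safety_engaged,
            infused_volume=infused,
        )


def _draw_times(start: float, interval: float):
    k = 0
    while True:
        yield start + k * interval
        k += 1


def hemorrhage_to_target(
    sim: ClosedLoopSim,
    ab_config: AutoBleedConfig,
    bag: BloodBag,
    phase: str,
) -> tuple[AutoBleedController, BloodBag]:
    """Run AutoBleed from the current state until the hypotensive target is met.

    "Met" means the filtered MAP enters the protocol's target band
    (default +/-2 mmHg around the AutoBleed target).
    """
    controller = AutoBleedController(ab_config)
    band = sim.pconfig.target_met_band

    def stop(elapsed, readings):
        if not controller.log:
            return False
        filtered = controller.log[-1][1]
        return abs(filtered - ab_config.target_map) <= band

    bag = sim.run_autobleed(
        controller,
        bag,
        phase,
        stop,
        max_duration=sim.pconfig.max_hemorrhage_duration,
    )
    return controller, bag


def run_protocol(
    params: SubjectParams | None = None,
    arc_config: ArcConfig | None = None,
    autobleed_config: AutoBleedConfig | None = None,
    protocol_config: ProtocolConfig | None = None,
    seed: int = 0,
) -> ProtocolResult:
    """Execute the full two-event study timeline for one subject."""
    params = params if params is not None else make_subject()
    arc_config = arc_config or ArcConfig()
    ab_config = autobleed_config or AutoBleedConfig()
    pconfig = protocol_config or ProtocolConfig()

    sim = ClosedLoopSim(params, seed=seed, config=pconfig)
    flags = {}
    events: dict[str, EventResult] = {}
    reports: dict[str, MetricsReport] = {}
    arc_logs: dict[str, pd.DataFrame] = {}
    ab_logs: dict[str, pd.DataFrame] = {}
    hold1 = hold2 = None
    hold2_planned = None

    # 1. baseline
    sim.run_idle(pconfig.baseline_duration, "baseline")
    base_rows = [r for r in sim.rows if r[9] == "baseline"]
    baseline_ref = float(np.mean([r[1] for r in base_rows[-300:]]))

    def run_hold(controller, bag, phase, threshold, max_duration, cap):
        readings: list = []
        hold_start = sim.now
        draws = _draw_times(hold_start, pconfig.lactate_sampling_interval)

        def stop(elapsed, rds):
            if cap is not None and rds and rds[-1][1] >= cap:
                return True
            if cap is None:
                met, _, _ = shock_criterion(
                    rds or [], threshold, max_duration, hold_start, now=sim.now
                )
                return met
            return elapsed >= max_duration - sim.dt / 2

        bag = sim.run_autobleed(
            controller,
            bag,
            phase,
            stop,
            lactate_times=draws,
            readings=readings,
            max_duration=max_duration + pconfig.lactate_sampling_interval,
        )
        end = sim.now
        if cap is not None:
            reason = "cap" if (readings and readings[-1][1] >= cap) else "matched"
        else:
            met, why, _ = shock_criterion(
                readings, threshold, max_duration, hold_start, now=end
            )
            reason = why or "timeout"
        if not sim.state.alive:
            reason = "death"
        return (
            HoldResult(hold_start, end, end - hold_start, readings, reason),
            bag,
        )

    alive = True
    # 2. first hemorrhage + hold
    bag1 = BloodBag()
    ab1, bag1 = hemorrhage_to_target(sim, ab_config, bag1, "hemorrhage1")
    alive = sim.state.alive
    if alive:
        hold1, bag1 = run_hold(
            ab1,
            bag1,
            "hold1",
            pconfig.hold_lactate_threshold_1,
            pconfig.hold_max_duration,
            cap=None,
        )
        ab_logs["event1"] = pd.DataFrame(
            ab1.log, columns=list(AutoBleedController.LOG_COLUMNS)
        )
        alive = sim.state.alive and hold1.reason != "death"

    # 3. first resuscitation: whole blood from the bag
    if alive:
        arc1 = ArcController(
            arc_config, fluid=WHOLE_BLOOD, baseline_map_reference=baseline_ref
        )
        events["event1"] = sim.run_arc_event(arc1, bag1, "event1")
        arc_logs["event1"] = pd.DataFrame(
            arc1.log, columns=list(ArcController.LOG_COLUMNS)
        )
        alive = sim.state.alive

    # 4. second hemorrhage + matched hold
    if alive:
        bag2 = BloodBag()
        ab2, bag2 = hemorrhage_to_target(sim, ab_config, bag2, "hemorrhage2")
        alive = sim.state.alive
        if alive:
            hold2_planned = hold1.duration
            hold2, bag2 = run_hold(
                ab2,
                bag2,
                "hold2",
                pconfig.hold_lactate_threshold_1,
                hold2_planned,
                cap=pconfig.hold_lactate_cap_2,
            )
            ab_logs["event2"] = pd.DataFrame(
                ab2.log, columns=list(AutoBleedController.LOG_COLUMNS)
            )
            alive = sim.state.alive and hold2.reason != "death"

    # 5. second resuscitation: crystalloid only
    if alive:
        arc2 = ArcController(
            arc_config, fluid=CRYSTALLOID, baseline_map_reference=baseline_ref
        )
        events["event2"] = sim.run_arc_event(arc2, None, "event2")
        arc_logs["event2"] = pd.DataFrame(
            arc2.log, columns=list(ArcController.LOG_COLUMNS)
        )
        alive = sim.state.alive

    trace = sim.trace()
    for name in ("event1", "event2"):
        if name in events:
            ev_trace = trace[trace["phase"] == name]
            reports[name] = compute_report(ev_trace, start=events[name].start)

    flags = {
        "alive": bool(sim.state.alive),
        "target_reached_1": bool(events.get("event1") and events["event1"].target_reached),
        "target_reached_2": bool(events.get("event2") and events["event2"].target_reached),
        "safety_engaged_1": bool(events.get("event1") and events["event1"].safety_engaged),
        "safety_engaged_2": bool(events.get("event2") and events["event2"].safety_engaged),
    }
    return ProtocolResult(
        trace=trace,
        boundaries=sim.boundaries,
        hold1=hold1,
        hold2=hold2,
        hold2_planned_duration=hold2_planned,
        events=events,
        reports=reports,
        arc_logs=arc_logs,
        autobleed_logs=ab_logs,
        final_state=sim.state,
        flags=flags,
        params=params,
        seed=seed,
    )


# -- smaller sessions used by tests and the reproduction script ------------


def run_autobleed_session(
    params: SubjectParams,
    ab_config: AutoBleedConfig | None = None,
    duration: float = 60.0,
    seed: int = 0,
) -> tuple[pd.DataFrame, AutoBleedController, BloodBag]:
    """Engage AutoBleed from baseline for a fixed duration (hemorrhage + hold)."""
    ab_config = ab_config or AutoBleedConfig()
    sim = ClosedLoopSim(params, seed=seed)
    controller = AutoBleedController(ab_config)
    bag = sim.run_autobleed(
        controller, BloodBag(), "autobleed", stop=None, max_duration=duration
    )
    return sim.trace(), controller, bag


def hemorrhage_rapidly(
    sim: ClosedLoopSim,
    target_map: float = 35.0,
    rate: float = 250.0,
) -> BloodBag:
    """Withdraw at a fixed rate until MAP reaches the hypotensive target.

    Produces the hemorrhaged initial condition (and the corresponding
    anticoagulated bag) for single-event ARC sessions.
    """
    bag = BloodBag()
    cmd = PumpCommand(-rate, WHOLE_BLOOD)
    while sim.state.map > target_map:
        hct = sim.state.hct
        sim.state = step(sim.params, sim.state, cmd, sim.dt)
        w = rate * sim.dt
        bag = bag_update(bag, withdrawn=w, subject_hct=hct, cpda=w / 7.0)
    return bag


def run_arc_session(
    params: SubjectParams,
    arc_config: ArcConfig | None = None,
    fluid: str = WHOLE_BLOOD,
    seed: int = 0,
    hemorrhage_target: float = 35.0,
) -> tuple[pd.DataFrame, ArcController, EventResult]:
    """Hemorrhage the subject, then run one complete ARC event."""
    arc_config = arc_config or ArcConfig()
    sim = ClosedLoopSim(params, seed=seed)
    bag = hemorrhage_rapidly(sim, hemorrhage_target)
    controller = ArcController(
        arc_config, fluid=fluid, baseline_map_reference=params.baseline_map
    )
    event = sim.run_arc_event(
        controller, bag if fluid == WHOLE_BLOOD else None, "event"
    )
    return sim.trace(), controller, event


# -- cohort ----------------------------------------------------------------


@dataclass
class CohortResult:
    results: list
    slopes: pd.DataFrame        # subject, anesthetic, hold1 lactate slope
    summary: dict               # per-stratum and pooled slope stats, metric stats

    def summary_frame(self) -> pd.DataFrame:
        rows = []
        for key, stats in self.summary.items():
            rows.append({"quantity": key, **stats})
        return pd.DataFrame(rows)


def _mean_sd(values) -> dict:
    arr = np.asarray([v for v in values if math.isfinite(v)], dtype=float)
    if arr.size == 0:
        return {"mean": math.nan, "sd": math.nan, "n": 0}
    sd = float(np.std(arr, ddof=1)) if arr.size > 1 else math.nan
    return {"mean": float(np.mean(arr)), "sd": sd, "n": int(arr.size)}


def run_cohort(
    n: int,
    strata: dict | None = None,
    base_seed: int = 0,
    overrides: dict | None = None,
    jitter: float = 0.0,
    arc_config: ArcConfig | None = None,
    autobleed_config: AutoBleedConfig | None = None,
    protocol_config: ProtocolConfig | None = None,
) -> CohortResult:
    """Run independent seeded subjects and aggregate cohort statistics.

    ``strata`` maps anesthetic name to subject count (must sum to ``n``);
    the default cohort splits 5 ketamine / 6 isoflurane when n = 11, else
    all ketamine.  The pooled lactate-accumulation slope is the unweighted
    mean of per-subject OLS slopes over the first-hold draws, as in a
    per-subject-rate presentation.  Summaries are order-invariant: each
    subject's seed derives from its index.
    """
    if n < 1:
        raise ValueError("cohort size must be at least 1")
    if strata is None:
        strata = {"ketamine": 5, "isoflurane": 6} if n == 11 else {"ketamine": n}
    if sum(strata.values()) != n:
        raise ValueError("strata counts must sum to n")

    assignments = []
    for anesthetic, count in sorted(strata.items()):
        assignments.extend([anesthetic] * count)

    sub_seeds = [
        int(s % (2**31))
        for s in np.random.SeedSequence(int(base_seed)).generate_state(n, np.uint64)
    ]

    results = []
    rows = []
    for idx, (anesthetic, sub_seed) in enumerate(zip(assignments, sub_seeds)):
        ov = dict(overrides or {})
        ov["anesthetic"] = anesthetic
        params = make_subject(ov, seed=sub_seed, jitter=jitter)
        result = run_protocol(
            params,
            arc_config=arc_config,
            autobleed_config=autobleed_config,
            protocol_config=protocol_config,
            seed=sub_seed,
        )
        results.append(result)
        rows.append(
            {
                "subject": idx,
                "anesthetic": anesthetic,
                "seed": sub_seed,
                "hold1_lactate_slope": result.hold1_lactate_slope,
            }
        )

    slopes = pd.DataFrame(rows)
    summary = {
        "lactate_slope_pooled": _mean_sd(slopes["hold1_lactate_slope"]),
    }
    for anesthetic in sorted(strata):
        sel = slopes[slopes["anesthetic"] == anesthetic]["hold1_lactate_slope"]
        summary[f"lactate_slope_{anesthetic}"] = _mean_sd(sel)
    for event in ("event1", "event2"):
        for name in ("mdpe", "mdape", "wobble", "target_overshoot", "rise_time",
                     "mean_infusion", "resuscitation_effectiveness"):
            vals = [
                getattr(r.reports[event], name)
                for r in results
                if event in r.reports
            ]
            summary[f"{event}_{name}"] = _mean_sd(vals)
    return CohortResult(results=results, slopes=slopes, summary=summary)
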