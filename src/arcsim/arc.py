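"""Adaptive resuscitation controller (ARC).

The controller continuously estimates the subject's pressure-volume
responsiveness (mmHg of MAP gained per mL infused) by sliding-window
ordinary least squares of observed MAP against cumulative infused volume,
then commands the infusion rate Q = pace / slope that would raise MAP at
the configured resuscitation pace (default 6 mmHg/min).  A CVP safety rule
lowers the active target when venous pressure indicates over-resuscitation.

The control loop runs in three phases: *resuscitation* (drive filtered MAP
up to the active target), *stabilization* (a fixed settling window after
first target attainment), and *maintenance* (hold the target; if the event
began on whole blood the infusate switches to crystalloid here).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np

from .subject import CRYSTALLOID, FLUIDS, WHOLE_BLOOD, PumpCommand, VitalsSample

RESUSCITATION = "resuscitation"
STABILIZATION = "stabilization"
MAINTENANCE = "maintenance"
PHASES = (RESUSCITATION, STABILIZATION, MAINTENANCE)


@dataclass
class ArcConfig:
    """Controller targets, pacing, estimator and safety settings.

    Times are seconds for the fast loop quantities (control interval,
    filter and regression windows) and minutes for protocol-scale
    durations, matching how each is naturally specified.
    """

    target_map: float = 65.0          # mmHg, resuscitation target
    pace: float = 6.0                 # mmHg/min desired MAP rise rate
    control_interval: float = 10.0    # s between rate updates
    regression_window: float = 180.0  # s of (volume, MAP) history for the slope fit
    q_min: float = 0.0                # mL/min
    q_max: float = 250.0              # mL/min pump bound
    deadband: float = 2.0             # mmHg below target at which infusion stops
    slope_floor: float = 0.005        # mmHg/mL minimum usable responsiveness
    bootstrap_slope: float = 0.03     # mmHg/mL used before any usable history
    min_window_volume: float = 5.0    # mL volume span required for a fit
    filter_window: float = 10.0       # s of raw samples for the pressure filter
    artifact_threshold: float = 20.0  # mmHg deviation rejected as artifact
    overshoot_margin: float = 0.25    # mmHg added to the volume-to-target cap
    cvp_threshold: float = 15.0       # mmHg safety threshold
    target_decrement: float = 2.0     # mmHg per safety reduction
    decrement_interval: float = 5.0   # min between successive reductions
    target_floor: float = 40.0        # mmHg hard floor for the active target
    stabilization_duration: float = 10.0   # min
    maintenance_duration: float = 120.0    # min

    def __post_init__(self) -> None:
        if self.pace <= 0:
            raise ValueError("pace must be positive")
        if not (0.0 <= self.q_min < self.q_max):
            raise ValueError("require 0 <= q_min < q_max")
        if self.deadband < 0:
            raise ValueError("deadband must be non-negative")
        if self.target_decrement <= 0:
            raise ValueError("target_decrement must be positive")
        if self.slope_floor <= 0 or self.bootstrap_slope <= 0:
            raise ValueError("slope_floor and bootstrap_slope must be positive")
        if self.control_interval <= 0 or self.regression_window <= 0:
            raise ValueError("control_interval and regression_window must be positive")
        if self.filter_window <= 0:
            raise ValueError("filter_window must be positive")
        if self.target_map <= 0 or self.target_floor <= 0:
            raise ValueError("targets must be positive")


@dataclass
class ArcState:
    """Mutable controller state across control ticks.

    ``history_*`` hold the 1-Hz observation stream (time min, cumulative
    infused volume mL, raw MAP mmHg) used by both the pressure filter and
    the responsiveness regression; entries older than the regression
    window are pruned as they expire.
    """

    active_target: float
    baseline_map_reference: float
    phase: str = RESUSCITATION
    fluid: str = WHOLE_BLOOD
    safety_engaged: bool = False
    last_decrement_time: float = math.nan
    attained_time: float | None = None
    started_on_whole_blood: bool = True
    last_tick_time: float = -math.inf
    last_observed_time: float = -math.inf
    history_t: list = field(default_factory=list)
    history_v: list = field(default_factory=list)
    history_p: list = field(default_factory=list)


def filter_pressure(samples, artifact_threshold: float = 20.0) -> float:
    """Artifact-rejecting moving median of raw MAP samples.

    Samples deviating more than ``artifact_threshold`` mmHg from the
    running median (blood-draw artifacts, line flushes) are discarded
    before the median is taken.
    """
    arr = np.asarray(list(samples), dtype=float)
    if arr.size == 0:
        raise ValueError("pressure filter requires at least one sample")
    med = float(np.median(arr))
    kept = arr[np.abs(arr - med) <= artifact_threshold]
    if kept.size == 0:
        return med
    return float(np.median(kept))


def estimate_responsiveness(
    volumes,
    maps,
    min_volume_span: float = 5.0,
    fallback: float = 0.03,
) -> float:
    """OLS slope of MAP on cumulative infused volume (mmHg/mL).

    Degenerate windows (fewer than two points, or a volume span below
    ``min_volume_span`` where the fit would be noise-dominated) return the
    ``fallback`` bootstrap slope instead of failing, so the controller
    always has a finite responsiveness to act on.
    """
    v = np.asarray(list(volumes), dtype=float)
    p = np.asarray(list(maps), dtype=float)
    if v.size != p.size:
        raise ValueError("volumes and maps must have equal length")
    if v.size < 2 or (v.max() - v.min()) < min_volume_span:
        return float(fallback)
    slope = np.polyfit(v, p, 1)[0]
    return float(slope)


def volume_to_target(map_mmHg: float, active_target: float, slope: float) -> float:
    """Estimated additional volume (mL) needed to raise MAP to the target."""
    if slope <= 0:
        raise ValueError("slope must be positive")
    return max(0.0, (active_target - map_mmHg) / slope)


def compute_rate(
    slope: float,
    map_mmHg: float,
    active_target: float,
    config: ArcConfig,
    deadband: float | None = None,
) -> float:
    """Infusion rate (mL/min) achieving the configured pace.

    The responsiveness estimate is clamped to ``slope_floor`` before use.
    At or above ``active_target - deadband`` the rate is zero.  Below it,
    Q = pace / slope, additionally capped so that a single control
    interval never commands more than the estimated remaining
    volume-to-target (this decelerates the final approach instead of
    overrunning the target), then clamped to the pump bounds.  The cap
    carries a small ``overshoot_margin`` so that a subject whose pressure
    decays between ticks (crystalloid leak) crosses the target rather than
    grazing it asymptotically.
    """
    db = config.deadband if deadband is None else deadband
    s = max(slope, config.slope_floor)
    if map_mmHg >= active_target - db:
        return 0.0
    q = config.pace / s
    tick_min = config.control_interval / 60.0
    cap_target = active_target + config.overshoot_margin
    q = min(q, volume_to_target(map_mmHg, cap_target, s) / tick_min)
    return float(min(max(q, config.q_min), config.q_max))


def safety_update(
    cvp: float,
    arc_state: ArcState,
    config: ArcConfig,
    now: float,
) -> ArcState:
    """Apply the CVP over-resuscitation rule to the active target.

    On the first crossing of the CVP threshold the active target drops to
    the subject's baseline MAP reference (or, if it already sits at or
    below baseline, takes the first fixed decrement immediately).  While
    CVP stays at or above threshold, further decrements follow at
    ``decrement_interval`` spacing, never below ``target_floor``.  The
    active target is non-increasing once the rule engages.
    """
    if cvp >= config.cvp_threshold:
        if not arc_state.safety_engaged:
            arc_state.safety_engaged = True
            reduced = min(arc_state.active_target, arc_state.baseline_map_reference)
            if reduced < arc_state.active_target:
                arc_state.active_target = reduced
            else:
                arc_state.active_target = max(
                    config.target_floor,
                    arc_state.active_target - config.target_decrement,
                )
            arc_state.last_decrement_time = now
        elif now - arc_state.last_decrement_time >= config.decrement_interval:
            arc_state.active_target = max(
                config.target_floor,
                arc_state.active_target - config.target_decrement,
            )
            arc_state.last_decrement_time = now
    return arc_state


def observe(
    arc_state: ArcState,
    now: float,
    map_raw: float,
    cumulative_volume: float,
    config: ArcConfig,
) -> None:
    """Append one 1-Hz observation and prune expired history."""
    if now <= arc_state.last_observed_time:
        raise ValueError("observations must have strictly increasing timestamps")
    arc_state.last_observed_time = now
    arc_state.history_t.append(now)
    arc_state.history_v.append(cumulative_volume)
    arc_state.history_p.append(map_raw)
    horizon = now - config.regression_window / 60.0
    drop = 0
    t = arc_state.history_t
    while drop < len(t) and t[drop] < horizon:
        drop += 1
    if drop:
        del arc_state.history_t[:drop]
        del arc_state.history_v[:drop]
        del arc_state.history_p[:drop]


def _filtered_map(arc_state: ArcState, now: float, config: ArcConfig) -> float:
    horizon = now - config.filter_window / 60.0
    window = [
        p
        for t, p in zip(arc_state.history_t, arc_state.history_p)
        if t >= horizon
    ]
    if not window:
        window = arc_state.history_p[-1:]
    return filter_pressure(window, config.artifact_threshold)


def arc_step(
    arc_state: ArcState,
    sample: VitalsSample,
    cumulative_volume: float,
    config: ArcConfig,
    now: float,
):
    """One control tick: ingest vitals, run safety, emit a pump command.

    Returns ``(PumpCommand, ArcState, info)`` where ``info`` carries the
    filtered MAP and slope estimate for logging.  Must be called with
    strictly increasing ``now``; out-of-order ticks are rejected.
    """
    if now <= arc_state.last_tick_time:
        raise ValueError("control ticks must have strictly increasing timestamps")
    arc_state.last_tick_time = now

    if now > arc_state.last_observed_time:
        observe(arc_state, now, sample.map, cumulative_volume, config)

    filtered = _filtered_map(arc_state, now, config)
    safety_update(sample.cvp, arc_state, config, now)

    if arc_state.phase == RESUSCITATION:
        if filtered >= arc_state.active_target:
            arc_state.phase = STABILIZATION
            arc_state.attained_time = now
    elif (
        arc_state.phase == STABILIZATION
        and now - arc_state.attained_time >= config.stabilization_duration
    ):
        arc_state.phase = MAINTENANCE
        if arc_state.started_on_whole_blood:
            arc_state.fluid = CRYSTALLOID

    slope = estimate_responsiveness(
        arc_state.history_v,
        arc_state.history_p,
        min_volume_span=config.min_window_volume,
        fallback=config.bootstrap_slope,
    )
    deadband = 0.0 if arc_state.phase == RESUSCITATION else None
    rate = compute_rate(slope, filtered, arc_state.active_target, config, deadband)
    command = PumpCommand(rate=rate, fluid=arc_state.fluid)
    info = {"filtered_map": filtered, "slope": slope}
    return command, arc_state, info


class ArcController:
    """Convenience wrapper binding an :class:`ArcConfig` to an :class:`ArcState`.

    ``observe`` is fed every vitals sample (1 Hz); ``tick`` is called every
    control interval and returns the pump command.  Decisions are logged as
    rows of (time_min, phase, active_target_mmHg, slope_mmHg_per_mL,
    commanded_rate_mL_min, fluid, safety_engaged).
    """

    LOG_COLUMNS = (
        "time_min",
        "phase",
        "active_target_mmHg",
        "slope_mmHg_per_mL",
        "commanded_rate_mL_min",
        "fluid",
        "safety_engaged",
    )

    def __init__(
        self,
        config: ArcConfig | None = None,
        fluid: str = WHOLE_BLOOD,
        baseline_map_reference: float | None = None,
        target: float | None = None,
    ) -> None:
        if fluid not in FLUIDS:
            raise ValueError(f"fluid must be one of {FLUIDS}")
        self.config = config or ArcConfig()
        self.state = ArcState(
            active_target=target if target is not None else self.config.target_map,
            baseline_map_reference=(
                baseline_map_reference
                if baseline_map_reference is not None
                else self.config.target_map
            ),
            fluid=fluid,
            started_on_whole_blood=(fluid == WHOLE_BLOOD),
        )
        self.log: list[tuple] = []

    def observe(self, now: float, map_raw: float, cumulative_volume: float) -> None:
        observe(self.state, now, map_raw, cumulative_volume, self.config)

    def tick(self, now: float, sample: VitalsSample, cumulative_volume: float) -> PumpCommand:
        command, _, info = arc_step(
            self.state, sample, cumulative_volume, self.config, now
        )
        self.log.append(
            (
                now,
                self.state.phase,
                self.state.active_target,
                info["slope"],
                command.rate,
                command.fluid,
                self.state.safety_engaged,
            )
        )
        return command

    @property
    def maintenance_start(self) -> float | None:
        if self.state.attained_time is None:
            return None
        return self.state.attained_time + self.config.stabilization_duration
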