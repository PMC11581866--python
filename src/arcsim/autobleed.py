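"""AutoBleed: decision-table hemorrhage controller with blood-bag tracking.

AutoBleed creates and maintains the controlled hemorrhage injury: it
withdraws blood until the filtered MAP reaches a hypotensive target
(default 35 mmHg) and then holds it there, withdrawing more when pressure
drifts above target and reinfusing bag blood when it drifts below.  Rates
are fixed by a monotone decision table on the MAP error - the controller
is deliberately not adaptive.  During withdrawal a second pump co-infuses
CPDA-1 anticoagulant into the bag at a fixed 1:7 volumetric ratio with the
blood, and the bag's volume and hematocrit are tracked by red-cell mass
balance so that reinfused blood carries the diluted bag hematocrit.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

from .arc import filter_pressure
from .subject import WHOLE_BLOOD, PumpCommand, VitalsSample

#: (|error| threshold mmHg, rate magnitude mL/min), descending.  The
#: commanded rate is the magnitude for the first band the error exceeds,
#: signed so that above-target errors withdraw and below-target errors
#: reinfuse; errors at or below the final threshold (the deadband) give 0.
DEFAULT_BANDS = ((10.0, 60.0), (4.0, 25.0), (1.0, 10.0), (0.5, 5.0))


@dataclass
class AutoBleedConfig:
    """Hemorrhage-controller settings.

    ``tolerance`` is the deadband half-width inside which no fluid moves;
    ``bands`` maps absolute MAP error to rate magnitude (see
    :data:`DEFAULT_BANDS`).  The clinical hold band of +/-2 mmHg around the
    hypotensive target is a property of the protocol, not of this table.
    """

    target_map: float = 35.0
    tolerance: float = 0.5
    bands: tuple = DEFAULT_BANDS
    cpda_ratio: float = 7.0           # blood:anticoagulant volumetric ratio
    control_interval: float = 10.0    # s
    filter_window: float = 10.0       # s
    artifact_threshold: float = 20.0  # mmHg

    def __post_init__(self) -> None:
        if self.target_map <= 0:
            raise ValueError("target_map must be positive")
        if self.tolerance < 0:
            raise ValueError("tolerance must be non-negative")
        if self.cpda_ratio <= 0:
            raise ValueError("cpda_ratio must be positive")
        thresholds = [b[0] for b in self.bands]
        rates = [b[1] for b in self.bands]
        if any(t <= 0 for t in thresholds) or any(r < 0 for r in rates):
            raise ValueError("band thresholds must be positive and rates non-negative")
        if sorted(thresholds, reverse=True) != list(thresholds):
            raise ValueError("bands must be ordered by descending |error| threshold")
        if sorted(rates, reverse=True) != list(rates):
            raise ValueError("band rates must not increase as |error| decreases")
        if not math.isclose(thresholds[-1], self.tolerance):
            raise ValueError("innermost band threshold must equal the tolerance")


@dataclass(slots=True)
class BloodBag:
    """Anticoagulated whole-blood reservoir.

    Hematocrit follows from red-cell mass balance: only the blood
    contribution carries red cells, so hct = rbc / (blood + CPDA).
    Proportional draws (reinfusion) leave the hematocrit unchanged.
    """

    blood_volume: float = 0.0  # mL of withdrawn blood
    cpda_volume: float = 0.0   # mL of anticoagulant
    rbc_volume: float = 0.0    # mL of red cells
    temperature_held: bool = True

    @property
    def total_volume(self) -> float:
        return self.blood_volume + self.cpda_volume

    @property
    def hct(self) -> float:
        total = self.total_volume
        return self.rbc_volume / total if total > 0 else 0.0


def decision_rate(filtered_map: float, config: AutoBleedConfig) -> float:
    """Signed rate (mL/min) from the decision table; negative = withdrawal."""
    error = filtered_map - config.target_map
    mag = abs(error)
    for threshold, rate in config.bands:
        if mag > threshold:
            return -math.copysign(rate, error)
    return 0.0


def cpda_rate(blood_withdrawal_rate: float, ratio: float = 7.0) -> float:
    """Anticoagulant co-infusion rate for a blood withdrawal magnitude."""
    if blood_withdrawal_rate < 0:
        raise ValueError("withdrawal rate magnitude must be non-negative")
    return blood_withdrawal_rate / ratio


def bag_update(
    bag: BloodBag,
    withdrawn: float = 0.0,
    subject_hct: float = 0.0,
    cpda: float = 0.0,
    reinfused: float = 0.0,
) -> BloodBag:
    """Apply fluid transfers to the bag and return the updated bag.

    Withdrawn blood adds red cells at the subject's hematocrit; reinfusion
    draws blood, CPDA and red cells proportionally from the mixed bag.  A
    reinfusion request exceeding the bag content signals a logic fault
    upstream and is rejected.
    """
    if withdrawn < 0 or cpda < 0 or reinfused < 0:
        raise ValueError("bag transfer volumes must be non-negative")
    blood = bag.blood_volume + withdrawn
    rbc = bag.rbc_volume + withdrawn * subject_hct
    cpda_v = bag.cpda_volume + cpda
    total = blood + cpda_v
    if reinfused > total + 1e-9:
        raise ValueError(
            f"reinfusion of {reinfused:.3f} mL exceeds bag volume {total:.3f} mL"
        )
    if reinfused > 0.0 and total > 0.0:
        keep = 1.0 - reinfused / total
        keep = max(keep, 0.0)
        blood *= keep
        cpda_v *= keep
        rbc *= keep
    return BloodBag(
        blood_volume=blood,
        cpda_volume=cpda_v,
        rbc_volume=rbc,
        temperature_held=bag.temperature_held,
    )


def autobleed_step(
    raw_map_window,
    config: AutoBleedConfig,
    bag: BloodBag,
    engaged: bool = True,
):
    """One control tick: filter -> decision table -> CPDA co-infusion.

    Returns ``(PumpCommand, cpda_rate_mL_min, filtered_map)``.  Reinfusion
    commands draw from the bag at bag hematocrit and are silenced when the
    bag is empty; the caller performs the per-step :func:`bag_update`
    bookkeeping as fluid actually moves.
    """
    filtered = filter_pressure(raw_map_window, config.artifact_threshold)
    if not engaged:
        return PumpCommand(0.0, WHOLE_BLOOD), 0.0, filtered
    rate = decision_rate(filtered, config)
    if rate > 0 and bag.total_volume <= 0.0:
        rate = 0.0
    anticoagulant = cpda_rate(-rate if rate < 0 else 0.0, config.cpda_ratio)
    command = PumpCommand(
        rate=rate,
        fluid=WHOLE_BLOOD,
        source_hct=bag.hct if rate > 0 else None,
    )
    return command, anticoagulant, filtered


class AutoBleedController:
    """Stateful wrapper: raw-sample buffer, engagement flag, decision log.

    Log rows: (time_min, filtered_map_mmHg, commanded_rate_mL_min,
    cpda_rate_mL_min, bag_volume_mL, bag_hct_frac, engaged).
    """

    LOG_COLUMNS = (
        "time_min",
        "filtered_map_mmHg",
        "commanded_rate_mL_min",
        "cpda_rate_mL_min",
        "bag_volume_mL",
        "bag_hct_frac",
        "engaged",
    )

    def __init__(self, config: AutoBleedConfig | None = None, engaged: bool = True):
        self.config = config or AutoBleedConfig()
        self.engaged = engaged
        self._times: list[float] = []
        self._maps: list[float] = []
        self.log: list[tuple] = []

    def observe(self, now: float, map_raw: float) -> None:
        self._times.append(now)
        self._maps.append(map_raw)
        horizon = now - self.config.filter_window / 60.0
        drop = 0
        while drop < len(self._times) and self._times[drop] < horizon:
            drop += 1
        if drop:
            del self._times[:drop]
            del self._maps[:drop]

    def tick(self, now: float, bag: BloodBag):
        command, anticoagulant, filtered = autobleed_step(
            self._maps or [0.0], self.config, bag, self.engaged
        )
        self.log.append(
            (
                now,
                filtered,
                command.rate,
                anticoagulant,
                bag.total_volume,
                bag.hct,
                self.engaged,
            )
        )
        return command, anticoagulant
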