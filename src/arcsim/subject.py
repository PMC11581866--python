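"""Synthetic swine hemodynamic model.

This module stands in for an instrumented large-animal subject in a
hemorrhage/resuscitation study.  It exposes a small state-space model with
the features the closed-loop controllers actually interact with:

* a linear mean-arterial-pressure (MAP) response to intravascular volume,
  which is what whole-blood infusion exploits;
* diminishing intravascular retention of crystalloid at higher pressures,
  plus an ongoing pressure-driven leak of previously retained crystalloid
  into the interstitium (so crystalloid maintenance demands visibly higher
  rates than whole blood);
* central venous pressure (CVP) rising with volume loading and with
  interstitial fluid accumulation (the over-resuscitation safety signal);
* lactate accumulating during ischemic hypotension at an
  anesthetic-stratified rate, and clearing - after a lag - once pressure
  has been restored;
* hematocrit dilution tracked by red-cell mass balance.

It deliberately does not synthesise cardiac waveforms, drug
pharmacokinetics, or arrhythmic death; the only failure mode is volume
depletion.
"""

from __future__ import annotations

import dataclasses
import math
from dataclasses import dataclass

import numpy as np
from numpy.random import Generator, Philox, SeedSequence

WHOLE_BLOOD = "whole_blood"
CRYSTALLOID = "crystalloid"
FLUIDS = (WHOLE_BLOOD, CRYSTALLOID)

ANESTHETICS = ("ketamine", "isoflurane", "propofol")

#: Lactate accumulation rate (mmol/L/hr) during ischemic hypotension, by
#: anesthetic stratum.  The ketamine and isoflurane values are the reported
#: in vivo strata; propofol (a single-subject stratum in the source cohort)
#: falls back to the pooled mean.
LACTATE_ACCUM_BY_ANESTHETIC = {
    "ketamine": 4.95,
    "isoflurane": 2.49,
    "propofol": 3.61,
}

#: Hardware ceiling for any single pump channel (mL/min).  Commands beyond
#: this are rejected as physically impossible rather than clamped.
PUMP_MAX_RATE = 300.0

#: Parameters given multiplicative Gaussian jitter by :func:`make_subject`
#: when cohort variability is requested.
_JITTERED_FIELDS = ("weight", "wb_slope", "baseline_hct", "lactate_accum_rate")


def rng_from_seed(seed: int) -> Generator:
    """Counter-based (Philox) generator so runs are bit-reproducible."""
    return Generator(Philox(SeedSequence(int(seed))))


@dataclass
class SubjectParams:
    """Fixed parameters of one virtual subject.

    Units: masses kg, volumes mL, pressures mmHg, rates per minute unless
    a field name says otherwise (lactate rates are mmol/L/hr).
    """

    weight: float = 40.0                      # kg
    blood_volume_per_kg: float = 70.0         # mL/kg
    baseline_map: float = 65.0                # mmHg at reference volume
    baseline_cvp: float = 4.0                 # mmHg at reference volume
    baseline_lactate: float = 1.0             # mmol/L
    baseline_hct: float = 0.30                # fraction
    wb_slope: float = 0.03                    # mmHg per mL intravascular volume
    crystalloid_retention_max: float = 0.80   # fraction retained at low MAP
    crystalloid_retention_min: float = 0.25   # fraction retained at high MAP
    retention_knee_low: float = 45.0          # mmHg
    retention_knee_high: float = 65.0         # mmHg
    leak_rate: float = 0.001                  # /min per mmHg above knee_low
    cvp_volume_gain: float = 0.005            # mmHg per mL volume deficit/excess
    cvp_interstitial_gain: float = 0.0007     # mmHg per mL interstitial excess
    lactate_accum_rate: float = 4.95          # mmol/L/hr while MAP < ischemia threshold
    lactate_clear_rate_wb: float = 1.0        # mmol/L/hr after whole-blood resuscitation
    lactate_clear_rate_crystalloid: float = 2.0  # mmol/L/hr after crystalloid
    clearance_lag: float = 20.0               # min above clearance threshold before clearing
    ischemia_map_threshold: float = 40.0      # mmHg
    clearance_map_threshold: float = 55.0     # mmHg
    noise_sd: float = 2.0                     # mmHg additive noise on pressure channels
    anesthetic: str = "ketamine"

    def __post_init__(self) -> None:
        numeric = {
            f.name: getattr(self, f.name)
            for f in dataclasses.fields(self)
            if f.name != "anesthetic"
        }
        for name, value in numeric.items():
            if not math.isfinite(float(value)):
                raise ValueError(f"subject parameter {name!r} must be finite")
        if self.anesthetic not in ANESTHETICS:
            raise ValueError(
                f"anesthetic must be one of {ANESTHETICS}, got {self.anesthetic!r}"
            )
        if not (0.0 <= self.crystalloid_retention_min <= self.crystalloid_retention_max <= 1.0):
            raise ValueError("require 0 <= retention_min <= retention_max <= 1")
        if not self.retention_knee_low < self.retention_knee_high:
            raise ValueError("require retention_knee_low < retention_knee_high")
        if self.wb_slope <= 0:
            raise ValueError("wb_slope must be positive")
        if not 0.0 < self.baseline_hct < 1.0:
            raise ValueError("baseline_hct must lie in (0, 1)")
        if self.weight <= 0 or self.blood_volume_per_kg <= 0:
            raise ValueError("weight and blood_volume_per_kg must be positive")
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be non-negative")
        if self.leak_rate < 0 or self.clearance_lag < 0:
            raise ValueError("leak_rate and clearance_lag must be non-negative")

    @property
    def reference_volume(self) -> float:
        """Euvolemic intravascular volume V0 (mL)."""
        return self.weight * self.blood_volume_per_kg


@dataclass(slots=True)
class SubjectState:
    """Evolving hemodynamic state of one subject.

    ``crystalloid_volume`` (the retained-crystalloid fraction of the
    intravascular volume) and the three cumulative audit counters are
    bookkeeping needed by the leak model and the volume-conservation
    audit; they carry no independent physiology.
    """

    time: float                        # min
    intravascular_volume: float        # mL
    interstitial_excess: float         # mL
    rbc_volume: float                  # mL
    crystalloid_volume: float          # mL, retained crystalloid in circulation
    map: float                         # mmHg
    cvp: float                         # mmHg
    lactate: float                     # mmol/L
    hct: float                         # fraction
    time_above_clearance_threshold: float  # min
    last_infusion_fluid: str           # fluid of most recent infusion
    alive: bool
    cum_withdrawn: float = 0.0         # mL removed from circulation
    cum_retained_infused: float = 0.0  # mL added to circulation
    cum_leaked: float = 0.0            # mL leaked to interstitium


@dataclass(slots=True)
class PumpCommand:
    """Signed fluid-transfer order.

    Positive ``rate`` infuses into the subject, negative withdraws.
    ``source_hct`` is the hematocrit of infused whole blood (e.g. the
    diluted blood-bag hematocrit during reinfusion); ignored for
    crystalloid.
    """

    rate: float                        # mL/min
    fluid: str = WHOLE_BLOOD
    source_hct: float | None = None

    def __post_init__(self) -> None:
        if self.fluid not in FLUIDS:
            raise ValueError(f"fluid must be one of {FLUIDS}, got {self.fluid!r}")
        if abs(self.rate) > PUMP_MAX_RATE:
            raise ValueError(
                f"|rate| = {abs(self.rate):.1f} mL/min exceeds pump maximum "
                f"{PUMP_MAX_RATE:.0f} mL/min"
            )
        if self.rate < 0 and self.fluid != WHOLE_BLOOD:
            raise ValueError("withdrawal is only permitted with whole blood")


@dataclass(slots=True)
class VitalsSample:
    """One noisy vitals observation; lactate present only on scheduled draws."""

    map: float
    cvp: float
    lactate: float | None = None


def make_subject(
    overrides: dict | None = None,
    seed: int = 0,
    jitter: float = 0.0,
) -> SubjectParams:
    """Build a subject parameter set from defaults plus overrides.

    Parameters
    ----------
    overrides
        Mapping of field name to value.  Unknown names are rejected.
        Setting ``anesthetic`` selects the stratum lactate accumulation
        rate unless ``lactate_accum_rate`` is itself overridden.
    seed
        Seed for the jitter draws; with ``jitter=0`` (the default) the
        result is the deterministic default/override set.
    jitter
        Coefficient of variation for multiplicative Gaussian jitter on
        a few physiological fields, for cohort variability.
    """
    overrides = dict(overrides or {})
    known = {f.name for f in dataclasses.fields(SubjectParams)}
    unknown = sorted(set(overrides) - known)
    if unknown:
        raise ValueError(f"unknown subject parameter(s): {', '.join(unknown)}")

    values = dataclasses.asdict(SubjectParams())
    anesthetic = overrides.get("anesthetic", values["anesthetic"])
    if anesthetic not in ANESTHETICS:
        raise ValueError(
            f"anesthetic must be one of {ANESTHETICS}, got {anesthetic!r}"
        )
    values["anesthetic"] = anesthetic
    values["lactate_accum_rate"] = LACTATE_ACCUM_BY_ANESTHETIC[anesthetic]
    values.update(overrides)

    if jitter > 0.0:
        rng = rng_from_seed(seed)
        for name in _JITTERED_FIELDS:
            z = rng.standard_normal()  # always drawn, keeps the stream aligned
            if name not in overrides:
                values[name] *= max(0.1, 1.0 + jitter * z)

    return SubjectParams(**values)


def initial_state(params: SubjectParams) -> SubjectState:
    """Euvolemic baseline state for a subject."""
    v0 = params.reference_volume
    return SubjectState(
        time=0.0,
        intravascular_volume=v0,
        interstitial_excess=0.0,
        rbc_volume=v0 * params.baseline_hct,
        crystalloid_volume=0.0,
        map=params.baseline_map,
        cvp=params.baseline_cvp,
        lactate=params.baseline_lactate,
        hct=params.baseline_hct,
        time_above_clearance_threshold=0.0,
        last_infusion_fluid=WHOLE_BLOOD,
        alive=True,
    )


def map_from_volume(params: SubjectParams, intravascular_volume: float) -> float:
    """Linear MAP-volume law, floored at zero.

    MAP = baseline + wb_slope * (V - V0).  Whole blood acts through this
    relation directly; crystalloid acts through it via its retained
    fraction only.
    """
    if intravascular_volume <= 0:
        raise ValueError("intravascular volume must be positive")
    v0 = params.reference_volume
    return max(0.0, params.baseline_map + params.wb_slope * (intravascular_volume - v0))


def crystalloid_retention(params: SubjectParams, map_mmHg: float) -> float:
    """Fraction of infused crystalloid retained intravascularly at a MAP.

    Maximal retention at or below the low knee, minimal at or above the
    high knee, linear in between (the pressure-driven interstitial
    redistribution that makes crystalloid lose volume responsiveness).
    """
    if map_mmHg < 0:
        raise ValueError("MAP must be non-negative")
    return float(
        np.interp(
            map_mmHg,
            [params.retention_knee_low, params.retention_knee_high],
            [params.crystalloid_retention_max, params.crystalloid_retention_min],
        )
    )


def step(
    params: SubjectParams,
    state: SubjectState,
    command: PumpCommand,
    dt: float,
) -> SubjectState:
    """Advance the subject one explicit-Euler step of ``dt`` minutes.

    Whole blood enters (or leaves) the circulation in full; crystalloid
    enters at the current retention fraction, the remainder going to the
    interstitium.  Retained crystalloid additionally leaks to the
    interstitium at ``leak_rate * (MAP - knee_low)`` per minute while MAP
    exceeds the low retention knee.  Withdrawal removes red cells and
    crystalloid in proportion to their current fractions, so hematocrit is
    invariant under hemorrhage.  A step that would exhaust the circulating
    volume flags the subject as not alive.
    """
    if dt <= 0:
        raise ValueError("dt must be positive")
    if not state.alive:
        return dataclasses.replace(state, time=state.time + dt)

    rate = command.rate
    v = state.intravascular_volume
    rbc = state.rbc_volume
    crys = state.crystalloid_volume
    inter = state.interstitial_excess
    cum_w = state.cum_withdrawn
    cum_i = state.cum_retained_infused
    cum_l = state.cum_leaked
    last_fluid = state.last_infusion_fluid
    map0 = state.map

    if rate > 0:
        vol = rate * dt
        if command.fluid == WHOLE_BLOOD:
            src_hct = (
                command.source_hct
                if command.source_hct is not None
                else params.baseline_hct
            )
            v += vol
            rbc += vol * src_hct
            cum_i += vol
        else:
            retained = crystalloid_retention(params, map0) * vol
            v += retained
            crys += retained
            inter += vol - retained
            cum_i += retained
        last_fluid = command.fluid
    elif rate < 0:
        vol = -rate * dt
        frac_rbc = rbc / v
        frac_crys = crys / v
        v -= vol
        rbc -= vol * frac_rbc
        crys -= vol * frac_crys
        cum_w += vol

    if crys > 0.0 and map0 > params.retention_knee_low:
        leak = min(
            crys,
            params.leak_rate * (map0 - params.retention_knee_low) * crys * dt,
        )
        v -= leak
        crys -= leak
        inter += leak
        cum_l += leak

    alive = state.alive
    if v <= 0.0:
        alive = False
        v = 1e-9
        rbc = max(rbc, 0.0)
        crys = max(crys, 0.0)

    new_map = map_from_volume(params, v)
    v0 = params.reference_volume
    cvp = (
        params.baseline_cvp
        + params.cvp_volume_gain * (v - v0)
        + params.cvp_interstitial_gain * inter
    )

    lactate = state.lactate
    t_above = state.time_above_clearance_threshold
    if new_map < params.ischemia_map_threshold:
        lactate += params.lactate_accum_rate * dt / 60.0
    if new_map >= params.clearance_map_threshold:
        t_above += dt
        if t_above >= params.clearance_lag:
            clear = (
                params.lactate_clear_rate_crystalloid
                if last_fluid == CRYSTALLOID
                else params.lactate_clear_rate_wb
            )
            lactate = max(params.baseline_lactate, lactate - clear * dt / 60.0)
    else:
        t_above = 0.0

    return SubjectState(
        time=state.time + dt,
        intravascular_volume=v,
        interstitial_excess=inter,
        rbc_volume=rbc,
        crystalloid_volume=crys,
        map=new_map,
        cvp=cvp,
        lactate=lactate,
        hct=rbc / v,
        time_above_clearance_threshold=t_above,
        last_infusion_fluid=last_fluid,
        alive=alive,
        cum_withdrawn=cum_w,
        cum_retained_infused=cum_i,
        cum_leaked=cum_l,
    )


def sample_vitals(
    state: SubjectState,
    params: SubjectParams,
    rng: Generator,
    include_lactate: bool = False,
) -> VitalsSample:
    """Noisy observation of the pressure channels; state is untouched.

    Additive Gaussian noise with sd ``params.noise_sd`` on MAP and CVP.
    Lactate is a point-of-care draw and is only emitted when the caller's
    sampling schedule requests it.
    """
    if params.noise_sd > 0.0:
        m = state.map + params.noise_sd * rng.standard_normal()
        c = state.cvp + params.noise_sd * rng.standard_normal()
    else:
        m = state.map
        c = state.cvp
    return VitalsSample(
        map=m,
        cvp=c,
        lactate=state.lactate if include_lactate else None,
    )
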