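# Methods

This note documents the models and procedures implemented in `arcsim`,
the defaults chosen where the design was genuinely open, and what the
synthetic subject does and does not capture.

## Synthetic subject model

The subject is a lumped two-compartment volume model advanced by explicit
Euler at a 1-s step, with one noisy vitals sample per step (real
acquisition chains sample analog waveforms far faster, but both
controllers consume a filtered mean pressure, so sub-second waveform
detail carries no information the loop uses).

**Pressure–volume.** MAP is linear in intravascular volume,
`MAP = MAP0 + s·(V − V0)`, floored at zero, with `s = wb_slope =
0.03 mmHg/mL` and `V0 = weight × 70 mL/kg` (2800 mL at 40 kg). The
linear law is taken from the characterization of whole-blood dynamics as
linear across the working MAP range; the default slope is set so a
1,000-mL bleed spans 65 → 35 mmHg, the protocol's two operating points.
Whole blood transfers volume (and red cells at the source hematocrit)
one-for-one.

**Crystalloid.** Infused crystalloid is retained intravascularly at a
fraction that falls linearly from 0.80 at ≤ 45 mmHg to 0.25 at
≥ 65 mmHg (the loss of volume responsiveness at higher pressures caused
by interstitial redistribution); the remainder goes directly to an
interstitial-excess compartment. Retained crystalloid additionally leaks
to the interstitium at `leak_rate × (MAP − 45 mmHg)` per minute
(`leak_rate = 0.001 /min/mmHg`). The leak constant was chosen once so
that crystalloid maintenance of the 65-mmHg target demands event-mean
infusion rates of a few tens of mL/min — the order reported for in vivo
crystalloid resuscitation — while whole-blood maintenance demands almost
none. There is no return path from interstitium to circulation; over a
multi-hour protocol this overstates cumulative interstitial accumulation
somewhat.

**CVP.** `CVP = 4 + 0.005·(V − V0) + 0.0007·interstitial_excess` mmHg.
The gains were set once against the reported in vivo CVP trajectory
shape: ≈ −1 mmHg at the end of a 1-L hemorrhage, single digits after a
crystalloid maintenance window, threshold-crossing (15 mmHg) only under
extreme crystalloid loading. CVP may be negative; no floor is applied.

**Lactate.** Lactate rises at the anesthetic-stratum rate while
MAP < 40 mmHg (ketamine 4.95, isoflurane 2.49 mmol/L/hr; the propofol
stratum, too small to characterize separately in vivo, uses the pooled
3.61). It clears only after MAP has stayed ≥ 55 mmHg continuously for
20 min — shock resolution lags pressure restoration — at 1.0 mmol/L/hr
when the most recent infusate was whole blood and 2.0 mmol/L/hr after
crystalloid, floored at the 1.0 mmol/L baseline. Between 40 and
55 mmHg lactate neither accumulates nor clears; the in-between behavior
is not observable in the source data and the thresholds are this
package's choice. Baseline lactate (1.0 mmol/L) is likewise an assumed
default.

**Hematocrit and death.** Hematocrit is `rbc_volume / V` by mass
balance, so hemorrhage leaves it unchanged and crystalloid dilutes it.
The only failure mode is volume depletion (`alive` flag); arrhythmic
death is deliberately not modeled.

**Randomness.** All stochastic draws come from a counter-based Philox
generator keyed by a named seed per subject, so every run is
bit-reproducible from `(config, seed)`.

## ARC

The controller keeps a 1-Hz history of (cumulative infused volume, raw
MAP) and, each 10-s control tick:

1. filters pressure with an artifact-rejecting moving median (10-s
   window; samples > 20 mmHg from the running median are discarded —
   blood-draw artifacts);
2. estimates responsiveness ΔP/ΔV by ordinary least squares over the
   trailing 180 s of history. Windows with fewer than two points or a
   volume span under 5 mL return a bootstrap slope of 0.03 mmHg/mL so
   the first command is finite. The window length was sized from the
   OLS slope-variance budget: with 2-mmHg pressure noise and the pump
   capped at 250 mL/min, 180 s of 1-Hz samples keeps the relative
   estimate error under ~7% across true slopes 0.01–0.1 mmHg/mL,
   which a 60-s window of tick-level filtered pairs cannot achieve;
3. applies the CVP safety rule (below);
4. commands `Q = pace / max(slope, slope_floor)`, clamped to
   [0, 250] mL/min. Q is additionally capped so one control interval
   never delivers more than the estimated remaining volume-to-target
   plus a 0.25-mmHg margin. The cap is what decelerates the final
   approach (pace is otherwise held constant); the margin ensures a
   subject whose pressure decays between ticks (crystalloid leak) still
   crosses the target instead of approaching it asymptotically.

The pump bound of 250 mL/min is a deliberate default: the configured
pace of 6 mmHg/min on a 0.03 mmHg/mL subject requires 200 mL/min, and
the bound must not silently truncate the design pace for the nominal
subject.

**Phases.** During *resuscitation* the deadband is suppressed and
"target reached" means filtered MAP ≥ active target at a control tick
(ties count). Attainment starts a 10-min *stabilization* window, after
which *maintenance* begins and an event that started on whole blood
switches to crystalloid. In stabilization/maintenance, infusion stops
within 2 mmHg (deadband) of the target.

**Safety rule.** The first time CVP ≥ 15 mmHg, the active target drops
to the subject's baseline MAP reference; if it already sits at or below
baseline, the first fixed 2-mmHg decrement applies immediately. While
CVP remains at or above threshold, further 2-mmHg decrements follow
every 5 min, never below a 40-mmHg floor. The active target is
non-increasing once engaged; decrementing stops as soon as CVP falls
below threshold (the operationalization of "until a stable MAP").

## AutoBleed

A fixed (non-adaptive) monotone decision table on the filtered MAP error
`e = MAP − 35`: |e| > 10 → 60 mL/min, 4–10 → 25, 1–4 → 10, 0.5–1 → 5,
and 0 inside ±0.5 mmHg; above-target errors withdraw, below-target
errors reinfuse bag blood. The exact in vivo table entries are not public;
this table reproduces "progressively quicker rates with distance from
target" and gives first-hemorrhage durations of the right order for a
40-kg subject. The inner deadband is ±0.5 mmHg rather than the clinical
±2-mmHg band because a noise-free subject freezes wherever the zero band
begins: the deadband half-width *is* the steady-state error bound, and
the controller is required to hold the target to within 1 mmHg. The
±2-mmHg band remains the protocol's criterion for "target met".

During withdrawal a second channel mixes CPDA-1 anticoagulant at exactly
1:7 with the blood into the bag; bag hematocrit follows red-cell mass
balance (≈ 7/8 of subject hematocrit for a pure mix), and reinfusion
draws proportionally from the mixed bag, so the dilution effect of the
anticoagulant is retained.

## Protocol

Baseline is a single 30-min stabilization (line placement and surgery
have no simulated counterpart). The hold starts when filtered MAP enters
the ±2-mmHg band; lactate is drawn every 10 min from hold start, and the
hold ends at the first draw ≥ 4 mmol/L or at 90 min. The second hold is
planned to match the realized first-hold duration and is cut short if a
draw reaches 6 mmol/L. The calcium bolus given at resuscitation start in
the live protocol has no modeled hemodynamic effect and is not
simulated. Per-subject lactate accumulation slopes are OLS over the
hold draws converted to mmol/L/hr, and cohort means are unweighted
means of per-subject slopes.

## Metrics

Performance error is `100·(MAP − target)/target` per sample against the
*instantaneous* active target, so safety-rule reductions change the
denominator from the reduction time onward. MDPE/MDAPE/wobble are plain
medians (even-length medians averaged); band boundaries are inclusive;
overshoot uses the single largest positive excursion; areas are
trapezoidal; infusion variability is the sample SD (n−1). Metrics are
computed over the full event window (resuscitation start through
maintenance end) by default — the scoring window is configurable because
the original analysis window is unstated. Rise time is plain
time-to-target in minutes; if "rise time efficiency" elsewhere denotes a
normalized quantity, this definition diverges and is documented rather
than guessed. All metrics run on the simulator's 1-Hz channel.

## Problem sizes and runtimes

A full two-event protocol is ≈ 400–500 simulated minutes (≈ 25,000–30,000
1-s steps) and takes well under a second of wall time; the 11-subject
cohort a few seconds; the complete test suite and the reproduction
script each tens of seconds. The responsiveness-recovery suite evaluates
ticks after the regression window has filled (the spin-up period returns
the bootstrap value by construction and is not an estimate of the
subject).

## What passing tests do and do not show

The synthetic subject is a control-oriented abstraction: it reproduces
the *directions and operating points* that matter to the loop (linear
whole-blood response, diminishing crystalloid responsiveness and its
demand asymmetry, lactate lag and strata, hematocrit dilution, CVP as an
over-resuscitation signal). It has no baroreflex or compensatory
vasoconstriction, no anesthetic pharmacodynamics, no vasodilatory drift,
no cardiac waveforms, and no arrhythmias. Consequently closed-loop
results here demonstrate controller logic and metric correctness, not
in vivo fidelity: a noise-free synthetic run settles far more cleanly
than an animal, and transient metrics such as overshoot land below the
in vivo cohort's values because the synthetic plant lacks the reactive
dynamics that produce them.
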