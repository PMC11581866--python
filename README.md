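# arcsim

A desk-scale, fully closed-loop simulator for automated hemorrhage and
fluid-resuscitation control.

Hemorrhage is the leading cause of preventable trauma death, and in
pre-hospital or resource-austere settings there is often no provider free
to titrate fluids continuously. Physiological closed-loop controllers
(PCLCs) automate this: they read an arterial pressure signal and drive an
infusion pump with no human in the loop. Developing and scoring such
controllers on animal subjects is slow and expensive, so `arcsim`
provides the whole loop in software for controller engineers and
physiological-modeling researchers: a synthetic swine hemodynamic model,
the two controllers, the full two-event shock/resuscitation study
protocol, and the standard controller-performance scorecard.

## What is in the box

* **Synthetic subject** (`arcsim.subject`) — a 40-kg virtual swine with a
  linear MAP–volume response to whole blood (slope `wb_slope`, default
  0.03 mmHg/mL), pressure-dependent intravascular retention of
  crystalloid with an ongoing interstitial leak, CVP driven by volume and
  interstitial loading, anesthetic-stratified lactate kinetics
  (ketamine 4.95, isoflurane 2.49 mmol/L/hr during ischemia; clearance
  1.0 mmol/L/hr after whole blood vs 2.0 mmol/L/hr after crystalloid,
  with a 20-min lag), and hematocrit by red-cell mass balance.
* **Adaptive resuscitation controller (ARC)** (`arcsim.arc`) — estimates
  pressure–volume responsiveness ΔP/ΔV by sliding-window least squares of
  MAP on cumulative infused volume and commands the flow rate

      Q = (ΔP/ΔT) / (ΔP/ΔV)

  that achieves the configured resuscitation pace ΔP/ΔT (default
  6 mmHg/min) toward a 65 mmHg permissive-hypotension target, with a CVP
  ≥ 15 mmHg safety rule that lowers the active target to baseline and
  then in 2-mmHg steps.
* **AutoBleed** (`arcsim.autobleed`) — a decision-table hemorrhage
  controller that withdraws/reinfuses blood to hold a 35 mmHg hypotensive
  target and co-infuses CPDA-1 anticoagulant at a strict 1:7 volumetric
  ratio into a tracked blood bag.
* **Protocol runner** (`arcsim.protocol`) — the full study timeline:
  baseline, hemorrhage, lactate-gated hypovolemic hold (≥ 4 mmol/L or
  90 min), whole-blood resuscitation, 10-min stabilization, 120-min
  crystalloid maintenance, a matched second hemorrhage/hold (6 mmol/L
  cap), and a crystalloid-only second resuscitation. Cohort driver with
  anesthetic strata included.
* **Metrics** (`arcsim.metrics`) — the twelve-metric scorecard (MDPE,
  MDAPE, wobble, effectiveness, resuscitation effectiveness, overshoot,
  areas above/below target, rise time, infusion-rate statistics) and the
  two-event ratio table.

## Worked example

```bash
cat > example.yaml <<'YAML'
subject:
  anesthetic: ketamine
  noise_sd: 2.0
seed: 42
YAML
arcsim simulate --config example.yaml --seed 42 --out run42
```

prints

```
[event1] rise_time=4.35 min mdpe=0.30% mdape=2.16% mean_infusion=7.72 mL/min
[event2] rise_time=5.77 min mdpe=-2.32% mdape=2.78% mean_infusion=71.03 mL/min
wrote outputs to run42 (config 0cc44e22e433)
```

Event 1 is the whole-blood resuscitation: the controller reaches the
65 mmHg target in about four minutes and then holds it with a median
performance error of a fraction of a percent; most of the event is quiet
maintenance, so the event-mean infusion rate is low. Event 2 is the
crystalloid-only rebleed resuscitation: the rise is slower and the mean
infusion rate is roughly ten-fold higher, because crystalloid is poorly
retained at higher pressures — exactly the qualitative asymmetry the
protocol is designed to expose. `run42/` contains per-phase trace CSVs,
both controllers' decision logs, per-event metric reports and a
manifest; the two-event comparison table comes from

```bash
arcsim report --event1 run42/metrics_event1.txt --event2 run42/metrics_event2.txt
```

A stratified cohort with per-subject jitter runs via
`arcsim cohort --n 11 --ketamine 5 --isoflurane 6 --seed 1 --out cohort/`,
and `arcsim metrics --trace some_trace.csv --target 65` scores any
recorded trace in the documented CSV schema.

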