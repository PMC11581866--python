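"""Direct-definition metric oracle, deliberately sharing no code with arcsim.

Used by the metric tests to cross-check every metric on randomly generated
traces: plain-Python medians, explicit trapezoids, first-passage scan.
"""

import math
import statistics

import numpy as np
import pandas as pd


def naive_metrics(t, m, tgt, rates, band=5.0):
    pe = [100.0 * (mi - gi) / gi for mi, gi in zip(m, tgt)]
    mdpe = statistics.median(pe)
    mdape = statistics.median([abs(x) for x in pe])
    wobble = statistics.median([abs(x - mdpe) for x in pe])
    n = len(m)
    eff = 100.0 * sum(1 for mi, gi in zip(m, tgt) if abs(mi - gi) <= band) / n
    resus = 100.0 * sum(1 for mi, gi in zip(m, tgt) if mi >= gi - band) / n
    rise = next((ti - t[0] for ti, mi, gi in zip(t, m, tgt) if mi >= gi), math.nan)
    overshoot = max(0.0, max((mi - gi) / gi for mi, gi in zip(m, tgt))) * 100.0
    above = below = 0.0
    for i in range(n - 1):
        dt = t[i + 1] - t[i]
        a0, a1 = max(m[i] - tgt[i], 0.0), max(m[i + 1] - tgt[i + 1], 0.0)
        b0, b1 = max(tgt[i] - m[i], 0.0), max(tgt[i + 1] - m[i + 1], 0.0)
        above += 0.5 * (a0 + a1) * dt
        below -= 0.5 * (b0 + b1) * dt
    med_q = statistics.median(rates)
    mean_q = sum(rates) / n
    var_q = statistics.stdev(rates) if n > 1 else 0.0
    return (mdpe, mdape, wobble, eff, resus, overshoot, above, below, rise,
            med_q, mean_q, var_q)


def random_trace(rng, n=None):
    n = n or int(rng.integers(3, 120))
    t0 = float(rng.uniform(0, 100))
    t = t0 + np.arange(n) / 60.0
    target = np.full(n, float(rng.uniform(40, 80)))
    if rng.uniform() < 0.3:  # piecewise target reduction partway through
        target[n // 2:] -= float(rng.uniform(2, 10))
    m = target + rng.normal(0, 8, n)
    rates = np.abs(rng.normal(30, 25, n))
    return pd.DataFrame(
        {"time_min": t, "map_mmHg": m, "target_mmHg": target,
         "infusion_mL_min": rates}
    )
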