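"""Fit a Hill-sigmoid learning curve to one rotarod series.

Simulates a single animal's 15 accelerating-rotarod trials (90 s cap) and
fits t(x) = t0 + (tmax - t0) x^h / (ls50^h + x^h).  Two learning-speed
readouts are printed: the fitted midpoint parameter and the literal "trials
to reach 50 % of maximum time", which differ when the baseline t0 > 0.
"""

import pandas as pd

from csdstools import SimulationConfig, fit_learning_curve, learning_speed
from csdstools.motor import max_time
from csdstools.synthetic import gen_rotarod

cfg = SimulationConfig(seed=1)
labels = pd.DataFrame({"animal_id": ["demo"], "planted_phenotype": ["resilient"]})
series = gen_rotarod(cfg, labels).sort_values("trial")["time_s"].to_numpy()

fit = fit_learning_curve(series)
ls = learning_speed(fit)
mt = max_time(series, fit)

print("trial times (s):", [round(float(t), 1) for t in series])
print(f"fit: t0={fit.t0:.1f} s  tmax={fit.tmax:.1f} s  ls50={fit.ls50:.2f}  h={fit.h:.2f}")
print(f"max time: fitted {mt['fitted_tmax_s']:.1f} s, empirical {mt['empirical_max_s']:.1f} s")
print(f"learning speed: midpoint parameter {fit.ls50:.2f} trials, "
      f"literal 50%-of-max {ls.trials:.2f} trials")
# planted resilient parameters: t0=20, tmax=75, ls50=4.5, h=2.5 with 5 s noise
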