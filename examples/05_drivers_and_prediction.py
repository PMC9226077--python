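"""Fit the composite path model and predict specialization under change.

Simulates data from a known recursive system linking temperature and
nitrogen to specialization through five proximal composites, refits the
path model, and then pushes a warming + eutrophication scenario through the
fitted coefficients (Delta H2' relative to a baseline year).
"""

import numpy as np
import pandas as pd

from edtia import drivers

rng = np.random.default_rng(0)
true = {f"{v},{p}": round(float(rng.uniform(-0.6, 0.6)), 2)
        for v, ps in drivers.DEFAULT_PATH_SPEC.items() for p in ps}

n = 300
vals = {"temp": rng.normal(0, 1, n), "N": rng.normal(0, 1, n)}
for var, parents in drivers.DEFAULT_PATH_SPEC.items():
    vals[var] = sum(true[f"{var},{p}"] * vals[p] for p in parents) \
        + rng.normal(0, 0.5, n)

table = pd.DataFrame({k: v for k, v in vals.items() if k != "H2"})
model = drivers.fit_path_model(table, vals["H2"])
fs = model.fit_stats
print(f"path model fit: chi2 = {fs['chi2']:.2f} (df {fs['df']}, "
      f"p = {fs['chi2_p']:.3f}), CFI = {fs['CFI']:.3f}, "
      f"SRMR = {fs['SRMR']:.4f}, admissible = {model.admissible}")
direct = {k: round(v, 2) for k, v in model.lambdas.items()
          if k.startswith("H2,")}
print("direct paths into H2':", direct)

# scenario: 4 sites, 12 years of gradual warming and nitrogen increase
rows = [{"site": f"site_{s}", "year": 2007 + t,
         "temperature": 17.0 + 0.06 * t + 0.2 * s,
         "total_nitrogen": 2.0 + 0.3 * t}
        for s in range(4) for t in range(12)]
scen = pd.DataFrame(rows)
model.standardization = {"temp_mean": 17.0, "temp_sd": 1.0,
                         "N_mean": 2.0, "N_sd": 2.0}
deltas = drivers.scenario_deltas(scen, {"fitted": model}, baseline_year=2007)
by_year = deltas.groupby("year")["delta_H2"].mean()
print("\nmean Delta H2' by year (0 at the 2007 baseline):")
print(by_year.round(3).to_string())
print("\nThe sign and size of the trend follow the fitted direct and "
      "indirect temperature/nitrogen paths.")
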