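"""How sampling density affects parameter identifiability.

Fits the transient model to trials simulated under a sparse (10-day) and a
dense (daily) measurement schedule and compares the precision (RSE) of the
window-amplitude parameter N_max, whose effect saturates as N grows — the
canonical weakly-identified parameter of this model.
Run time ~1 minute (two SAEM fits).
"""

import numpy as np

from vesselnorm import SaemSettings, TrialDesign, kpl4_population, richness_study

pop = kpl4_population()
sparse = TrialDesign()  # the default: 10 measurement days
dense = TrialDesign(measurement_days=tuple(np.arange(38.0, 71.0)))

table = richness_study(
    pop, [sparse, dense], rng_seed=11,
    design_labels=["sparse (10 days)", "dense (daily)"],
    settings=SaemSettings(n_burnin=200, n_smooth=150, n_chains=1,
                          init_theta={**pop.theta, "T0": 70.0}, init_b=0.2),
)
show = table[table.parameter.isin(["alpha_T", "N_max", "delta_V_bevacizumab"])]
print(show[["design", "parameter", "estimate", "truth", "rel_error", "rse_pct"]]
      .round(3).to_string(index=False))
nmax = table[table.parameter == "N_max"].set_index("design").rse_pct
print(f"\nRSE(N_max): {nmax.round(0).to_dict()}")
print("Daily sampling shrinks the uncertainty of the window parameters; with "
      "10 points per animal, N_max is nearly unidentified (large estimates "
      "give near-identical trajectories).")
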