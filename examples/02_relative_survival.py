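"""Fit the spatial relative-survival (excess mortality) model.

Simulates individual cancer-survival records on an 8x8 lattice — background
mortality from a life table plus a piecewise-constant excess hazard, with
one area given double the excess hazard — applies the registry exclusion
rules, collapses person-time into model cells, fits the model and prints
the smoothed relative excess risk (RER) at the planted area.  An RER of 1
means average cancer-attributable mortality; above 1 means worse survival.
"""

import numpy as np

from arealrisk import (
    DESK_SCALE,
    apply_survival_exclusions,
    collapse_person_time,
    fit_excess_mortality,
    repair_isolates,
    summarize_rer,
)
from arealrisk.simulate import (
    make_geography,
    simulate_populations_and_lifetable,
    simulate_survival_records,
)

WINDOW = ("1998-01-01", "2007-12-31")

_, g0 = make_geography(8, 8, 0, seed=5)
graph, _ = repair_isolates(g0)
pops, life_table = simulate_populations_and_lifetable(graph, seed=5)

alpha_j = np.log([0.30, 0.20, 0.12, 0.08, 0.06])  # excess hazard by year
beta_k = np.array([0.0, 0.3, 0.6, 1.0])           # broad age-group effects
planted = np.zeros(graph.n_areas)
planted[27] = np.log(2.0)                         # doubled excess hazard

sim = simulate_survival_records(graph, alpha_j, beta_k, pops, life_table,
                                n_cases=20_000, window=WINDOW,
                                area_log_rer=planted, seed=11)
kept, tally = apply_survival_exclusions(sim.records, WINDOW)
print("exclusion tally:", tally)

cells = collapse_person_time(kept, life_table, WINDOW,
                             area_ids=list(graph.area_ids))
print(f"{cells.n_cells} cells, {cells.y.sum():.0f} person-years, "
      f"{int(cells.d.sum())} deaths ({cells.dstar.sum():.0f} expected from "
      "background mortality alone)")

draws = fit_excess_mortality(cells, graph, mcmc=DESK_SCALE, seed=1)
est = summarize_rer(draws)
i = 27
print(f"\nplanted area {est.area_ids[i]}: RER median "
      f"{est.median[i]:.2f} (95% CrI {est.lo95[i]:.2f}-{est.hi95[i]:.2f}), "
      f"category '{est.category[i]}'")
others = np.delete(est.median, i)
print(f"all other areas: medians {others.min():.2f}-{others.max():.2f}")
print("the interval above 1 flags genuinely elevated cancer-attributable "
      "mortality; shrinkage pulls the point estimate below the true 2.0")
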