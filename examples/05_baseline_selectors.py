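"""Run the comparison wavelength selectors: CARS, MC-UVE and SPA.

Each returns the same SelectionResult structure as FIC-SS, so they plug
into the same downstream training.  The run-to-run stability of the
stochastic selectors is summarized as a mean pairwise Jaccard index of
their selections across seeds (1 = identical selections every time).
"""

import numpy as np

from ficss import (
    CarsConfig,
    McuveConfig,
    SpaConfig,
    cars_select,
    generate,
    jaccard_stability,
    make_reference_scenario,
    mcuve_select,
    sg_filter,
    spa_select,
    split_calibration_prediction,
)

dataset, truth = generate(make_reference_scenario(), seed=7)
dataset = sg_filter(dataset)
dataset = split_calibration_prediction(dataset, seed=7)

results = {
    "CARS": cars_select(dataset, CarsConfig(), seed=0),
    "MC-UVE": mcuve_select(dataset, McuveConfig(n_mc_runs=100), seed=0),
    "SPA": spa_select(dataset, SpaConfig()),
}
for name, res in results.items():
    hit = truth.informative_mask[res.selected].mean()
    s = res.stats
    print(f"{name:7s} NFW={s.nfw:4d} NWI={s.nwi:3d} AWIW={s.awiw:6.2f} "
          f"informative fraction of selection: {100 * hit:.0f}%")

cars_runs = [cars_select(dataset, CarsConfig(), seed=s).selected for s in range(3)]
print(f"CARS selection Jaccard stability over 3 seeds: "
      f"{jaccard_stability(cars_runs):.2f} (stochastic)")
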