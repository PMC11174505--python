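"""Model-comparison protocol: full-spectrum baselines vs selector + ELM.

Produces a tidy table with one row per (model, analyte): calibration and
prediction RMSE/R², RPD, and the wavelength-selection statistics NFW, NWI
and AWIW for the selector-based models.  All model selection (PLS component
count, ELM hidden-node count, wavelength subsets) happens on the
calibration set only; the prediction set is touched exactly once per model,
at evaluation time.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .baseline_selectors import (
    CarsConfig,
    McuveConfig,
    SpaConfig,
    cars_select,
    mcuve_select,
    spa_select,
)
from .interval_selection import ELMScreener, SelectionResult, fic_ss_select
from .metrics import evaluate, selection_stats
from .regressors import (
    DEFAULT_NODE_GRID,
    choose_pls_components,
    elm_fit,
    elm_select_hidden_nodes,
    pls_fit,
)
from .spectra import SpectralDataset

__all__ = ["BenchmarkConfig", "train_elm", "run_benchmark", "SELECTOR_NAMES"]

SELECTOR_NAMES = ("fic-ss", "mc-uve", "spa", "cars")


@dataclass
class BenchmarkConfig:
    """Protocol sizes for one benchmark run.

    Defaults are scaled for a desk-size run: the ELM node search repeats 10
    random restarts per candidate (the stand-alone default is 50) and MC-UVE
    uses 100 Monte-Carlo runs (stand-alone default 500).
    """

    selectors: tuple[str, ...] = SELECTOR_NAMES
    p: int = 20
    q_cap: int = 12
    screener_hidden: int = 20
    screener_cv: int = 5
    pls_max_components: int = 15
    elm_grid: tuple[int, ...] = DEFAULT_NODE_GRID
    elm_repeats: int = 10
    elm_cv: int = 5
    cars: CarsConfig = field(default_factory=lambda: CarsConfig())
    mcuve: McuveConfig = field(default_factory=lambda: McuveConfig(n_mc_runs=100))
    spa: SpaConfig = field(default_factory=lambda: SpaConfig())


def train_elm(
    X: np.ndarray,
    C: np.ndarray,
    seed: int,
    grid: tuple[int, ...] = DEFAULT_NODE_GRID,
    repeats: int = 10,
    cv: int = 5,
):
    """Full ELM training protocol: node search, then best random draw.

    The hidden-node count is chosen by averaging k-fold CV RMSE over
    ``repeats`` random input layers per candidate; at the winning count the
    same number of candidate draws is scored again by CV and the draw with
    the lowest RMSE becomes the final model (the random input layer makes
    single draws unstable, so the lowest-RMSE structure is kept).  Returns
    (model, best_l, mean_rmse_by_l).
    """
    from sklearn.model_selection import KFold

    best_l, curve = elm_select_hidden_nodes(
        X, C, grid=grid, repeats=repeats, seed=seed, cv=cv
    )
    folds = list(KFold(n_splits=cv, shuffle=True, random_state=seed).split(X))
    sd = C.std(axis=0)
    sd = np.where(sd > 0, sd, 1.0)
    cand = [
        int(s.generate_state(1)[0] % (2**31))
        for s in np.random.SeedSequence(seed + 1).spawn(repeats)
    ]
    scores = []
    for s in cand:
        errs = []
        for tr, te in folds:
            m = elm_fit(X[tr], C[tr], best_l, seed=s)
            per = np.sqrt(np.mean((m.predict(X[te]) - C[te]) ** 2, axis=0))
            errs.append(np.mean(per / sd))
        scores.append(np.mean(errs))
    model = elm_fit(X, C, best_l, seed=cand[int(np.argmin(scores))])
    return model, best_l, curve


def _rows(name, ds, model, channels, analytes, sel_stats=None):
    cal, pred = ds.calibration(), ds.prediction()
    Xc = cal.absorbance[:, channels] if channels is not None else cal.absorbance
    Xp = pred.absorbance[:, channels] if channels is not None else pred.absorbance
    rep_c = evaluate(cal.targets, model.predict(Xc), analytes, phase="calibration")
    rep_p = evaluate(pred.targets, model.predict(Xp), analytes, phase="prediction")
    rows = []
    for j, a in enumerate(analytes):
        rows.append(
            {
                "model": name,
                "analyte": a,
                "NFW": sel_stats.nfw if sel_stats else len(ds.wavenumbers),
                "NWI": sel_stats.nwi if sel_stats else 1,
                "AWIW": round(sel_stats.awiw, 2) if sel_stats else float(len(ds.wavenumbers)),
                "RMSEC": rep_c.rmse[j],
                "Rc2": rep_c.r2[j],
                "RMSEP": rep_p.rmse[j],
                "Rp2": rep_p.r2[j],
                "RPD": rep_p.rpd[j],
            }
        )
    return rows


def run_benchmark(
    ds: SpectralDataset,
    seed: int = 0,
    config: BenchmarkConfig | None = None,
) -> tuple[pd.DataFrame, dict[str, SelectionResult]]:
    """Compare full-spectrum PLS and ELM with selector-ELM models.

    ``ds`` must carry a calibration/prediction split.  Returns the result
    table and the per-selector :class:`SelectionResult` objects.
    """
    config = config or BenchmarkConfig()
    if ds.split is None:
        raise ValueError("dataset needs a calibration/prediction split")
    cal = ds.calibration()
    analytes = ds.analyte_names
    ss = np.random.SeedSequence(seed)
    stage_seed = {
        name: int(s.generate_state(1)[0] % (2**31))
        for name, s in zip(
            ["elm_full", "cars", "mc-uve", "screener", "elm_sel"], ss.spawn(5)
        )
    }
    rows: list[dict] = []

    # full-spectrum PLS baseline
    k = choose_pls_components(
        cal.absorbance, cal.targets, max_components=config.pls_max_components,
        seed=stage_seed["screener"],
    )
    pls = pls_fit(cal.absorbance, cal.targets, k)
    rows += _rows("PLS (full spectrum)", ds, pls, None, analytes)

    # full-spectrum ELM
    elm, _, _ = train_elm(
        cal.absorbance, cal.targets, stage_seed["elm_full"],
        grid=config.elm_grid, repeats=config.elm_repeats, cv=config.elm_cv,
    )
    rows += _rows("ELM (full spectrum)", ds, elm, None, analytes)

    # selector + ELM models
    selections: dict[str, SelectionResult] = {}
    screener = ELMScreener(
        n_hidden=config.screener_hidden,
        cv=config.screener_cv,
        seed=stage_seed["screener"],
    )
    for sel_name in config.selectors:
        if sel_name == "fic-ss":
            result = fic_ss_select(ds, p=config.p, screener=screener, q_cap=config.q_cap)
        elif sel_name == "cars":
            result = cars_select(ds, config.cars, seed=stage_seed["cars"])
        elif sel_name == "mc-uve":
            result = mcuve_select(ds, config.mcuve, seed=stage_seed["mc-uve"])
        elif sel_name == "spa":
            result = spa_select(ds, config.spa)
        else:
            raise ValueError(f"unknown selector {sel_name!r}")
        selections[sel_name] = result
        ch = result.selected
        model, _, _ = train_elm(
            cal.absorbance[:, ch], cal.targets, stage_seed["elm_sel"],
            grid=config.elm_grid, repeats=config.elm_repeats, cv=config.elm_cv,
        )
        rows += _rows(
            f"{sel_name.upper()}-ELM", ds, model, ch, analytes,
            sel_stats=selection_stats(ch),
        )
    return pd.DataFrame(rows), selections
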