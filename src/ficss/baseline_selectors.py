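"""Baseline wavelength selectors: CARS, MC-UVE and SPA.

These are the standard comparison methods for interval/variable selection
in NIR calibration.  All three operate on the calibration samples only and
return a :class:`~ficss.interval_selection.SelectionResult`, so downstream
model training is selector-agnostic.

CARS (competitive adaptive reweighted sampling) runs a fixed number of
Monte-Carlo iterations; at each one a PLS model fit on a random sample
subset weighs channels by absolute regression coefficient, an exponentially
decreasing function dictates how many channels survive, and adaptive
reweighted sampling resolves which; the iteration subset with the smallest
cross-validated RMSE wins.

MC-UVE (Monte-Carlo uninformative variable elimination) scores each channel
by the stability (mean/std) of its PLS coefficient over many random
subsamples and discards channels whose stability does not exceed that of
appended pure-noise channels.

SPA (successive projections algorithm) greedily grows chains of channels
with minimal collinearity — each step adds the channel with the largest
component orthogonal to the span of those already chosen — and keeps the
chain length/start with the smallest cross-validated MLR RMSE.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from sklearn.model_selection import KFold

from .interval_selection import SelectionResult
from .metrics import selection_stats
from .regressors import pls_fit
from .spectra import SpectralDataset

__all__ = [
    "CarsConfig",
    "McuveConfig",
    "SpaConfig",
    "cars_select",
    "mcuve_select",
    "spa_select",
    "jaccard_stability",
]


@dataclass
class CarsConfig:
    n_iterations: int = 100       # Monte-Carlo sampling runs
    subsample: float = 0.9        # fraction of calibration samples per run
    cv_folds: int = 5
    n_components: int = 10
    min_channels: int = 2


@dataclass
class McuveConfig:
    n_mc_runs: int = 500
    subsample: float = 0.8
    n_noise_vars: int | None = None   # default: as many as real channels
    cutoff_quantile: float = 0.99     # of the noise-channel stabilities
    n_components: int = 10


@dataclass
class SpaConfig:
    max_vars: int = 30
    n_starts: int = 20                # evenly spaced candidate start columns
    cv_folds: int = 5
    tol: float = 1e-10


def _cal_xy(ds: SpectralDataset) -> tuple[np.ndarray, np.ndarray]:
    if ds.split is None:
        raise ValueError("dataset needs a calibration/prediction split")
    cal = ds.calibration()
    return cal.absorbance, cal.targets


def _cv_rmse(X, Y, channels, n_components, folds) -> float:
    """Scaled aggregate CV RMSE of a PLS model on a channel subset."""
    sd = Y.std(axis=0)
    sd = np.where(sd > 0, sd, 1.0)
    Xs = X[:, channels]
    err = np.zeros(Y.shape[1])
    for tr, te in folds:
        k = min(n_components, len(tr) - 1, Xs.shape[1])
        m = pls_fit(Xs[tr], Y[tr], k)
        err += np.mean((m.predict(Xs[te]) - Y[te]) ** 2, axis=0) * len(te)
    err /= X.shape[0]
    return float(np.mean(np.sqrt(err) / sd))


def _coef_weights(X, Y, n_components) -> np.ndarray:
    """Channel weights: summed |PLS coefficient| across sd-scaled analytes."""
    sd = Y.std(axis=0)
    Ys = Y / np.where(sd > 0, sd, 1.0)
    k = min(n_components, X.shape[0] - 1, X.shape[1])
    m = pls_fit(X, Ys, k)
    return np.abs(m.coef_).sum(axis=1)


def cars_select(
    ds: SpectralDataset, cfg: CarsConfig | None = None, seed: int = 0
) -> SelectionResult:
    """Competitive adaptive reweighted sampling selection."""
    cfg = cfg or CarsConfig()
    X, Y = _cal_xy(ds)
    n, p = X.shape
    if p < cfg.min_channels:
        raise ValueError("fewer channels than the minimum retention")
    rng = np.random.default_rng(seed)
    n_sub = max(2, int(round(cfg.subsample * n)))
    N = cfg.n_iterations
    # two-point exponentially decreasing function: all p channels at run 1,
    # min_channels at run N
    if N > 1:
        k = np.log(p / cfg.min_channels) / (N - 1)
        ratios = np.exp(-k * np.arange(N))
    else:
        ratios = np.array([1.0])
    retain_counts = np.maximum(
        np.round(ratios * p).astype(int), cfg.min_channels
    )
    folds = list(
        KFold(n_splits=cfg.cv_folds, shuffle=True, random_state=seed).split(X)
    )
    current = np.arange(p)
    best_subset, best_rmse = None, np.inf
    history = []
    for it in range(N):
        rows = rng.choice(n, size=n_sub, replace=False)
        w = _coef_weights(X[np.ix_(rows, current)], Y[rows], cfg.n_components)
        n_keep = min(retain_counts[it], len(current))
        # enforced retention by weight rank
        top = current[np.argsort(w, kind="stable")[::-1][:n_keep]]
        # adaptive reweighted sampling among the retained channels
        wt = w[np.argsort(w, kind="stable")[::-1][:n_keep]]
        if wt.sum() > 0 and n_keep > cfg.min_channels:
            picks = rng.choice(top, size=n_keep, replace=True, p=wt / wt.sum())
            sampled = np.unique(picks)
            if len(sampled) >= cfg.min_channels:
                top = sampled
        current = np.sort(top)
        score = _cv_rmse(X, Y, current, cfg.n_components, folds)
        history.append({"iteration": it, "n_channels": len(current), "cv_rmse": score})
        if score < best_rmse:
            best_rmse, best_subset = score, current.copy()
    assert best_subset is not None
    return SelectionResult(
        selected=np.sort(best_subset),
        method="cars",
        stats=selection_stats(best_subset),
        provenance={"seed": seed, "best_cv_rmse": best_rmse, "history": history},
    )


def mcuve_select(
    ds: SpectralDataset, cfg: McuveConfig | None = None, seed: int = 0
) -> SelectionResult:
    """Monte-Carlo uninformative variable elimination."""
    cfg = cfg or McuveConfig()
    if cfg.n_mc_runs < 2:
        raise ValueError("n_mc_runs must be >= 2 (stability needs a std)")
    X, Y = _cal_xy(ds)
    n, p = X.shape
    rng = np.random.default_rng(seed)
    n_noise = cfg.n_noise_vars if cfg.n_noise_vars is not None else p
    noise = rng.standard_normal((n, n_noise)) * (X.std() if X.std() > 0 else 1.0)
    Xa = np.hstack([X, noise])
    sd = Y.std(axis=0)
    Ys = Y / np.where(sd > 0, sd, 1.0)
    n_sub = max(2, int(round(cfg.subsample * n)))
    coefs = np.empty((cfg.n_mc_runs, Xa.shape[1], Y.shape[1]))
    for r in range(cfg.n_mc_runs):
        rows = rng.choice(n, size=n_sub, replace=False)
        k = min(cfg.n_components, n_sub - 1, Xa.shape[1])
        m = pls_fit(Xa[rows], Ys[rows], k)
        coefs[r] = m.coef_
    mean = coefs.mean(axis=0)
    std = coefs.std(axis=0, ddof=1)
    zero_std = std == 0
    if np.any(zero_std):
        warnings.warn("zero coefficient std for some channels: stability set to inf")
    stability = np.where(
        zero_std, np.inf * np.sign(mean), np.divide(mean, np.where(zero_std, 1, std))
    )
    score = np.abs(stability).max(axis=1)          # shared across analytes
    cutoff = float(np.quantile(score[p:], cfg.cutoff_quantile))
    selected = np.flatnonzero(score[:p] > cutoff)
    if selected.size == 0:
        raise ValueError("MC-UVE eliminated every channel; lower the cutoff quantile")
    return SelectionResult(
        selected=selected,
        method="mc-uve",
        stats=selection_stats(selected),
        provenance={
            "seed": seed,
            "cutoff": cutoff,
            "n_mc_runs": cfg.n_mc_runs,
            "stability_real": score[:p],
            "stability_noise_max": float(score[p:].max()),
        },
    )


def _spa_chain(Xc: np.ndarray, start: int, max_vars: int, tol: float) -> list[int]:
    """Greedy orthogonal-projection chain from one start column."""
    p = Xc.shape[1]
    norms0 = np.linalg.norm(Xc, axis=0)
    chain = [start]
    R = Xc.copy()
    # deflate by the chosen column each step
    for _ in range(max_vars - 1):
        v = R[:, chain[-1]]
        nv = np.linalg.norm(v)
        if nv <= tol * max(norms0.max(), 1.0):
            break
        u = v / nv
        R = R - np.outer(u, u @ R)
        norms = np.linalg.norm(R, axis=0)
        norms[chain] = -1.0
        nxt = int(np.argmax(norms))    # argmax takes the lowest index on ties
        if norms[nxt] <= tol * max(norms0.max(), 1.0):
            warnings.warn("residual norms vanished before max_vars; stopping early")
            break
        chain.append(nxt)
    return chain


def _mlr_cv_rmse(X, Y, channels, folds) -> float:
    sd = Y.std(axis=0)
    sd = np.where(sd > 0, sd, 1.0)
    Xs = X[:, channels]
    err = np.zeros(Y.shape[1])
    for tr, te in folds:
        A = np.hstack([np.ones((len(tr), 1)), Xs[tr]])
        B, *_ = np.linalg.lstsq(A, Y[tr], rcond=None)
        At = np.hstack([np.ones((len(te), 1)), Xs[te]])
        err += np.mean((At @ B - Y[te]) ** 2, axis=0) * len(te)
    err /= X.shape[0]
    return float(np.mean(np.sqrt(err) / sd))


def spa_select(ds: SpectralDataset, cfg: SpaConfig | None = None) -> SelectionResult:
    """Successive projections algorithm selection (deterministic)."""
    cfg = cfg or SpaConfig()
    X, Y = _cal_xy(ds)
    n, p = X.shape
    max_vars = min(cfg.max_vars, n - 2, p)
    if max_vars < 1:
        raise ValueError("max_vars must allow at least one channel")
    Xc = X - X.mean(axis=0)
    starts = np.unique(np.linspace(0, p - 1, min(cfg.n_starts, p)).astype(int))
    folds = list(KFold(n_splits=cfg.cv_folds, shuffle=True, random_state=0).split(X))
    best_sel, best_rmse = None, np.inf
    for s in starts:
        chain = _spa_chain(Xc, int(s), max_vars, cfg.tol)
        for length in range(1, len(chain) + 1):
            sel = sorted(chain[:length])
            score = _mlr_cv_rmse(X, Y, sel, folds)
            if score < best_rmse - 1e-15:
                best_rmse, best_sel = score, sel
    assert best_sel is not None
    selected = np.asarray(best_sel, dtype=int)
    return SelectionResult(
        selected=selected,
        method="spa",
        stats=selection_stats(selected),
        provenance={"best_cv_rmse": best_rmse, "n_starts": len(starts)},
    )


def jaccard_stability(selections: list[np.ndarray]) -> float:
    """Mean pairwise Jaccard index of selections across seeds.

    Quantifies the run-to-run randomness of stochastic selectors (1 =
    identical selections every run).
    """
    sets = [set(int(i) for i in s) for s in selections]
    if len(sets) < 2:
        raise ValueError("need at least two selections")
    vals = []
    for i in range(len(sets)):
        for j in range(i + 1, len(sets)):
            union = sets[i] | sets[j]
            vals.append(len(sets[i] & sets[j]) / len(union) if union else 1.0)
    return float(np.mean(vals))
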