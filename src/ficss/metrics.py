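"""Calibration figures of merit and wavelength-selection statistics.

RMSE, R² and the residual prediction deviation RPD = 1/sqrt(1 - R²) score a
calibration (RMSEC/Rc² on the training phase, RMSEP/Rp² on held-out
prediction samples; RPD >= 3 conventionally marks a usable calibration).
Selection statistics summarize a chosen wavelength set: NFW (number of
feature wavelengths), NWI (number of maximal contiguous wavelength
intervals) and AWIW = NFW/NWI, the average interval width.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, asdict

import numpy as np

__all__ = [
    "rmse",
    "r_squared",
    "rpd",
    "aggregate_rmse",
    "evaluate",
    "EvaluationReport",
    "SelectionStats",
    "selection_stats",
]


def rmse(y_true: np.ndarray, y_pred: np.ndarray) -> float:
    """Root-mean-square error sqrt(sum((yhat - y)^2) / n)."""
    y_true = np.asarray(y_true, dtype=float).ravel()
    y_pred = np.asarray(y_pred, dtype=float).ravel()
    if y_true.size == 0:
        raise ValueError("empty input")
    if y_true.shape != y_pred.shape:
        raise ValueError("y_true and y_pred lengths differ")
    return float(np.sqrt(np.mean((y_pred - y_true) ** 2)))


def r_squared(y_true: np.ndarray, y_pred: np.ndarray) -> float:
    """Coefficient of determination 1 - SSres/SStot.

    SStot is taken about the mean of the measured values; a constant
    measured vector has no variance to explain and is rejected.
    """
    y_true = np.asarray(y_true, dtype=float).ravel()
    y_pred = np.asarray(y_pred, dtype=float).ravel()
    if y_true.size < 2:
        raise ValueError("need at least 2 samples")
    if y_true.shape != y_pred.shape:
        raise ValueError("y_true and y_pred lengths differ")
    ss_tot = float(np.sum((y_true - y_true.mean()) ** 2))
    if ss_tot == 0:
        raise ValueError("y_true is constant: R^2 undefined")
    ss_res = float(np.sum((y_pred - y_true) ** 2))
    return 1.0 - ss_res / ss_tot


def rpd(r2: float) -> float:
    """Residual prediction deviation from R²: 1/sqrt(1 - R²).

    Equivalent to SD(y)/SEP for a bias-free prediction.  At R² >= 1 the
    deviation is unbounded; an infinity sentinel is returned with a warning.
    """
    if r2 >= 1.0:
        warnings.warn("R^2 >= 1: RPD unbounded, returning inf", stacklevel=2)
        return math.inf
    return 1.0 / math.sqrt(1.0 - r2)


def aggregate_rmse(
    y_true: np.ndarray, y_pred: np.ndarray, scale: np.ndarray | None = None
) -> float:
    """Mean per-analyte RMSE, each analyte scaled to comparable units.

    ``scale`` defaults to the per-analyte standard deviation of ``y_true``;
    it lets analytes with very different concentration ranges contribute
    equally when ranking wavelength subsets across analytes.
    """
    y_true = np.atleast_2d(np.asarray(y_true, dtype=float))
    y_pred = np.atleast_2d(np.asarray(y_pred, dtype=float))
    if scale is None:
        scale = y_true.std(axis=0)
    scale = np.where(np.asarray(scale, dtype=float) > 0, scale, 1.0)
    per = np.sqrt(np.mean((y_pred - y_true) ** 2, axis=0))
    return float(np.mean(per / scale))


@dataclass
class EvaluationReport:
    """Per-analyte calibration scores for one evaluation phase."""

    phase: str                      # "calibration" or "prediction"
    n: int
    analyte_names: list[str]
    rmse: list[float]
    r2: list[float]
    rpd: list[float]

    def as_dict(self) -> dict:
        return asdict(self)


def evaluate(
    y_true: np.ndarray,
    y_pred: np.ndarray,
    analyte_names: list[str],
    phase: str = "prediction",
) -> EvaluationReport:
    """Score a multi-analyte prediction, one RMSE/R²/RPD triple per analyte."""
    y_true = np.atleast_2d(np.asarray(y_true, dtype=float))
    y_pred = np.atleast_2d(np.asarray(y_pred, dtype=float))
    return EvaluationReport(
        phase=phase,
        n=y_true.shape[0],
        analyte_names=list(analyte_names),
        rmse=[rmse(y_true[:, j], y_pred[:, j]) for j in range(y_true.shape[1])],
        r2=[r_squared(y_true[:, j], y_pred[:, j]) for j in range(y_true.shape[1])],
        rpd=[rpd(r_squared(y_true[:, j], y_pred[:, j])) for j in range(y_true.shape[1])],
    )


@dataclass
class SelectionStats:
    """Size/shape summary of a selected wavelength set."""

    nfw: int    # number of selected wavelengths
    nwi: int    # number of maximal contiguous index runs
    awiw: float  # nfw / nwi

    def as_dict(self) -> dict:
        return asdict(self)


def selection_stats(selected) -> SelectionStats:
    """NFW/NWI/AWIW for a set of selected channel indices.

    An interval is a maximal run of consecutive indices; AWIW is the mean
    number of wavelengths per interval.
    """
    idx = np.unique(np.asarray(list(selected), dtype=int))
    if idx.size == 0:
        raise ValueError("empty selection")
    if np.any(idx < 0):
        raise ValueError("negative channel index")
    nwi = int(1 + np.sum(np.diff(idx) > 1))
    nfw = int(idx.size)
    return SelectionStats(nfw=nfw, nwi=nwi, awiw=nfw / nwi)
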