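"""Feature interval combination sensitivity segmentation (FIC-SS).

The selector works in two tiers.  Coarse-grained: the wavelength axis is cut
into p equal-width sub-intervals; each is scored by a local calibration
model against full-spectrum thresholds, surviving intervals are combined
exhaustively, and the union of intervals with the lowest aggregate RMSE
wins.  Fine-grained: within the winning combination, each channel gets a
sensitivity factor per analyte — the analyte's unit-content absorbance
divided by the summed unit-content absorbance of all analytes at that
channel — and channels whose factor falls below the interval's mean factor
for every target analyte are pruned.  The result is a compact wavelength
set focused on channels where at least one analyte's signal stands out from
the overlap.

Unit-content spectra are not measured directly; they are estimated by a
per-channel non-negative regression of absorbance on the concentration
vectors (a classical-least-squares estimate), which is adequate whenever
the concentration design matrix is well conditioned.
"""

from __future__ import annotations

import itertools
import json
import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy.optimize import nnls
from sklearn.model_selection import KFold

from .metrics import SelectionStats, selection_stats
from .regressors import elm_fit, pls_fit
from .spectra import SpectralDataset

__all__ = [
    "IntervalPartition",
    "IntervalScore",
    "IntervalCombination",
    "SensitivityProfile",
    "SelectionResult",
    "PLSScreener",
    "ELMScreener",
    "partition_spectrum",
    "global_thresholds",
    "screen_intervals",
    "combine_intervals",
    "estimate_unit_spectra",
    "sensitivity_factors",
    "sensitivity_segment",
    "fic_ss_select",
]


# ---------------------------------------------------------------------------
# types
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class IntervalPartition:
    """p contiguous half-open index ranges covering the channel axis."""

    p: int
    boundaries: tuple[tuple[int, int], ...]

    def channels(self, interval_id: int) -> np.ndarray:
        start, end = self.boundaries[interval_id]
        return np.arange(start, end)

    def union(self, interval_ids) -> np.ndarray:
        return np.concatenate([self.channels(i) for i in sorted(interval_ids)])


@dataclass
class IntervalScore:
    """Local-model scores for one sub-interval (one value per analyte)."""

    interval_id: int
    rmse: np.ndarray
    r2: np.ndarray
    survived: bool


@dataclass
class IntervalCombination:
    """A union of surviving sub-intervals with its screener scores."""

    members: tuple[int, ...]
    rmse: float                 # cross-analyte aggregate (scaled units)
    per_analyte_rmse: np.ndarray
    per_analyte_r2: np.ndarray


@dataclass
class SensitivityProfile:
    """Per-channel, per-analyte sensitivity factors.

    ``alpha[a, ch]`` = unit_spectra[a, ch] / sum_a unit_spectra[a, ch];
    the factors sum to 1 over analytes at every absorbing channel.  Channels
    with zero total unit absorbance get alpha 0 everywhere and are flagged.
    """

    unit_spectra: np.ndarray      # (n_analytes, n_channels), non-negative
    alpha: np.ndarray             # (n_analytes, n_channels) in [0, 1]
    zero_channels: np.ndarray     # bool mask of non-absorbing channels


@dataclass
class SelectionResult:
    """Final selected channels plus stage-by-stage provenance."""

    selected: np.ndarray                 # sorted channel indices
    method: str
    stats: SelectionStats
    provenance: dict = field(default_factory=dict)

    def to_json(self, wavenumbers: np.ndarray | None = None) -> str:
        payload = {
            "method": self.method,
            "selected_channels": [int(i) for i in self.selected],
            "stats": self.stats.as_dict(),
            "provenance": _jsonable(self.provenance),
        }
        if wavenumbers is not None:
            payload["selected_wavenumbers"] = [
                float(wavenumbers[i]) for i in self.selected
            ]
        return json.dumps(payload, indent=2)

    @classmethod
    def from_json(cls, text: str) -> "SelectionResult":
        d = json.loads(text)
        sel = np.asarray(d["selected_channels"], dtype=int)
        return cls(
            selected=sel,
            method=d["method"],
            stats=SelectionStats(**d["stats"]),
            provenance=d.get("provenance", {}),
        )


def _jsonable(obj):
    if isinstance(obj, dict):
        return {str(k): _jsonable(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_jsonable(v) for v in obj]
    if isinstance(obj, np.ndarray):
        return obj.tolist()
    if isinstance(obj, (np.integer,)):
        return int(obj)
    if isinstance(obj, (np.floating,)):
        return float(obj)
    return obj


# ---------------------------------------------------------------------------
# screener
# ---------------------------------------------------------------------------

class PLSScreener:
    """Cross-validated PLS scorer used to rate channel subsets.

    Scores are k-fold cross-validation statistics on the calibration set
    (the prediction set never enters the search).  The component count is
    capped by the data dimensions; the screener is deterministic for a
    fixed configuration (no run-to-run randomness).
    """

    def __init__(self, n_components: int = 10, cv: int = 5, seed: int = 0):
        self.n_components = n_components
        self.cv = cv
        self.seed = seed

    def crossval(self, X: np.ndarray, Y: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
        """Per-analyte (rmse, r2) from out-of-fold predictions."""
        X = np.atleast_2d(np.asarray(X, dtype=float))
        Y = np.atleast_2d(np.asarray(Y, dtype=float))
        folds = KFold(n_splits=self.cv, shuffle=True, random_state=self.seed)
        pred = np.empty_like(Y)
        for tr, te in folds.split(X):
            k = min(self.n_components, len(tr) - 1, X.shape[1])
            model = pls_fit(X[tr], Y[tr], k)
            pred[te] = model.predict(X[te])
        resid = pred - Y
        rmse_ = np.sqrt(np.mean(resid**2, axis=0))
        sst = np.sum((Y - Y.mean(axis=0)) ** 2, axis=0)
        r2_ = 1.0 - np.sum(resid**2, axis=0) / sst
        return rmse_, r2_


class ELMScreener:
    """Cross-validated ELM scorer used to rate channel subsets (default).

    Small fixed-size ELMs are cross-validated on the calibration set, with
    a couple of random-restart repetitions averaged to tame the random
    input layer.  All seeds are derived from the configured seed, so the
    screener is deterministic end to end.

    This screener, not the PLS one, is the default for interval screening:
    an ELM's random projections are diluted by every redundant channel they
    mix in, so its full-spectrum cross-validation score genuinely reflects
    the cost of carrying 1500 channels, and informative sub-intervals beat
    it reliably.  A cross-validated PLS is so effective at projecting out
    irrelevant channels that its full-spectrum score dominates every local
    interval and the screening stage would eliminate everything.
    """

    def __init__(
        self, n_hidden: int = 20, cv: int = 5, seed: int = 0, restarts: int = 2
    ):
        self.n_hidden = n_hidden
        self.cv = cv
        self.seed = seed
        self.restarts = restarts

    def crossval(self, X: np.ndarray, Y: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
        """Per-analyte (rmse, r2), averaged over random restarts."""
        X = np.atleast_2d(np.asarray(X, dtype=float))
        Y = np.atleast_2d(np.asarray(Y, dtype=float))
        n = X.shape[0]
        folds = list(
            KFold(n_splits=self.cv, shuffle=True, random_state=self.seed).split(X)
        )
        sse = np.zeros(Y.shape[1])
        for r in range(self.restarts):
            pred = np.empty_like(Y)
            for tr, te in folds:
                l = min(self.n_hidden, len(tr) - 1)
                m = elm_fit(X[tr], Y[tr], l, seed=self.seed + 7919 * r)
                pred[te] = m.predict(X[te])
            sse += np.sum((pred - Y) ** 2, axis=0)
        sse /= self.restarts
        sst = np.sum((Y - Y.mean(axis=0)) ** 2, axis=0)
        return np.sqrt(sse / n), 1.0 - sse / sst


#: anything with a ``crossval(X, Y) -> (rmse, r2)`` method
Screener = PLSScreener | ELMScreener


# ---------------------------------------------------------------------------
# coarse-grained stage
# ---------------------------------------------------------------------------

def partition_spectrum(n_channels: int, p: int) -> IntervalPartition:
    """Cut the channel axis into p contiguous intervals of near-equal width.

    When p does not divide n_channels, the remainder channels are handed one
    each to the leading intervals, so widths differ by at most 1.
    """
    if not 1 <= p <= n_channels:
        raise ValueError(f"p must be in [1, {n_channels}]")
    base, rem = divmod(n_channels, p)
    boundaries = []
    start = 0
    for i in range(p):
        width = base + (1 if i < rem else 0)
        boundaries.append((start, start + width))
        start += width
    return IntervalPartition(p=p, boundaries=tuple(boundaries))


def _calibration(ds: SpectralDataset) -> SpectralDataset:
    if ds.split is None:
        raise ValueError("dataset needs a calibration/prediction split")
    return ds.calibration()


def global_thresholds(
    ds: SpectralDataset, screener: Screener | None = None
) -> tuple[np.ndarray, np.ndarray]:
    """Full-spectrum screener scores used as interval-survival thresholds.

    Returns per-analyte (RMSE, R²) of the screener cross-validated on the
    calibration set over all channels.
    """
    screener = screener or ELMScreener()
    cal = _calibration(ds)
    return screener.crossval(cal.absorbance, cal.targets)


def screen_intervals(
    ds: SpectralDataset,
    partition: IntervalPartition,
    thresholds: tuple[np.ndarray, np.ndarray],
    screener: Screener | None = None,
) -> list[IntervalScore]:
    """Score every sub-interval with a local model and flag the survivors.

    An interval survives when, for at least one analyte, its local RMSE is
    at or below the global RMSE *and* its local R² is at or above the global
    R² (inclusive comparisons, so boundary intervals survive).
    """
    screener = screener or ELMScreener()
    cal = _calibration(ds)
    g_rmse, g_r2 = thresholds
    scores = []
    for i in range(partition.p):
        ch = partition.channels(i)
        rmse_i, r2_i = screener.crossval(cal.absorbance[:, ch], cal.targets)
        survived = bool(np.any((rmse_i <= g_rmse) & (r2_i >= g_r2)))
        scores.append(IntervalScore(interval_id=i, rmse=rmse_i, r2=r2_i, survived=survived))
    if not any(s.survived for s in scores):
        raise ValueError(
            "no interval beat the full-spectrum thresholds; try a larger p "
            "or a weaker screener"
        )
    return scores


def combine_intervals(
    ds: SpectralDataset,
    partition: IntervalPartition,
    survivor_ids,
    screener: Screener | None = None,
    q_cap: int = 12,
    survivor_rank: np.ndarray | None = None,
) -> IntervalCombination:
    """Exhaustively score all non-empty unions of surviving intervals.

    Each of the 2^q - 1 subsets is rated by the screener's cross-validated
    aggregate RMSE (mean of per-analyte RMSEs scaled by the calibration
    standard deviation of each analyte, so analytes weigh equally).  Ties at
    1e-12 resolve to fewer channels, then lower interval ids.  If q exceeds
    ``q_cap`` the q_cap best-ranked survivors are kept first.
    """
    screener = screener or ELMScreener()
    survivor_ids = sorted(int(i) for i in survivor_ids)
    if not survivor_ids:
        raise ValueError("no surviving intervals to combine")
    if len(survivor_ids) > q_cap:
        if survivor_rank is None:
            raise ValueError(
                f"{len(survivor_ids)} survivors exceed q_cap={q_cap}; provide "
                "survivor_rank (e.g. best per-analyte scaled RMSE) to cap"
            )
        order = np.argsort(survivor_rank, kind="stable")[:q_cap]
        survivor_ids = sorted(survivor_ids[i] for i in order)
    cal = _calibration(ds)
    sd = cal.targets.std(axis=0)
    best: IntervalCombination | None = None
    best_key: tuple | None = None
    for t in range(1, len(survivor_ids) + 1):
        for members in itertools.combinations(survivor_ids, t):
            ch = partition.union(members)
            rmse_i, r2_i = screener.crossval(cal.absorbance[:, ch], cal.targets)
            agg = float(np.mean(rmse_i / np.where(sd > 0, sd, 1.0)))
            key = (round(agg / 1e-12), len(ch), members)
            if best_key is None or key < best_key:
                best_key = key
                best = IntervalCombination(
                    members=members,
                    rmse=agg,
                    per_analyte_rmse=rmse_i,
                    per_analyte_r2=r2_i,
                )
    assert best is not None
    return best


# ---------------------------------------------------------------------------
# fine-grained stage
# ---------------------------------------------------------------------------

def estimate_unit_spectra(
    ds: SpectralDataset, include_offset: bool = True
) -> np.ndarray:
    """Per-analyte unit-content absorbance via channel-wise NNLS.

    Solves ``absorbance[:, ch] ~ targets @ s (+ offset)`` with s >= 0 for
    every channel over the calibration samples (all samples if the dataset
    is unsplit).  The non-negative offset column (default on) absorbs any
    additive baseline; without it a baseline biases every channel's
    estimates upward, because the positive-mean concentrations can mimic a
    constant.
    """
    cal = ds.calibration() if ds.split is not None else ds
    Ct = cal.targets
    if np.linalg.matrix_rank(Ct) < Ct.shape[1]:
        raise ValueError("analyte concentrations are collinear: unit spectra unidentifiable")
    n_analytes, n_channels = Ct.shape[1], cal.n_channels
    design = np.hstack([Ct, np.ones((Ct.shape[0], 1))]) if include_offset else Ct
    S = np.empty((n_analytes, n_channels))
    for ch in range(n_channels):
        coef, _ = nnls(design, cal.absorbance[:, ch])
        S[:, ch] = coef[:n_analytes]
    return S


def sensitivity_factors(unit_spectra: np.ndarray) -> SensitivityProfile:
    """Normalize unit spectra into per-channel sensitivity factors.

    At each channel the factors across analytes sum to 1; channels where no
    analyte absorbs are flagged and get factor 0 everywhere.
    """
    S = np.atleast_2d(np.asarray(unit_spectra, dtype=float))
    if np.any(S < 0):
        raise ValueError("unit spectra must be non-negative")
    total = S.sum(axis=0)
    zero = total <= 0
    alpha = np.zeros_like(S)
    np.divide(S, total, out=alpha, where=~zero)
    return SensitivityProfile(unit_spectra=S, alpha=alpha, zero_channels=zero)


def sensitivity_segment(
    partition: IntervalPartition,
    combination: IntervalCombination,
    profile: SensitivityProfile,
    analytes: list[int] | None = None,
) -> SelectionResult:
    """Prune the optimal combination channel-by-channel by sensitivity.

    Within each member interval, a channel is retained when at least one
    target analyte's factor is at or above that analyte's mean factor over
    the interval (ties keep).  The shared multi-analyte selection uses all
    analytes; passing a subset gives the per-analyte variant, which prunes
    channels dominated by non-target interferents.
    """
    if not combination.members:
        raise ValueError("empty combination")
    n_analytes = profile.alpha.shape[0]
    targets = list(range(n_analytes)) if analytes is None else list(analytes)
    kept: list[np.ndarray] = []
    interval_means: dict[int, np.ndarray] = {}
    for i in combination.members:
        ch = partition.channels(i)
        means = profile.alpha[:, ch].mean(axis=1)
        interval_means[i] = means
        keep = np.zeros(len(ch), dtype=bool)
        for a in targets:
            keep |= profile.alpha[a, ch] >= means[a]
        keep &= ~profile.zero_channels[ch]
        kept.append(ch[keep])
    selected = np.sort(np.concatenate(kept)) if kept else np.array([], dtype=int)
    if selected.size == 0:
        raise ValueError("sensitivity segmentation pruned every channel")
    return SelectionResult(
        selected=selected,
        method="fic-ss",
        stats=selection_stats(selected),
        provenance={
            "combination_members": list(combination.members),
            "interval_mean_alpha": {i: m for i, m in interval_means.items()},
            "target_analytes": targets,
        },
    )


# ---------------------------------------------------------------------------
# full pipeline
# ---------------------------------------------------------------------------

def fic_ss_select(
    ds: SpectralDataset,
    p: int = 20,
    screener: Screener | None = None,
    q_cap: int = 12,
    analytes: list[int] | None = None,
) -> SelectionResult:
    """Run the full coarse+fine selection and return the channel set.

    Stages: full-spectrum thresholds -> p-interval screening -> exhaustive
    combination of the q survivors -> sensitivity-factor pruning of the
    optimal combination.  Deterministic for a deterministic screener;
    stage-by-stage provenance is recorded in the result.
    """
    screener = screener or ELMScreener()
    if p == ds.n_channels:
        warnings.warn(
            "p equals the channel count: degenerates to per-channel screening",
            stacklevel=2,
        )
    partition = partition_spectrum(ds.n_channels, p)
    thresholds = global_thresholds(ds, screener)
    scores = screen_intervals(ds, partition, thresholds, screener)
    survivors = [s for s in scores if s.survived]
    cal = _calibration(ds)
    sd = cal.targets.std(axis=0)
    rank = np.array(
        [np.min(s.rmse / np.where(sd > 0, sd, 1.0)) for s in survivors]
    )
    combo = combine_intervals(
        ds,
        partition,
        [s.interval_id for s in survivors],
        screener,
        q_cap=q_cap,
        survivor_rank=rank,
    )
    unit = estimate_unit_spectra(ds)
    profile = sensitivity_factors(unit)
    result = sensitivity_segment(partition, combo, profile, analytes=analytes)
    result.provenance.update(
        {
            "p": p,
            "global_rmse": thresholds[0],
            "global_r2": thresholds[1],
            "interval_scores": [
                {
                    "interval_id": s.interval_id,
                    "rmse": s.rmse,
                    "r2": s.r2,
                    "survived": s.survived,
                }
                for s in scores
            ],
            "survivor_ids": [s.interval_id for s in survivors],
            "combination_rmse": combo.rmse,
            "combination_channels": partition.union(combo.members),
        }
    )
    return result
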