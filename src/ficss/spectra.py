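"""Data model and preprocessing for multi-analyte NIR spectral datasets.

A dataset couples an absorbance matrix (samples x wavelength channels, with
a wavenumber axis in cm^-1) to a matrix of per-sample analyte concentrations
(e.g. the four catechin monomers EC, ECG, EGC, EGCG in tea, as % dry mass).
Spectra are stored as absorbance A = log10(1/R); preprocessing is limited to
Savitzky-Golay smoothing, matching common practice for diffuse-reflectance
NIR calibration work.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
from scipy.signal import savgol_filter

CALIBRATION = "calibration"
PREDICTION = "prediction"

__all__ = [
    "SpectralDataset",
    "read_dataset",
    "write_dataset",
    "absorbance_from_reflectance",
    "sg_filter",
    "split_calibration_prediction",
    "pca_summary",
    "CALIBRATION",
    "PREDICTION",
]


class AlignmentError(ValueError):
    """Spectra and target files disagree on sample ids."""


@dataclass
class SpectralDataset:
    """Absorbance spectra with aligned analyte concentrations.

    Parameters
    ----------
    wavenumbers : (n_channels,) strictly increasing axis in cm^-1.
    absorbance : (n_samples, n_channels) unitless absorbance values.
    targets : (n_samples, n_analytes) concentrations (non-negative).
    analyte_names : ordered analyte labels.
    sample_ids : unique per-sample labels.
    split : optional per-sample flag, "calibration" or "prediction".
    """

    wavenumbers: np.ndarray
    absorbance: np.ndarray
    targets: np.ndarray
    analyte_names: list[str]
    sample_ids: list[str]
    split: np.ndarray | None = field(default=None)

    def __post_init__(self) -> None:
        self.wavenumbers = np.asarray(self.wavenumbers, dtype=float)
        self.absorbance = np.atleast_2d(np.asarray(self.absorbance, dtype=float))
        self.targets = np.atleast_2d(np.asarray(self.targets, dtype=float))
        self.analyte_names = list(self.analyte_names)
        self.sample_ids = [str(s) for s in self.sample_ids]
        n, k = self.absorbance.shape
        if self.targets.shape[0] != n:
            raise ValueError(
                f"targets has {self.targets.shape[0]} rows, absorbance has {n}"
            )
        if len(self.wavenumbers) != k:
            raise ValueError(
                f"{len(self.wavenumbers)} wavenumbers but {k} absorbance columns"
            )
        if self.targets.shape[1] != len(self.analyte_names):
            raise ValueError("analyte_names length does not match targets columns")
        if len(self.sample_ids) != n:
            raise ValueError("sample_ids length does not match sample count")
        if len(set(self.sample_ids)) != n:
            raise ValueError("sample_ids must be unique")
        if np.any(np.diff(self.wavenumbers) <= 0):
            raise ValueError("wavenumbers must be strictly increasing")
        if not np.all(np.isfinite(self.absorbance)):
            raise ValueError("absorbance contains non-finite values")
        if not np.all(np.isfinite(self.targets)):
            raise ValueError("targets contain non-finite values")
        if np.any(self.targets < 0):
            raise ValueError("targets must be non-negative concentrations")
        if self.split is not None:
            self.split = np.asarray(self.split, dtype=object)
            if len(self.split) != n:
                raise ValueError("split length does not match sample count")
            bad = set(self.split) - {CALIBRATION, PREDICTION}
            if bad:
                raise ValueError(f"unknown split labels: {sorted(bad)}")

    @property
    def n_samples(self) -> int:
        return self.absorbance.shape[0]

    @property
    def n_channels(self) -> int:
        return self.absorbance.shape[1]

    @property
    def n_analytes(self) -> int:
        return self.targets.shape[1]

    def _mask(self, phase: str) -> np.ndarray:
        if self.split is None:
            raise ValueError("dataset has no calibration/prediction split")
        return np.asarray([s == phase for s in self.split], dtype=bool)

    def calibration(self) -> "SpectralDataset":
        """Subset of samples flagged as calibration (training)."""
        return self.subset(self._mask(CALIBRATION))

    def prediction(self) -> "SpectralDataset":
        """Subset of samples flagged as prediction (held-out test)."""
        return self.subset(self._mask(PREDICTION))

    def subset(self, rows: np.ndarray) -> "SpectralDataset":
        rows = np.asarray(rows)
        ids = [self.sample_ids[i] for i in np.flatnonzero(rows)] if rows.dtype == bool \
            else [self.sample_ids[i] for i in rows]
        return replace(
            self,
            absorbance=self.absorbance[rows],
            targets=self.targets[rows],
            sample_ids=ids,
            split=self.split[rows] if self.split is not None else None,
        )

    def select_channels(self, channels: np.ndarray) -> "SpectralDataset":
        """Restrict the wavelength axis to the given channel indices."""
        channels = np.sort(np.asarray(channels, dtype=int))
        return replace(
            self,
            wavenumbers=self.wavenumbers[channels],
            absorbance=self.absorbance[:, channels],
        )


def read_dataset(spectra_path, targets_path) -> SpectralDataset:
    """Read a dataset from a spectra CSV and a targets CSV.

    The spectra file has a ``sample_id`` column followed by one numeric
    wavenumber column per channel; the targets file shares sample ids and has
    one column per analyte.  Rows are aligned by sample id, preserving the
    order of the spectra file.
    """
    spec = pd.read_csv(spectra_path, float_precision="round_trip")
    targ = pd.read_csv(targets_path, float_precision="round_trip")
    for df, path in ((spec, spectra_path), (targ, targets_path)):
        if df.columns[0] != "sample_id":
            raise ValueError(f"{path}: first column must be 'sample_id'")
    try:
        wavenumbers = np.array([float(c) for c in spec.columns[1:]])
    except ValueError as exc:
        raise ValueError(f"{spectra_path}: non-numeric wavenumber header: {exc}")
    spec_ids = spec["sample_id"].astype(str).tolist()
    targ = targ.set_index(targ["sample_id"].astype(str))
    missing = [s for s in spec_ids if s not in targ.index]
    extra = [s for s in targ.index if s not in set(spec_ids)]
    if missing or extra:
        raise AlignmentError(
            f"sample ids do not align: missing from targets {missing[:5]}, "
            f"extra in targets {extra[:5]}"
        )
    targ = targ.loc[spec_ids]
    split = None
    tcols = [c for c in targ.columns if c != "sample_id"]
    if "split" in tcols:
        split = targ["split"].to_numpy()
        tcols.remove("split")
    for df, path in ((spec.iloc[:, 1:], spectra_path), (targ[tcols], targets_path)):
        bad = df.apply(lambda c: pd.to_numeric(c, errors="coerce")).isna()
        if bad.to_numpy().any():
            r, c = np.argwhere(bad.to_numpy())[0]
            raise ValueError(f"{path}: non-numeric cell at row {r}, column '{bad.columns[c]}'")
    return SpectralDataset(
        wavenumbers=wavenumbers,
        absorbance=spec.iloc[:, 1:].to_numpy(dtype=float),
        targets=targ[tcols].to_numpy(dtype=float),
        analyte_names=tcols,
        sample_ids=spec_ids,
        split=split,
    )


def write_dataset(ds: SpectralDataset, spectra_path, targets_path) -> None:
    """Write a dataset as the CSV pair read back by :func:`read_dataset`.

    Values are written with ``repr`` round-trip precision so that a
    write/read cycle is lossless at double precision.  The split flag, if
    present, is stored as a ``split`` column of the targets file.
    """
    spec = pd.DataFrame(
        ds.absorbance, columns=[format(float(w), ".17g") for w in ds.wavenumbers]
    )
    spec.insert(0, "sample_id", ds.sample_ids)
    spec.to_csv(spectra_path, index=False, float_format="%.17g")
    targ = pd.DataFrame(ds.targets, columns=ds.analyte_names)
    targ.insert(0, "sample_id", ds.sample_ids)
    if ds.split is not None:
        targ["split"] = ds.split
    targ.to_csv(targets_path, index=False, float_format="%.17g")


def absorbance_from_reflectance(reflectance: np.ndarray) -> np.ndarray:
    """Convert reflectance R in (0, 1] to absorbance A = log10(1/R).

    Values above 1 are allowed (they yield negative absorbance) but trigger
    a warning; non-positive values are a domain error.
    """
    R = np.asarray(reflectance, dtype=float)
    if np.any(R <= 0):
        raise ValueError("reflectance must be positive")
    if np.any(R > 1):
        warnings.warn("reflectance > 1 yields negative absorbance", stacklevel=2)
    return np.log10(1.0 / R)


def sg_filter(ds: SpectralDataset, window: int = 11, polyorder: int = 2) -> SpectralDataset:
    """Savitzky-Golay smooth each spectrum along the wavelength axis.

    Same-length output: edge windows are handled by polynomial interpolation
    (no truncation), so channel indexing downstream is unaffected.
    """
    if window % 2 == 0:
        raise ValueError("window must be odd")
    if window <= polyorder:
        raise ValueError("window must exceed polyorder")
    if window > ds.n_channels:
        raise ValueError("window exceeds number of channels")
    smoothed = savgol_filter(ds.absorbance, window, polyorder, axis=1, mode="interp")
    return replace(ds, absorbance=smoothed)


def split_calibration_prediction(
    ds: SpectralDataset, ratio: float = 2 / 3, seed: int = 0
) -> SpectralDataset:
    """Randomly flag samples as calibration or prediction.

    ``round(ratio * n)`` samples become the calibration set (e.g. 70 of 105
    at the conventional 2:1 ratio); deterministic for a given seed.
    """
    if not 0 < ratio < 1:
        raise ValueError("ratio must lie strictly between 0 and 1")
    n = ds.n_samples
    if n < 3:
        raise ValueError("need at least 3 samples to split")
    n_cal = int(round(ratio * n))
    n_cal = min(max(n_cal, 1), n - 1)
    rng = np.random.default_rng(seed)
    order = rng.permutation(n)
    split = np.array([PREDICTION] * n, dtype=object)
    split[order[:n_cal]] = CALIBRATION
    return replace(ds, split=split)


def pca_summary(ds: SpectralDataset, k: int = 3) -> np.ndarray:
    """Proportions of spectral variance explained by the first k PCs.

    Spectra are mean-centered internally; returns k values in [0, 1],
    non-increasing, summing to at most 1.
    """
    n, p = ds.absorbance.shape
    if not 1 <= k <= min(n - 1, p):
        raise ValueError(f"k must be in [1, {min(n - 1, p)}]")
    X = ds.absorbance - ds.absorbance.mean(axis=0)
    sv = np.linalg.svd(X, compute_uv=False)
    var = sv**2
    total = var.sum()
    if total == 0:
        return np.zeros(k)
    return var[:k] / total
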