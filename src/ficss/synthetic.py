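"""Synthetic NIR mixture spectra with known ground truth.

The generator emulates the statistical structure a catechin-type calibration
problem exhibits: a 4000-10,000 cm^-1 absorbance grid; several analytes
whose Gaussian absorption bands overlap pairwise and share one severely
overlapped common region; positively correlated concentrations (with one
near-zero pair); a gentle polynomial baseline; additive Gaussian noise; and
a mild quadratic detector/self-absorption nonlinearity that makes the
concentration-to-spectrum map depart from strict Beer-Lambert linearity —
the departure that motivates nonlinear calibration models in the first
place.  Because the true unit spectra, informative channels and
concentrations are known, every stage of wavelength selection and
calibration can be tested against ground truth.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np

from .spectra import SpectralDataset

__all__ = [
    "Band",
    "SyntheticScenario",
    "GroundTruth",
    "make_reference_scenario",
    "scenario_unit_spectra",
    "generate",
]


@dataclass(frozen=True)
class Band:
    """One Gaussian absorption band: center and width in cm^-1, height in
    absorbance units per unit analyte content."""

    center: float
    width: float
    height: float


@dataclass
class SyntheticScenario:
    """Full parameterization of a synthetic mixture-spectra dataset."""

    n_samples: int
    wn_start: float                  # cm^-1, inclusive
    wn_stop: float                   # cm^-1, exclusive
    wn_step: float                   # cm^-1 per channel
    analyte_names: list[str]
    bands: dict[str, list[Band]]     # per-analyte band lists
    conc_mean: np.ndarray            # concentration units (e.g. % dry mass)
    conc_sd: np.ndarray
    conc_corr: np.ndarray            # symmetric positive-definite
    interferents: list[list[Band]] = field(default_factory=list)
    interferent_sd: float = 0.4      # relative spread of interferent levels
    baseline_coeffs: tuple[float, float, float] = (0.0, 0.0, 0.0)
    noise_sd: float = 0.0            # absorbance units
    distortion: float = 0.0          # quadratic nonlinearity coefficient
    scatter_sd: float = 0.0          # per-sample multiplicative scatter spread
    saturation: float = 0.0          # concentration-response saturation kappa
    seed: int = 0
    informative_threshold: float = 0.01   # fraction of peak total absorbance

    def __post_init__(self) -> None:
        self.conc_mean = np.asarray(self.conc_mean, dtype=float)
        self.conc_sd = np.asarray(self.conc_sd, dtype=float)
        self.conc_corr = np.asarray(self.conc_corr, dtype=float)
        m = len(self.analyte_names)
        if not (len(self.conc_mean) == len(self.conc_sd) == m):
            raise ValueError("concentration moments must match analyte count")
        if self.conc_corr.shape != (m, m):
            raise ValueError("correlation matrix shape mismatch")
        if not np.allclose(self.conc_corr, self.conc_corr.T):
            raise ValueError("correlation matrix must be symmetric")
        if np.min(np.linalg.eigvalsh(self.conc_corr)) <= 0:
            raise ValueError("correlation matrix must be positive-definite")
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be non-negative")
        wn = self.wavenumbers
        all_bands = [b for name in self.analyte_names for b in self.bands[name]]
        all_bands += [b for species in self.interferents for b in species]
        for b in all_bands:
            if not (wn[0] <= b.center <= wn[-1]):
                raise ValueError(f"band at {b.center} cm^-1 outside the grid")

    @property
    def wavenumbers(self) -> np.ndarray:
        return np.arange(self.wn_start, self.wn_stop, self.wn_step)

    @property
    def n_channels(self) -> int:
        return len(self.wavenumbers)

    def noiseless(self) -> "SyntheticScenario":
        """Copy with noise, baseline and nonlinearity switched off (exact
        Beer-Lambert mixing; used for round-trip recovery checks)."""
        return replace(
            self,
            noise_sd=0.0,
            baseline_coeffs=(0.0, 0.0, 0.0),
            distortion=0.0,
            scatter_sd=0.0,
            saturation=0.0,
            interferents=[],
        )


@dataclass
class GroundTruth:
    """What the generator knows and an analysis method must recover."""

    unit_spectra: np.ndarray       # (n_analytes, n_channels)
    informative_mask: np.ndarray   # bool, channels carrying analyte signal
    concentrations: np.ndarray     # (n_samples, n_analytes)


def make_reference_scenario(
    n_samples: int = 105,
    noise_sd: float = 0.003,
    distortion: float = 0.25,
    scatter_sd: float = 0.0,
    saturation: float = 2.2,
) -> SyntheticScenario:
    """The default four-analyte study scenario.

    1500 channels at 4 cm^-1 over 4000-10,000 cm^-1.  The four analytes
    mimic the tea catechins EC, ECG, EGC and EGCG.  EC and ECG have dominant
    bands in the 5500-6100 cm^-1 region (overlapping tails), EGC and EGCG in
    6400-7000 cm^-1, and all four absorb in a nearly coincident blob at
    8500-8800 cm^-1 — the most severely overlapped part of the axis, where
    the signal is collectively strong but individually unresolvable.  Band
    heights are inversely matched to mean concentrations so every analyte
    contributes comparable absorbance.  Concentrations are
    positively correlated except for one near-zero pair (ECG-EGC, r=0.098),
    with natural sample-to-sample spreads of about 40% of the mean.  The
    saturating concentration response (kappa=2.2) plus the noise level place
    full-spectrum PLS prediction R^2 around 0.7-0.85 per analyte, leaving
    visible headroom for wavelength selection and nonlinear calibration.
    """
    names = ["EC", "ECG", "EGC", "EGCG"]
    # each analyte: one clean diagnostic band plus a contribution to the
    # common 8500-8800 cm^-1 blob where all four bands nearly coincide
    # (severe overlap: collectively strong, individually unresolvable)
    bands = {
        "EC": [Band(5650, 50, 1.00), Band(8620, 35, 0.100)],
        "ECG": [Band(5950, 50, 0.16), Band(8600, 35, 0.016)],
        "EGC": [Band(6550, 50, 0.13), Band(8640, 35, 0.013)],
        "EGCG": [Band(6850, 50, 0.048), Band(8610, 35, 0.006)],
    }
    corr = np.array(
        [
            [1.00, 0.55, 0.45, 0.62],
            [0.55, 1.00, 0.098, 0.58],
            [0.45, 0.098, 1.00, 0.50],
            [0.62, 0.58, 0.50, 1.00],
        ]
    )
    return SyntheticScenario(
        n_samples=n_samples,
        wn_start=4000.0,
        wn_stop=10000.0,
        wn_step=4.0,
        analyte_names=names,
        bands=bands,
        conc_mean=np.array([0.40, 2.50, 3.00, 8.00]),
        conc_sd=np.array([0.16, 1.00, 1.20, 3.20]),
        conc_corr=corr,
        baseline_coeffs=(0.05, 0.03, -0.02),
        noise_sd=noise_sd,
        distortion=distortion,
        scatter_sd=scatter_sd,
        saturation=saturation,
        seed=20240,
    )


def scenario_unit_spectra(scenario: SyntheticScenario) -> np.ndarray:
    """True per-analyte unit-content absorbance spectra (analytes x channels)."""
    wn = scenario.wavenumbers
    S = np.zeros((len(scenario.analyte_names), len(wn)))
    for a, name in enumerate(scenario.analyte_names):
        for b in scenario.bands[name]:
            S[a] += b.height * np.exp(-0.5 * ((wn - b.center) / b.width) ** 2)
    return S


def _draw_concentrations(scenario: SyntheticScenario, rng: np.random.Generator) -> np.ndarray:
    """Correlated Gaussian concentrations, truncated at zero by resampling."""
    cov = scenario.conc_corr * np.outer(scenario.conc_sd, scenario.conc_sd)
    L = np.linalg.cholesky(cov)
    n = scenario.n_samples
    out = np.empty((n, len(scenario.conc_mean)))
    filled = 0
    for _ in range(1000):
        draw = scenario.conc_mean + rng.standard_normal((n, len(L))) @ L.T
        ok = draw[np.all(draw >= 0, axis=1)]
        take = min(n - filled, len(ok))
        out[filled : filled + take] = ok[:take]
        filled += take
        if filled == n:
            return out
    raise RuntimeError("zero-truncation rejected too many draws; check moments")


def generate(
    scenario: SyntheticScenario, seed: int | None = None
) -> tuple[SpectralDataset, GroundTruth]:
    """Generate one dataset realization and its ground truth.

    Absorbance = (c . S) + distortion * (c . S)^2 + baseline + iid noise,
    with the baseline a quadratic in the normalized wavenumber.  Channels
    whose total unit absorbance exceeds ``informative_threshold`` of its
    maximum count as informative.  Deterministic per seed (defaults to the
    scenario's own seed).
    """
    rng = np.random.default_rng(scenario.seed if seed is None else seed)
    S = scenario_unit_spectra(scenario)
    wn = scenario.wavenumbers
    conc = _draw_concentrations(scenario, rng)
    if scenario.saturation > 0:
        # saturating concentration response (Beer-Lambert deviation): the
        # band intensity grows sub-linearly with content, so the inverse
        # map from spectrum to concentration is genuinely nonlinear
        eff = conc / (1.0 + scenario.saturation * conc / scenario.conc_mean)
    else:
        eff = conc
    A = eff @ S
    if scenario.interferents:
        # non-target matrix species with independent random levels: their
        # channels carry variance but no analyte information
        for species in scenario.interferents:
            spec = np.zeros(len(wn))
            for b in species:
                spec += b.height * np.exp(-0.5 * ((wn - b.center) / b.width) ** 2)
            level = np.clip(
                rng.normal(1.0, scenario.interferent_sd, (scenario.n_samples, 1)),
                0.0, None,
            )
            A = A + level * spec
    A = A + scenario.distortion * A**2
    if scenario.scatter_sd > 0:
        # uncorrected per-sample multiplicative scatter: the dominant
        # nonlinearity of diffuse-reflectance NIR when no MSC/SNV is applied
        s = rng.normal(1.0, scenario.scatter_sd, size=(scenario.n_samples, 1))
        A = A * np.clip(s, 0.5, None)
    x = (wn - wn[0]) / (wn[-1] - wn[0])
    b0, b1, b2 = scenario.baseline_coeffs
    A = A + b0 + b1 * x + b2 * x**2
    if scenario.noise_sd > 0:
        A = A + rng.normal(0.0, scenario.noise_sd, size=A.shape)
    total = S.sum(axis=0)
    informative = total > scenario.informative_threshold * total.max()
    ds = SpectralDataset(
        wavenumbers=wn,
        absorbance=A,
        targets=conc,
        analyte_names=list(scenario.analyte_names),
        sample_ids=[f"s{i:04d}" for i in range(scenario.n_samples)],
    )
    return ds, GroundTruth(
        unit_spectra=S, informative_mask=informative, concentrations=conc
    )
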