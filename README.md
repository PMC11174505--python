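# ficss — NIR chemometric calibration with two-tier wavelength selection

`ficss` is a Python toolkit for multi-analyte calibration of near-infrared
(NIR) spectra in the situation chemometricians dread: several structurally
similar analytes (the motivating case is the four tea catechin monomers EC,
ECG, EGC and EGCG) whose absorption bands overlap severely, far more
wavelength channels than samples, and a nonlinear relationship between
spectrum and concentration.  It implements:

- **FIC-SS** (feature interval combination sensitivity segmentation), a
  two-tier wavelength selection algorithm: a coarse tier that screens and
  exhaustively combines equal-width spectral intervals, and a fine tier
  that prunes individual channels by a per-analyte *sensitivity factor*;
- a **multi-output extreme learning machine (ELM)** calibration model that
  predicts all analytes simultaneously;
- the standard baseline selectors **CARS**, **MC-UVE** and **SPA**, and a
  **PLS2** baseline model (with a fast SVD-based core, cross-checked
  against scikit-learn);
- the usual evaluation metrics (RMSE, R², RPD) and the selection-shape
  statistics NFW / NWI / AWIW;
- a **synthetic spectra generator** with known ground truth (unit spectra,
  informative channels, concentrations) that reproduces the statistical
  structure of the problem — overlapping Gaussian bands, positively
  correlated concentrations, baseline, noise, and a saturating
  concentration response that makes the calibration genuinely nonlinear.

## The method

Spectra are absorbance A = log₁₀(1/R) on a wavenumber grid (by default
1500 channels at 4 cm⁻¹ over 4000–10,000 cm⁻¹), Savitzky–Golay smoothed,
and split 2:1 into calibration and prediction sets.

**FIC-SS** proceeds in six steps:

1. Cross-validate a full-spectrum screener model on the calibration set;
   its per-analyte RMSE and R² become the screening thresholds.
2. Divide the axis into *p* equal-width sub-intervals (default *p* = 20).
3. Score a local model per interval; an interval survives if it matches the
   full-spectrum thresholds (RMSEᵢ ≤ RMSE and Rᵢ² ≥ R²) for at least one
   analyte.  *q* intervals survive.
4. Fit the screener on every non-empty union of survivors (2^q − 1
   candidates, exhaustively).
5. Keep the combination with the lowest cross-analyte aggregate RMSE.
6. Estimate each analyte's **unit-content absorbance** spectrum Aᵢ(λ) by
   channel-wise non-negative regression of absorbance on the concentration
   matrix, form sensitivity factors

   αᵢ(λ) = Aᵢ(λ) / Σⱼ Aⱼ(λ),

   and, inside each interval of the winning combination, drop every channel
   whose αᵢ is below the interval's mean ᾱᵢ for all target analytes.

The **ELM** is a single-hidden-layer network y = Σⱼ βⱼ g(ωⱼ·x + bⱼ) with
input weights ω and biases b drawn uniformly from [−1, 1] and never
trained; only the output weights are solved, β* = H†C, via the
Moore–Penrose pseudoinverse of the hidden-layer output matrix H.  The
hidden-node count is searched over 4…40 in steps of 2 with repeated random
restarts, and the draw with the lowest cross-validated RMSE becomes the
model.  Model quality is reported as RMSEP, Rp² and the residual prediction
deviation RPD = 1/√(1 − R²) (RPD ≥ 3 conventionally marks a usable
calibration).

## Worked example

```bash
python examples/03_fic_ss_selection.py
python examples/04_elm_calibration.py
```

prints (seed 7 of the reference scenario):

```
global thresholds (R2 per analyte): [0.77 0.82 0.76 0.83]
surviving intervals: [5, 6, 8, 9]
optimal combination: [5, 6, 8, 9]
selected: NFW=300 channels in NWI=2 runs, AWIW=150.00
ground truth: 85.2% of informative channels recovered, 5.2% of noise channels picked up

training on 300 selected channels
hidden nodes selected: 20 (CV RMSE 0.524, worst candidate 1.032)
FIC-SS-ELM prediction set (n=35):
  EC    RMSEP=0.036  Rp2=0.932  RPD=3.83
  ECG   RMSEP=0.405  Rp2=0.800  RPD=2.24
  EGC   RMSEP=0.359  Rp2=0.910  RPD=3.34
  EGCG  RMSEP=0.808  Rp2=0.899  RPD=3.14
```

Reading this: of the 20 intervals only the four holding the analytes'
diagnostic bands survive the screen; their union (300 channels, 20% of the
axis) recovers 85% of the channels that truly carry analyte signal while
touching only 5% of the noise channels.  The ELM calibrated on those
channels predicts all four analytes on the held-out set with R² ≈ 0.80–0.93
— compare the full-spectrum PLS baseline on the same split (example 02),
which reaches only R² ≈ 0.58–0.83.  `examples/06_benchmark.py` prints the
full comparison table (two full-spectrum baselines and four selector-ELM
models, per analyte).

There is also a thin CLI mirroring the examples
(`ficss generate / preprocess / select / train / evaluate / benchmark`);
every command writes a JSON log with its parameters and config hash.

## Limitations

The synthetic generator defines the study conditions; see
`docs/methods.md` for what it does and does not emulate, the numerical
choices inside every stage, and the design decisions that were genuinely
open.
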