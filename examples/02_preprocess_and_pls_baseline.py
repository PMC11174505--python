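"""Preprocess spectra and fit the full-spectrum PLS baseline.

Savitzky-Golay smoothing, a random 2:1 calibration/prediction split, PLS
component selection by 5-fold cross-validation, and held-out evaluation.
The prediction R^2 around 0.7-0.85 per analyte is the linear full-spectrum
reference that wavelength selection and the nonlinear ELM must beat.
"""

from ficss import (
    choose_pls_components,
    evaluate,
    generate,
    make_reference_scenario,
    pca_summary,
    pls_fit,
    sg_filter,
    split_calibration_prediction,
)

dataset, _ = generate(make_reference_scenario(), seed=7)
dataset = sg_filter(dataset, window=11, polyorder=2)
dataset = split_calibration_prediction(dataset, ratio=2 / 3, seed=7)
cal, pred = dataset.calibration(), dataset.prediction()
print(f"calibration/prediction: {cal.n_samples}/{pred.n_samples}")

props = pca_summary(dataset, k=3)
print("PCA explained variance (first 3 PCs):", [f"{100 * p:.2f}%" for p in props])

k = choose_pls_components(cal.absorbance, cal.targets, max_components=15, seed=0)
model = pls_fit(cal.absorbance, cal.targets, k)
report = evaluate(pred.targets, model.predict(pred.absorbance), dataset.analyte_names)
print(f"PLS with {k} latent variables, prediction set (n={report.n}):")
for name, rmse, r2, rpd in zip(report.analyte_names, report.rmse, report.r2, report.rpd):
    print(f"  {name:5s} RMSEP={rmse:.3f}  Rp2={r2:.3f}  RPD={rpd:.2f}")
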