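"""Generate the reference synthetic NIR dataset and save it as CSV.

Builds the four-analyte tea-catechin-like scenario (1500 channels at 4 cm^-1
over 4000-10,000 cm^-1, 105 samples), draws one realization, and writes the
spectra/targets CSV pair plus the ground truth.  The printed summary shows
how much of the axis actually carries analyte signal — the rest is baseline
and noise that wavelength selection should discard.
"""

from pathlib import Path

from ficss import generate, make_reference_scenario, write_dataset

out = Path("scratch/example_data")
out.mkdir(parents=True, exist_ok=True)

scenario = make_reference_scenario()
dataset, truth = generate(scenario, seed=7)
write_dataset(dataset, out / "spectra.csv", out / "targets.csv")

print(f"samples x channels: {dataset.n_samples} x {dataset.n_channels}")
print(f"analytes: {dataset.analyte_names}")
print(f"wavenumber range: {dataset.wavenumbers[0]:.0f}-{dataset.wavenumbers[-1]:.0f} cm^-1")
n_inf = truth.informative_mask.sum()
print(f"informative channels: {n_inf} ({100 * n_inf / dataset.n_channels:.1f}% of the axis)")
print(f"mean concentrations: {dataset.targets.mean(axis=0).round(2)}")
print(f"wrote {out}/spectra.csv and {out}/targets.csv")
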