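"""Compare two spectra with Pearson correlation and the Wasserstein
(optimal transport) distance, including baseline correction.

Run:  python examples/04_compare_spectra.py
"""

import numpy as np

from irmd import Spectrum, baseline_correct, compare_spectra

grid = np.linspace(200.0, 2000.0, 900)


def bands(centers, heights, width=18.0):
    out = np.zeros_like(grid)
    for c, h in zip(centers, heights):
        out += h * np.exp(-0.5 * ((grid - c) / width) ** 2)
    return out


# A "simulated" spectrum and an "experimental" one: same bands, slightly
# shifted, with a sloping instrumental baseline on top.
simulated = Spectrum(grid, bands([520, 1010, 1450], [0.6, 1.0, 0.4]))
experiment = Spectrum(
    grid,
    bands([528, 1018, 1459], [0.55, 1.0, 0.45]) + 0.15 + 1e-4 * grid,
)

raw = compare_spectra(simulated, experiment)
print(f"against raw experiment        : PCC {raw.pcc:.3f}   WD {raw.wd:7.2f} cm^-1")

corrected = compare_spectra(simulated, experiment, do_baseline=True, baseline_on="b")
print(f"after ALS baseline correction : PCC {corrected.pcc:.3f}   WD {corrected.wd:7.2f} cm^-1")

base = baseline_correct(experiment)
print(f"residual background (<400 cm^-1 region): "
      f"{base.intensities[grid < 400].max():.3f} (was "
      f"{experiment.intensities[grid < 400].max():.3f})")
print("PCC is scale-invariant; WD compares the spectra as unit-mass "
      "distributions, so it reads directly in cm^-1 of band displacement.")
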