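"""Fit four-parameter log-logistic dose-response curves.

Simulates a 9-replicate luminescence plate at a published-style EC50 and
Hill slope (10 log-spaced concentrations, 1e-13..1e-4 M, 5% noise), fits
LL.4 by multi-start least squares, and prints the recovered constants.
"""

import peptidergic as pg
from peptidergic.doseresponse import summarize_pairs

pairs = [
    ("HRPa", "R248", 8.9e-9, 1.75),
    ("FRPa", "R248", 2.3e-7, 0.42),  # shallow-slope regime
    ("VRHa", "R186", 2.7e-10, 1.0),  # sub-nanomolar regime
]

fits = []
for peptide, receptor, ec50, slope in pairs:
    plate = pg.gen_dose_response(
        pg.PlateSpec(true_ec50=ec50, true_slope=slope, noise_sd=0.05,
                     receptor_id=receptor, peptide_id=peptide, seed=1)
    )
    f = pg.fit_4pl(plate)
    fits.append(f)
    print(f"{peptide}/{receptor}: EC50 {f.ec50:.2e} M (true {ec50:.1e}), "
          f"slope {f.hill_slope:.2f} (true {slope}), converged={f.converged}")

summary = summarize_pairs(fits)
print("\nLowest EC50 per receptor (drives the connectome edge weights):")
print(summary["per_receptor"].to_string(index=False))
print("\nEC50 is the concentration of half-maximal activation; the Hill "
      "slope measures how switch-like the response is.")
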