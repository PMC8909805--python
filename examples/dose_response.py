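"""Dose-response simulation, 4PL fitting and the inhibition-rate transform.

Simulates 8-point dose series (0.01-100x EC50, 2% multiplicative noise) at
the three measured potencies of the DVL1 inhibitor series and fits the
four-parameter logistic to each; finally shows the absorbance-to-percent
transform used for cell-growth readouts.
"""

import numpy as np

from pdzscreen import fit_logistic, generate_dose_response, inhibition_rate

POTENCIES = {
    "racemate, DVL1 recruitment": 0.74,
    "(S)-enantiomer, DVL1 recruitment": 0.49,
    "(S)-enantiomer, HCT116 growth": 7.1,
}

for label, ec50 in POTENCIES.items():
    fits = [
        fit_logistic(generate_dose_response(ec50=ec50, noise_sd_frac=0.02, seed=s))
        for s in range(20)
    ]
    med = float(np.median([f.ec50 for f in fits]))
    one = fits[0]
    print(f"{label}: true EC50 {ec50} μM, median fitted {med:.3f} μM "
          f"(first replicate: {one.ec50:.3f} ± {one.ec50_se:.3f}, hill {one.hill:.2f})")

print("\nthe EC50 is the dose at the curve midpoint: at d = EC50 the 4PL "
      "returns exactly (top + bottom)/2 for any Hill slope.")

# inhibition-rate transform for a viability assay
control_od = 0.82
for sample_od in (0.82, 0.41, 0.12):
    print(f"control OD {control_od}, sample OD {sample_od} -> "
          f"inhibition {inhibition_rate(control_od, sample_od):.1f}%")
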