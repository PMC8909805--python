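"""Saturation binding and the competitive Kd shift.

Simulates the FRET titration design (1 μM dansylated TMEM88 peptide, PDZ
domain titrated 2-38 μM, normalised fluorescence at 540 nm with 2%
multiplicative noise), fits the hyperbola, then repeats the titration in the
presence of 1 μM competitor and converts the rightward Kd shift into a
competitive inhibition constant.
"""

import numpy as np

from pdzscreen import (
    apparent_kd,
    fit_hyperbolic,
    generate_binding_curve,
    ki_from_shift,
)

KD_FREE = 11.5     # μM, uninhibited PDZ-peptide affinity
KD_SHIFTED = 20.8  # μM, apparent affinity at 1 μM competitor

# derive the Ki implied by the measured shift (competitive model)
ki = ki_from_shift(KD_FREE, KD_SHIFTED, inhibitor_conc=1.0)
print(f"Ki from the {KD_FREE} -> {KD_SHIFTED} μM shift at 1 μM: {ki:.3f} μM")
print(f"forward check: Kd_app = {apparent_kd(KD_FREE, ki, 1.0):.1f} μM")

# simulate and fit both titrations
free = fit_hyperbolic(generate_binding_curve(KD_FREE, noise_sd_frac=0.02, seed=1))
comp = fit_hyperbolic(
    generate_binding_curve(KD_FREE, ki=ki, inhibitor_conc=1.0,
                           noise_sd_frac=0.02, seed=1)
)
print(f"\nfitted free Kd:      {free.kd:6.2f} ± {free.kd_se:.2f} μM")
print(f"fitted apparent Kd:  {comp.kd:6.2f} ± {comp.kd_se:.2f} μM")

medians = np.median(
    [
        fit_hyperbolic(generate_binding_curve(KD_FREE, noise_sd_frac=0.02, seed=s)).kd
        for s in range(20)
    ]
)
print(f"median free Kd over 20 replicate titrations: {medians:.2f} μM")
print("\na doubling of the apparent Kd at 1 μM competitor corresponds to a "
      "Ki near the competitor concentration itself — sub-1.3 μM here, i.e. "
      "binding-site competition at micromolar potency.")
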