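"""Why the quadratic bias-field correction matters.

A linear shading gradient with a 1.5x intensity ratio across one large
muscle region makes the brightest lean-muscle pixels overlap the darkest fat
pixels, so a single global threshold misclassifies them. Dividing out the
iteratively fitted quadratic surface restores two clean intensity classes.
"""

import numpy as np

from lumbarfi import MeasureConfig, measure_muscle
from lumbarfi.acceptance import BENEFIT_BIAS, validation_spec
from lumbarfi.phantom import generate_phantom

errors_on, errors_off = [], []
for seed in range(20):
    phantom = generate_phantom(
        validation_spec(0.40, seed, bias_coefficients=BENEFIT_BIAS, noise_sd=0.6)
    )
    truth = 100 * phantom.truth_fat_fraction[("PPM", "left")]
    corrected = measure_muscle(phantom.image, phantom.masks, 1)
    uncorrected = measure_muscle(
        phantom.image, phantom.masks, 1, MeasureConfig(bias_correction=False)
    )
    errors_on.append(abs(corrected.FI - truth))
    errors_off.append(abs(uncorrected.FI - truth))

print(f"true fat infiltration:            40.0 %")
print(f"mean |FI error| with correction:   {np.mean(errors_on):.2f} points")
print(f"mean |FI error| without:           {np.mean(errors_off):.2f} points")
print()
print("Under a 1.5x shading gradient the uncorrected threshold misassigns")
print("several percent of the region's area; the corrected estimate stays at")
print("the ground truth.")
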