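"""Quantify MBF, PTF and transmural MBFt from a noisy dynamic scan.

Extracts image-derived input functions from the cavity pools, runs the
voxelwise basis-function fit and compares the regional estimates with the
phantom's ground truth.
"""

import numpy as np

from watermbf import (
    PhantomSpec,
    build_phantom,
    extract_input_functions,
    fit_image,
    regional_values,
)

spec = PhantomSpec(grid_shape=(48, 48, 48), voxel_size_mm=2.5, seed=7)
phantom = build_phantom(spec)

inputs = extract_input_functions(phantom.image, phantom.lv_voi, phantom.rv_voi)
mask = phantom.image.data.max(axis=3) > 0.05 * phantom.image.data.max()
maps = fit_image(phantom.image, inputs, mask)

table = regional_values(maps, phantom.labels)
print("region   fitted MBF   true MBF   fitted MBFt   (mL/g/min)")
for name in ("LV", "LAD", "RCA", "LCX"):
    if name == "LV":
        true = np.mean([t.mbf for t in spec.territory_truth.values()])
    else:
        true = spec.territory_truth[name].mbf
    row = table.loc[name]
    print(f"{name:6s}   {row.mbf:8.2f}   {true:8.2f}   {row.mbft:9.2f}")

print("\nMBF comes from the washout rate of the selected basis function; "
      "MBFt = MBF*PTF/(1-V_A) from the uptake amplitude. At ~5% frame "
      "noise the regional means recover truth to a few percent.")
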