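"""Delineate the myocardial wall and the three coronary territories.

Segmentation runs on the fitted PTF image with the anatomical-tissue-
fraction (ATF) rule, then the wall is split by circumferential angle into
LAD / RCA / LCX sectors.
"""

from watermbf import (
    PhantomSpec,
    assign_territories,
    build_phantom,
    compute_atf,
    extract_input_functions,
    fit_image,
    segment_myocardium,
)

phantom = build_phantom(PhantomSpec(grid_shape=(48, 48, 48), voxel_size_mm=2.5))
inputs = extract_input_functions(phantom.image, phantom.lv_voi, phantom.rv_voi)
mask0 = phantom.image.data.max(axis=3) > 0.05 * phantom.image.data.max()
maps = fit_image(phantom.image, inputs, mask0)

atf = compute_atf(maps)
print(f"ATF in LV blood pool: {atf[phantom.lv_voi].mean():.3f} (pure blood -> 0)")
print(f"ATF in wall:          {atf[phantom.wall_mask].mean():.3f} "
      f"(1 - blood fractions)")

mask, censored = segment_myocardium(maps.ptf, atf, atf_threshold=0.25)
labels = assign_territories(mask, phantom.geometry)
overlap = (mask & phantom.wall_mask).sum() / phantom.wall_mask.sum()
print(f"\nsegmented wall: {mask.sum()} voxels "
      f"({100 * overlap:.1f}% of the true wall recovered)")
for name, code in (("LAD", 1), ("RCA", 2), ("LCX", 3)):
    print(f"  {name}: {(labels == code).sum()} voxels")
print("\nVoxels with ATF below threshold would have had PTF zeroed before "
      "delineation - the rule that deletes artifact-laden wall under "
      "severe misalignment.")
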