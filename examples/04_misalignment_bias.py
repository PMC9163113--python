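"""Bias one scan with a 20 mm left-lateral PET-CT misalignment.

Applies the amplitude-bias field for condition X+20 and re-runs the full
quantification: washout-based MBF is untouched while uptake-based MBFt
drops sharply in the lateral (LCX) territory.
"""

from watermbf import (
    MisalignmentSpec,
    PhantomSpec,
    StudyConfig,
    apply_bias,
    build_phantom,
    misalignment_bias_field,
)
from watermbf.study import analyse_image

cfg = StudyConfig()  # default analysis settings
phantom = build_phantom(PhantomSpec(grid_shape=(48, 48, 48), voxel_size_mm=2.5))

reference = analyse_image(phantom.image, phantom, cfg)

condition = MisalignmentSpec(20, 0, 0, "X+20")
field = misalignment_bias_field(condition, phantom.geometry, epsilon_per_mm=0.01)
biased_img = apply_bias(phantom.image, field)
biased = analyse_image(biased_img, phantom, cfg)

print(f"bias field on the wall: factors {field.factors[phantom.wall_mask].min():.2f}"
      f" .. {field.factors[phantom.wall_mask].max():.2f}\n")
print("region   MBF dev %   MBFt dev %")
for region in ("LV", "LAD", "RCA", "LCX"):
    dev_mbf = 100 * (biased.loc[region, "mbf"] / reference.loc[region, "mbf"] - 1)
    dev_mbft = 100 * (biased.loc[region, "mbft"] / reference.loc[region, "mbft"] - 1)
    print(f"{region:6s}   {dev_mbf:8.2f}   {dev_mbft:9.2f}")

print("\nAmplitude errors cancel out of the washout-rate estimate (MBF) but "
      "scale straight into the uptake amplitude (MBFt): the LCX territory, "
      "facing the shift, loses the most.")
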