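"""Run the full misalignment experiment on a small synthetic cohort.

Six subjects, all eleven misalignment conditions, deviation statistics per
condition and region: mean bias % +/- SD, ICC(A,1) and the Wilcoxon
signed-rank p-value, plus threshold-crossing diagnosis changes.
"""

import pandas as pd

from watermbf import StudyConfig, run_study

pd.set_option("display.width", 120)

cfg = StudyConfig(n_subjects=6, seed=11)
result = run_study(cfg)

lcx = result.deviation_mbft[result.deviation_mbft.region == "LCX"]
print("MBFt deviations in the LCX territory:")
print(lcx.to_string(index=False, float_format=lambda v: f"{v:.2f}"))

pooled_mbf = result.deviation_mbf["bias_pct"].abs().mean()
pooled_mbft = result.deviation_mbft["bias_pct"].abs().mean()
print(f"\npooled mean |deviation|: MBF {pooled_mbf:.2f}%  vs  MBFt {pooled_mbft:.2f}%")
print(f"lowest ICC: MBF {result.deviation_mbf['icc'].min():.3f}, "
      f"MBFt {result.deviation_mbft['icc'].min():.3f}")

diag = result.diagnosis_changes.groupby("kind")[
    ["false_positives", "false_negatives"]
].sum()
print("\nischemia diagnosis changes (thresholds 2.3 / 1.8 mL/g/min):")
print(diag)
print("\nThe washout-based estimate is systematically the more robust one: "
      "misalignment amplitude errors leave MBF almost untouched while MBFt "
      "shifts by up to tens of percent in the territories facing the shift.")
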