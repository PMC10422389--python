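"""Run a small repeated-measures design and compute device agreement.

Simulates subjects x shoes x trials walks (each recorded by both devices),
builds the long-format parameter table (one row per design cell per curve
descriptor) and reports device-pair intraclass correlations and mean peak
differences.
"""

import footkinetics as fk

spec = fk.DesignSpec(n_subjects=4, n_trials=3, noise_sd=2.0, seed=42)
res = fk.run_design(spec)

print(f"parameter table: {len(res.params)} rows, "
      f"{res.rows_per_parameter()} per parameter "
      f"(= {spec.n_subjects} subjects x 2 shoes x 2 devices x {spec.n_trials} trials)")

diff = fk.device_difference(res.params, "dfpf", "max_val")
print("\npeak sagittal-moment device differences (% of platform mean):")
for _, row in diff.iterrows():
    print(f"  {row.joint:6s} {row.pct_difference:+6.2f} %")

icc_table = fk.device_agreement(res.params)
peaks = icc_table[icc_table.parameter.isin(["max_val", "min_val"])]
print("\ndevice-pair ICC (k = 2) on peak values:")
for _, row in peaks.iterrows():
    print(f"  {row.joint:6s} {row.motion:6s} {row.parameter:8s} "
          f"consistency {row.consistency:.3f}  agreement {row.agreement:.3f}")
print("\nUnbiased devices sampling one field agree almost perfectly; real")
print("studies see lower ICCs from physiology the grids cannot share.")
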