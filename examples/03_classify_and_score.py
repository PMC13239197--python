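"""Classify a full simulated in-lab cohort and reproduce the validation table.

Runs the whole lab pipeline: generate 30 subjects (3 of them with noisy
device-off data from investigator handling), calibrate thresholds,
classify every epoch, compute per-subject accuracy/error, exclude
outliers by the mean+2SD rule, and compare against the vendor VANE
output read directly from the device monitors.
"""

from offload_adherence import ScenarioConfig
from offload_adherence.study import run_inlab_study

result = run_inlab_study(ScenarioConfig(n_subjects=30, seed=7))

print(f"thresholds: th_min={result.thresholds.th_min:.4f}, th_max={result.thresholds.th_max:.4f}")
print(f"excluded by mean+2SD error QC: {result.excluded_ids} -> n={len(result.kept_ids)}\n")

print(f"{'device':<6} {'acc steps%':>10} {'acc stand%':>10} {'err steps%':>10} {'err stand%':>10} {'VANE steps%':>11}")
for device in ("rcw", "lift"):
    print(
        f"{device:<6}"
        f" {result.mean_metric('accuracy_steps', device):>10.2f}"
        f" {result.mean_metric('accuracy_standing', device):>10.2f}"
        f" {result.mean_metric('error_steps', device):>10.2f}"
        f" {result.mean_metric('error_standing', device):>10.2f}"
        f" {result.mean_metric('vane_accuracy_steps', device):>11.1f}"
    )

print("\nICC between thigh-measured and algorithm-attributed device-on totals:")
for (device, metric), agreement in result.icc.items():
    print(f"  {device:<5} {metric:<9} ICC = {agreement.icc:.4f} ({agreement.interpretation}), p = {agreement.p_value:.2g}")
print("\nThe custom algorithm recovers the thigh-measured activity almost exactly;")
print("the VANE baseline applied to device monitors is far less accurate.")
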