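"""Calibrate the variance thresholds on five random training subjects.

Per training subject, the extreme V_avg values during thigh-defined
standing and walking (device-on) bracket the two variance bands; the
across-subject extremes seed the initial thresholds, and a grid search
maximizes device-on accuracy minus device-off false attribution.  One
shared (th_min, th_max) pair is fit on pooled RCW + lift epochs.
"""

from offload_adherence import ScenarioConfig, select_training_subjects
from offload_adherence.study import calibrate_from_sessions
from offload_adherence.synth import generate_inlab_session

config = ScenarioConfig(n_subjects=30, seed=7)
ids = config.subject_ids()
sessions = {sid: generate_inlab_session(config, i) for i, sid in enumerate(ids)}

training_ids = select_training_subjects(ids, n=5, seed=config.seed)
print("training subjects:", training_ids)

calib = calibrate_from_sessions(sessions, training_ids)["rcw"]
th = calib.thresholds
print(f"optimized thresholds: th_min = {th.th_min:.4f}, th_max = {th.th_max:.4f}")
print(f"objective at optimum: J = {calib.objective_value:.2f} (accuracy% − false attribution%)")
print(
    "\nAn epoch of thigh-defined standing counts as device use when "
    f"{th.th_min:.3f} < V_avg < {th.th_max:.3f}; walking use when V_avg > {th.th_max:.3f}."
)
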