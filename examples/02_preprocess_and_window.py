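"""Preprocess a gappy CGM record into supervised windows.

Gap filling uses a cubic spline through the observed glucose values;
glucose is scaled by 0.01 and event channels are min-max normalized with
statistics from the training partition only; windows carry 120 min of
history plus the current step (25 steps x 4 channels) and glucose
targets 30/60/120 minutes ahead.
"""

from glybench import SimConfig, inject_gaps, simulate_patient
from glybench.training import preprocess_series

config = SimConfig(n_patients=1, days=7, seed=7)
patient = inject_gaps(simulate_patient(config, 0), config)
print(f"missing before imputation: {patient.n_missing}")

train_w, test_w = preprocess_series(patient, horizons=(30, 60, 120))
print(f"training windows: {len(train_w)}, test windows: {len(test_w)}")
print(f"window shape: {train_w.inputs.shape[1:]} (steps x channels, scaled)")
for h, steps in train_w.horizon_steps.items():
    print(f"  horizon {h} min = {steps} steps ahead; first target "
          f"{train_w.targets[h][0] * 100:.0f} mg/dL")
# The counts obey L - 24 - max(horizon steps) per partition: no window
# crosses the train/test boundary and the farthest target must exist.
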