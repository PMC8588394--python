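"""Simulate a small synthetic CGM cohort and inspect one patient.

The generator emulates an eight-week type-1-diabetes study record at
desk scale: meals and covering boluses on a 5-minute grid, glucose
dynamics with carb-up / insulin-down causality, sensor noise and
dropout gaps.
"""

import numpy as np

from glybench import SimConfig, inject_gaps, simulate_patient

config = SimConfig(n_patients=2, days=7, seed=7)
patient = inject_gaps(simulate_patient(config, 0), config)

bg = patient.bg[~np.isnan(patient.bg)]
print(f"patient {patient.patient_id}: {len(patient)} samples over {config.days} days")
print(f"glucose range {bg.min():.0f}-{bg.max():.0f} mg/dL, mean {bg.mean():.0f}")
print(f"meals: {np.count_nonzero(patient.ch)}, total carbs {patient.ch.sum():.0f} g")
print(f"missing samples from sensor gaps: {patient.n_missing}")
print(f"test partition: last {len(patient.partition_index('test'))} steps (20%)")
# A week of data gives ~2000 windows, enough to train any zoo model on a CPU.
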