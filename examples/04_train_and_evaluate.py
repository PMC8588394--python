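"""Train one forecaster, score it with the seven-metric suite, and
compare it against the persistence baseline.

Every model trains under the same protocol: Adam at learning rate 0.01,
MSE loss (unless the head dictates otherwise), early stopping on
validation loss with 10 epochs' patience. Predictions are rescaled to
mg/dL and clipped to the 40-400 CGM range before any metric.
"""

import numpy as np

from glybench import (
    SimConfig,
    TrainingProtocol,
    compute_metrics,
    inject_gaps,
    last_value_baseline,
    simulate_patient,
    train_model,
)
from glybench.series import unscale_bg
from glybench.training import fold_split, preprocess_series, _subset
from glybench.zoo import PredictionSet

config = SimConfig(n_patients=1, days=7, seed=7)
patient = inject_gaps(simulate_patient(config, 0), config)
train_w, test_w = preprocess_series(patient, horizons=(30, 60, 120))

protocol = TrainingProtocol(max_epochs=40, patience=10, seed=7)
tr_idx, va_idx = fold_split(len(train_w), 0, protocol)
model, history = train_model(
    "mirshekarian", _subset(train_w, tr_idx), _subset(train_w, va_idx), 30, protocol
)
print(f"trained for {len(history['loss'])} epochs "
      f"(final val MAE {history['val_mae'][-1]:.1f} mg/dL)")

actual = unscale_bg(test_w.targets[30])
pred = model.predict(test_w.inputs)
row = compute_metrics(PredictionSet(patient.patient_id, 30, actual, pred, "mirshekarian"))
print("30-min horizon on the held-out test partition:")
for k in ("rmse", "mae", "r2", "cc", "fit", "mard"):
    print(f"  {k:>4} = {row[k]:.3f}")

base = last_value_baseline(test_w, 30)
rmse_naive = float(np.sqrt(np.mean((base.predicted - base.actual) ** 2)))
print(f"naive last-value RMSE = {rmse_naive:.2f} mg/dL "
      f"-> the trained model {'beats' if row['rmse'] < rmse_naive else 'loses to'} it")
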