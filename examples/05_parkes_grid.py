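"""Score predictions clinically with the Parkes consensus error grid.

Zones A and B are clinically acceptable; C-E indicate increasingly
dangerous treatment errors. A good 30-min forecaster should keep nearly
all points in A∪B even when its RMSE is appreciable.
"""

import numpy as np

from glybench import peg_summary, peg_zone
from glybench.zoo import PredictionSet

print("single pairs (reference, prediction) -> zone:")
for ref, pred in [(120, 120), (100, 135), (70, 350), (250, 120)]:
    print(f"  ({ref:>3}, {pred:>3}) -> {peg_zone(ref, pred)}")

rng = np.random.default_rng(7)
actual = rng.uniform(60, 300, 2000)
predicted = np.clip(actual + rng.normal(0, 20, 2000), 40, 400)
res = peg_summary(PredictionSet("demo", 30, actual, predicted, "demo"))
print("\nsimulated forecaster with 20 mg/dL error sd:")
for zone, pct in res.percentages.items():
    print(f"  zone {zone}: {pct:5.2f} %")
print(f"  A∪B = {res.ab_percent:.2f} % (clinically acceptable fraction)")
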