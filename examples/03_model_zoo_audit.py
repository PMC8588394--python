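"""Build every architecture in the zoo and audit parameter counts.

For the eight catalog entries with unambiguous published totals, the
built graphs must match exactly — this pins layer sizes, activations and
wiring (including the two-branch input of the aiello spec and the
sequence-flatten-batchnorm path of the mayo spec).
"""

import numpy as np

from glybench import PRINTED_PARAM_COUNTS, SPEC_IDS, build_model, count_parameters

rng = np.random.default_rng(0)
batch = rng.normal(1.4, 0.2, size=(4, 25, 4))
batch[:, :, 1:] = rng.uniform(0, 1, size=(4, 25, 3))

print(f"{'spec':<16}{'parameters':>12}{'published':>12}")
for spec in SPEC_IDS:
    model = build_model(spec, seed=0)
    built = count_parameters(model)
    printed = PRINTED_PARAM_COUNTS.get(spec)
    status = "" if printed is None else ("  exact" if built == printed else "  OFF")
    print(f"{spec:<16}{built:>12}{str(printed if printed else '-'):>12}{status}")

preds = build_model("sun", seed=0).predict(batch)
print(f"\nuntrained sun forward pass -> {preds.round(1)} mg/dL (clipped to 40-400)")
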