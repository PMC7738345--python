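"""Build the difference data set against the max-yield standard field.

The mean spectrum and mean leaf N of the standard treatment define the
reference; every non-standard sample becomes a signed difference
(ΔR per band, ΔN in mg/g; negative ΔN = nitrogen deficit).
"""

import numpy as np

import leafndiff as L

config = L.SimulationConfig(seed=1)
samples = L.generate_samples(config)
standard = L.select_standard(L.generate_yields(config))
reference = L.build_reference(samples, standard)
diffs = L.compute_differences(samples, reference)
diffs = L.split_train_validation(diffs, fraction=0.73, seed=2)

print(f"standard field: {standard} kg/ha, standard N "
      f"{reference.standard_n:.2f} mg/g")
print(f"difference set: {len(diffs)} non-standard samples "
      f"({int(diffs.train_mask.sum())} train / "
      f"{int(diffs.validation_mask.sum())} validation)")
print(f"ΔN range: {diffs.delta_n.min():.2f} .. {diffs.delta_n.max():.2f} mg/g "
      f"(negative = N deficit relative to the standard)")
print(f"mean |ΔR| over all bands: {np.abs(diffs.delta_r).mean():.4f} "
      f"reflectance units")
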