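"""Choose the mother wavelet and decomposition depth for the DWMD features.

Scans db10/coif5/sym8 at depths 1-12, reporting the approximation count,
the compression ratio (percent of the 600 original bands) and the
correlation of the approximation-only reconstruction with the original
mean difference spectrum.  Compression stabilizes by depth 10; sym8
compresses hardest (15 coefficients, 2.5 %), so sym8/level 10 is selected.
"""

import leafndiff as L

config = L.SimulationConfig(seed=1)
samples = L.generate_samples(config)
reference = L.build_reference(samples,
                              L.select_standard(L.generate_yields(config)))
diffs = L.split_train_validation(L.compute_differences(samples, reference),
                                 0.73, seed=2)

spec, report = L.select_wavelet_and_level(diffs.delta_r[diffs.train_mask])
print(report.query("level >= 9")
      .to_string(index=False,
                 formatters={"compression_ratio": "{:.3f}".format,
                             "correlation": "{:.3f}".format}))
print(f"\nselected: {spec.family} at level {spec.level} "
      f"({L.approx_length(600, spec.filter_length, spec.level)} "
      f"approximation coefficients)")

features = L.extract_features(diffs, spec)
print(f"DWMD feature matrix: {features.X.shape[0]} samples x "
      f"{features.X.shape[1]} coefficients")
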