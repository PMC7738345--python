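"""Select informative wavelengths by SPA and IRIV; extract PCA scores.

SPA picks five minimally collinear bands scored by cross-validated OLS.
IRIV first screens the best 4-interval combination out of all C(30,4) =
27,405 synergy-interval-PLS candidates (this enumeration takes about half
a minute), then iteratively retains informative bands and collapses
correlated survivors.  PCA keeps five unsupervised score directions.
"""

import numpy as np

import leafndiff as L

config = L.SimulationConfig(seed=1)
samples = L.generate_samples(config)
reference = L.build_reference(samples,
                              L.select_standard(L.generate_yields(config)))
diffs = L.split_train_validation(L.compute_differences(samples, reference),
                                 0.73, seed=2)

spa = L.spa_features(diffs, candidate_N_range=(5,), seed=3)
print("SPA bands (nm):", spa.meta["wavelengths_nm"])

_, pca = L.pca_extract(diffs, n_components=5)
print("PCA explained variance ratio:",
      np.round(pca.meta["explained_variance_ratio"], 4))

iriv = L.iriv_features(diffs, seed=3)
print("IRIV joint intervals (1-based):", iriv.meta["joint_intervals"])
print("IRIV bands after pruning (nm):", iriv.meta["wavelengths_nm"])
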