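"""Fit the reduction x model grid and report R²/RMSE per cell.

Runs the wavelet (DWMD) and PCA reductions through PLSR, ELM and GA-ELM
on one synthetic campaign.  RMSE is in mg/g of leaf N difference; the
validation columns measure how well each cell inverts the N deficiency of
held-out leaves.
"""

import leafndiff as L

config = L.ExperimentConfig(seed=1, reductions=("dwmd", "pca"))
grid = L.run_grid(config)

summary = grid.summary()[["reduction", "model", "r2_train", "rmse_train",
                          "r2_val", "rmse_val"]]
print(summary.to_string(index=False, float_format="{:.3f}".format))
print("\nstandard treatment:", grid.standard_treatment, "kg/ha")
best = summary.loc[summary["r2_val"].idxmax()]
print(f"best validation cell: {best['reduction']} x {best['model']} "
      f"(R² {best['r2_val']:.3f}, RMSE {best['rmse_val']:.3f} mg/g)")
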