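"""Robustness of the morphospace to trait-range uncertainty.

Species traits are literature ranges, not point measurements. This example
redraws calyx height, calyx width and petal limb length uniformly inside
each species' (min, max) interval, reruns the phylogenetic PCA per
resampled dataset, and summarizes how stable the per-color score variances
are across datasets.
"""

from campion import resampled_ppca_summary
from campion.synthetic import SyntheticScenario, simulate_study

tree, table, _, _ = simulate_study(SyntheticScenario(seed=0))
summary = resampled_ppca_summary(table, tree, n_datasets=200, seed=0)

v = summary.summary.query("stat == 'variance' and component == 'pPC1'")
print("across-dataset distribution of pPC1 group variance:")
print(v[["group", "mean", "q05", "q50", "q95"]].round(2).to_string(index=False))

wide = (summary.per_dataset.query("component == 'pPC1'")
        .pivot(index="dataset", columns="group", values="variance"))
frac = ((wide["red"] < wide["white"]) & (wide["red"] < wide["pink"])).mean()
print(f"\nfraction of resampled datasets with red variance lowest: {frac:.2f}")
print("Near 1.0 means the reduced red-group variance is robust to where "
      "each species truly sits inside its published trait range.")
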