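"""Why ratio outcomes fail here: one latent factor drives all regions.

Reads the bundle written by 03_reliability_table.py (runs the pipeline
itself if absent) and prints the interregional V_T correlations, the PCA
variance decomposition of within-genotype z-scored regional V_T, and the
R² of each outcome against frontal-cortex V_T.
"""

from pathlib import Path

import pandas as pd

import petratio as pr

bundle = Path("example_run")
if not (bundle / "manifest.yaml").exists():
    pr.run_all(pr.RunConfig(cohort=pr.CohortSpec(seed=1)), bundle)

correlations = pd.read_csv(bundle / "correlations.tsv", sep="\t")
vt_corr = correlations[correlations.measure == "VT"].set_index("roi").drop(columns="measure")
print("interregional V_T correlations (Pearson r):")
print(vt_corr.round(3).to_string())

pca = pd.read_csv(bundle / "pca.tsv", sep="\t")
print("\nPCA of within-genotype z-scored regional V_T:")
for scan_idx, grp in pca.groupby("scan_index"):
    fracs = grp.sort_values("component").fraction.to_numpy()
    print(f"  scan {scan_idx}: first component {100 * fracs[0]:.1f}% "
          f"(remaining {', '.join(f'{100 * f:.1f}%' for f in fracs[1:3])} ...)")

table2 = pd.read_csv(bundle / "table2.tsv", sep="\t")
print("\nassociation with frontal V_T (R² within genotype):")
print(table2.pivot(index="measure", columns="genotype", values="r2").round(2).to_string())
# Near-unit interregional correlations and a ~99% first component mean the
# regions are close to collinear: SUVR/DVR divide that shared signal away,
# so their residual association with V_T is small.
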