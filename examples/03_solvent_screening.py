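"""Screen the three extraction solvent mixtures with PCA, HCA and PLS-DA.

36 synthetic extraction replicates (12 per solvent mixture: methanol/ethyl
acetate ME, ethanol/ethyl acetate EE, isopropanol/ethyl acetate IE) are
generated with EE the most heterogeneous group, then assessed by double
cross-validated and bootstrapped PLS-DA.
"""

from pathlib import Path

import mae_lipidomics as ml

screening = ml.gen_solvent_screening(ml.GeneratorConfig(seed=0))
out = Path("scratch/example_screening")
bundle = ml.run_screening(screening, out, seed=0, bootstrap_B=500)

print("PCA explained variance (%):", bundle.pca_model.explained_variance_pct[:2].round(1))
print()
print(bundle.report.round(3).to_string())
print()
print(
    "IE separates perfectly and ME keeps high sensitivity, while the EE "
    "replicates scatter into their neighbours (lowest sensitivity): the "
    "ethanol mixture is the poorly discriminated group, as the dendrogram "
    "in", out / "dendrogram.nwk", "also shows."
)
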