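"""Attribute variation in the ΔE₀ seasonal amplitude to site covariates.

Builds a synthetic table of 200 site-years whose covariates share two
latent climate/vegetation gradients, plants a response on the two leading
principal components, and runs the attribution stack: PCA contributions,
AICc-ranked linear models, and random-forest permutation importance.
"""

import numpy as np
import pandas as pd

from dnrflux import attribution as A

rng = np.random.default_rng(8)
n = 200
f1, f2 = rng.normal(0, 1, n), rng.normal(0, 1, n)
names = ["MAT", "Tair", "Tmax", "Tmin", "PAR", "VPD", "SPEI", "NDVI", "LAI", "SWC", "SOC", "SLA"]
table = pd.DataFrame(
    {
        nm: (1.0 if j % 2 == 0 else 0.2) * f1 + (0.2 if j % 2 == 0 else 1.0) * f2 + rng.normal(0, 0.3, n)
        for j, nm in enumerate(names)
    }
)

pca = A.pca_decompose(table)
print(f"Dim1 + Dim2 explain {pca.explained_pct[:2].sum():.1f} % of covariate variance")
print(f"top Dim1 contributors: {pca.contributions['Dim1'].nlargest(3).round(1).to_dict()}")

signal = 0.14 * pca.scores["Dim1"] - 0.14 * pca.scores["Dim2"]
response = signal + rng.normal(0, float(signal.std()), n)
glm = A.glm_aicc_rank(response, pca.scores)
print("\nAICc-ranked linear models of ΔE0 seasonal amplitude:")
print(glm[["rank", "model", "aicc", "r2", "p"]].round(3).to_string(index=False))

rf_table = pd.concat([pd.Series(response, name="asv_delta"), table], axis=1)
imp = A.rf_importance(rf_table, seed=8)
print("\nrandom-forest permutation importance (top 5):")
print(imp.head(5)[["variable", "share_pct", "family"]].round(1).to_string(index=False))
print("\nfamily shares (%):", A.family_shares(imp).round(1).to_dict())
print(
    "\nThe two-component model ranks first because the response was planted"
    "\non Dim1 and Dim2; the importance ranking highlights the covariates"
    "\nmost aligned with those gradients."
)
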