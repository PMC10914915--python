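"""From plot values to genotype means: spatial adjustment and Cullis H2.

Simulates a two-block trial with a spatially autocorrelated field error,
computes spatially adjusted genotype means and generalized heritability,
and compares the adjustment against raw genotype means.
"""

import numpy as np
import pandas as pd

from glaidyn import adjusted_means, generalized_heritability

rng = np.random.default_rng(3)
n_geno, n_cols = 100, 10
g = rng.normal(0, 1.0, n_geno)


def ar1_chol(n, rho):
    idx = np.arange(n)
    return np.linalg.cholesky(rho ** np.abs(idx[:, None] - idx[None, :])
                              + 1e-9 * np.eye(n))


n_rows = 2 * int(np.ceil(n_geno / n_cols))
field = 0.8 * ar1_chol(n_rows, 0.5) @ rng.standard_normal(
    (n_rows, n_cols)) @ ar1_chol(n_cols, 0.5).T

rows = []
for b in (1, 2):
    for k, gi in enumerate(rng.permutation(n_geno)):
        r, c = divmod(k, n_cols)
        r += (b - 1) * n_rows // 2
        rows.append({"genotype": f"g{gi:03d}", "block": b, "row": r,
                     "col": c,
                     "y": g[gi] + field[r, c] + rng.normal(0, 0.3)})
df = pd.DataFrame(rows)

means, rec = adjusted_means(df, "y", rho_grid=[0.0, 0.3, 0.5, 0.7])
raw = df.groupby("genotype")["y"].mean()
truth = pd.Series(g, index=[f"g{i:03d}" for i in range(n_geno)])
rmse_adj = float(np.sqrt(((means - truth) ** 2).mean()))
rmse_raw = float(np.sqrt(((raw - truth) ** 2).mean()))
h2 = generalized_heritability(df, "y", rho=(rec.rho_row, rec.rho_col))

print(f"chosen spatial correlation: rho_row={rec.rho_row}, "
      f"rho_col={rec.rho_col}")
print(f"RMSE vs true genotype value: adjusted {rmse_adj:.3f}  "
      f"raw {rmse_raw:.3f}")
print(f"generalized heritability H2 = {h2:.2f}")
# The AR1xAR1 adjustment recovers genotype values better than raw
# averaging whenever a smooth field trend is present.
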