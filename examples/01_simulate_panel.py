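"""Simulate a MAGIC doubled-haploid panel and inspect its structure.

Builds a 16-founder mosaic panel (120 lines, 3 chromosomes here for
speed), applies the 3.5% minor-allele-frequency filter, and prints the
panel dimensions, the realised MAF range and the family signal in the
identity-by-state kinship.
"""

import numpy as np

from glaidyn import ibs_kinship, simulate_magic_genotypes

panel = simulate_magic_genotypes(n_lines=120, n_chrom=3,
                                 n_markers_per_chrom=120, seed=7)
maf = panel.maf()
print(f"panel: {panel.n_samples} DH lines x {panel.n_markers} markers "
      f"(after MAF >= 3.5% filter)")
print(f"MAF range: {maf.min():.3f} .. {maf.max():.3f}")

K = ibs_kinship(panel.dosage)
fam = panel.families
same = K[np.equal.outer(fam, fam) & ~np.eye(len(fam), dtype=bool)]
diff = K[~np.equal.outer(fam, fam)]
print(f"mean IBS within families:  {same.mean():.3f}")
print(f"mean IBS between families: {diff.mean():.3f}")
# Within-family sharing exceeds between-family sharing: the funnel's
# family structure is visible in the kinship, which is exactly what the
# mixed-model GWAS has to correct for.
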