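"""SNP quality control and the VanRaden genomic relationship matrix.

QC retains markers with MAF > 0.01 and missingness < 5%, collapses duplicate
columns, and drops lines with >20% missing calls or excess heterozygosity;
the kinship matrix A = ZZ'/(2*sum p(1-p)) then drives GBLUP.
"""

import numpy as np

from phsgp import (
    PopulationSpec,
    impute_missing,
    pca,
    qc_filter,
    recode_minor_allele,
    simulate_population,
    vanraden_grm,
)

geno = simulate_population(PopulationSpec(n_markers=1500, seed=1))

# knock a few calls out to give the imputation something to do
rng = np.random.default_rng(3)
dos = geno.dosages.copy()
dos[rng.random(dos.shape) < 0.01] = np.nan
geno.dosages = dos

geno = recode_minor_allele(geno)
geno, report = qc_filter(geno)
print(report.to_frame().to_string(index=False))

geno = impute_missing(geno, seed=4)
A = vanraden_grm(geno)
print(f"\nA: {A.n_lines} x {A.n_lines}, mean diagonal {np.mean(np.diag(A.values)):.3f}")
print(f"row-sum bound (should be ~0): {np.abs(A.values.sum(axis=1)).max():.2e}")
# Inbred lines push the diagonal towards 2; zero row sums follow from the
# allele-frequency centering of Z.

res = pca(geno, k=2)
print(f"PC1/PC2 variance fractions: {res.explained_fraction[0]:.3f} "
      f"/ {res.explained_fraction[1]:.3f}  (weak structure, as in elite material)")
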