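"""Simulate a multi-program wheat breeding population with a major PHS locus.

Builds the default cohort emulated throughout the package: 400 F6 lines from
six breeding programs, split into a calibration set (CS, phenotyped in both
seasons) and two season-specific validation sets (VS15, VS16).
"""

import numpy as np

from phsgp import PopulationSpec, make_qtl_architecture, simulate_population

spec = PopulationSpec(n_markers=1500, seed=1)
geno = simulate_population(spec)

print(f"lines x markers: {geno.n_lines} x {geno.n_markers}")
print(f"mean minor-allele frequency: {np.mean(geno.maf()):.3f}")
for cohort in ("CS", "VS15", "VS16"):
    print(f"  {cohort}: {(geno.set_label == cohort).sum()} lines")

arch = make_qtl_architecture(geno, major_var_share=0.30, seed=2)
g = arch.genetic_values(geno)
print(f"\nmajor locus markers: {[str(m) for m in arch.major_marker_ids]}")
print(f"genetic values: mean {g.mean():.3f}, sd {g.std():.3f}")
# The two major markers carry ~30% of the genetic variance, mirroring a
# Phs-A1-like locus; the rest is a polygenic background of small effects.
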