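"""Across-season prediction scenarios on the two-season cohort.

One season's adjusted means train the model; the other season's lines are
predicted.  Calibration-set (CS) lines were phenotyped in both seasons, the
validation sets (VS15/VS16) in one season only — predicting a VS is the
honest "new lines" scenario and its correlations are lower.
"""

from phsgp import ModelSpec, ScenarioSpec, cross_season_predict
from phsgp.evaluation import season_correlations
from phsgp.synthetic import simulate_study_cohort

c = simulate_study_cohort(seed=21)
mspec = ModelSpec.from_architecture("model2_qtl17", c["arch"])

print("ES -> TS            N_ES  N_TS      r(GEBV, OBV)")
for es, ts in (("S15", "S16"), ("S16", "S15")):
    for subset in ("cs", "vs"):
        out = cross_season_predict(
            ScenarioSpec(es, ts, "all", subset), c["means_by_season"],
            c["geno"], c["A"], mspec,
        )
        print(f"{out['es']:>8} -> {out['ts']:<8} {out['n_es']:>4}  {out['n_ts']:>4}"
              f"      {out['r']:.3f}")

corr = season_correlations(c["means_by_season"], c["geno"], c["A"], mspec,
                           ("S15", "S16"))
print(f"\nCS lines across seasons ({corr['n_cs']} lines):")
print(f"  r(OBV_S15, OBV_S16)   = {corr['r_obv']:.3f}")
print(f"  r(GEBV_S15, GEBV_S16) = {corr['r_gebv']:.3f}")
# GEBVs are shrunken towards the kinship structure and therefore correlate
# more strongly across seasons than the raw observed means.
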