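"""BLUP breeding values and accuracies over the full pedigree.

After estimating variance components on the trimmed pedigree, the
final model is re-solved over every dog in the registry so that
untested ancestors and relatives also receive EBVs. Accuracy is
sqrt(1 - PEV / ((1 + f) sigma_a^2)): zero for a dog about which the
data say nothing, approaching one with abundant information.
"""

from kennelquant import (
    ModelSpec,
    SimConfig,
    accuracy_summary,
    build_design,
    compute_inbreeding,
    grade_to_liability,
    heritability_repeatability,
    pev_and_accuracy,
    reml_fit,
    simulate_pedigree,
    simulate_phenotypes,
    solve_blup,
    trim_to_phenotyped,
)

cfg = SimConfig(n_founders=80, n_generations=3, generation_size=150,
                phenotyped_generations=1, seed=3)
ped = compute_inbreeding(simulate_pedigree(cfg))
records, _ = simulate_phenotypes(ped, cfg)
lmap, liab = grade_to_liability(records["value"].to_numpy())
records = records.assign(liab=liab)

spec = ModelSpec(response="liab", spline_knots=4)
trimmed = compute_inbreeding(trim_to_phenotyped(ped, set(records["dog_id"])))
fit = reml_fit(build_design(records, trimmed, spec), trimmed, spec)
hr = heritability_repeatability(fit)

tbl, mm, st = solve_blup(records, ped, fit, spec)
tbl = pev_and_accuracy(tbl, mm, st, fit.components.sigma2_a)

print(f"EBVs for all {len(tbl)} dogs ({int(tbl['phenotyped'].sum())} with own records)")
print("\ntop five dogs by EBV (lower liability = better respiratory function):")
cols = ["id", "ebv", "accuracy", "phenotyped"]
print(tbl.nsmallest(5, "ebv")[cols].to_string(index=False, float_format="%.3f"))

summ = accuracy_summary(tbl, h2=hr["h2"])
print(f"\nmedian accuracy: {summ['median_accuracy']:.2f}")
print(f"fraction above own-phenotype threshold sqrt(h2) = {summ['thresholds']['own_phenotype']:.2f}: "
      f"{100 * summ['frac_above_own_phenotype']:.1f}%")
print(f"fraction above parent-average threshold sqrt(h2/2) = {summ['thresholds']['parent_average']:.2f}: "
      f"{100 * summ['frac_above_parent_average']:.1f}%")
unph = tbl[~tbl["phenotyped"]]
print(f"\nunphenotyped dogs still get informative EBVs through relatives: "
      f"median accuracy {unph['accuracy'].median():.2f}")
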