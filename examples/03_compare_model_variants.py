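"""Fit the model variants for disconnected regions and compare by DIC/WAIC.

The data are generated with equal regional baselines but different spatial
variances per region.  The split-random-effects models (IVa/IVb) let each
region carry its own precisions while still yielding a single DIC/WAIC; on
any one draw the simpler shared-precision variants can still edge ahead by
a DIC unit or two, which is exactly the comparison the table makes visible.
"""

import splitcar as sc

bundle = sc.scenario("common_baseline")
graph, summ = bundle.truth.graph, bundle.summaries()

fits = {}
for variant in ("I", "II", "III", "IVa", "IVb"):
    spec = sc.make_model(variant, graph)
    fits[variant] = sc.fit_model(spec, graph, summ)

report = sc.compare(fits)
print(report)
print("\nselected by DIC:", report.selected_model)

best = fits[report.selected_model]
print("\nfixed effects of the selected model:")
print(best.fixed_effects().round(3).to_string())
print("\nposterior mean random-effect variances:")
print(best.hyperparameter_summary()["mean_variance"].round(4).to_string())
print("\nfitted prevalence for three unsampled areas (prior + neighbours only):")
print(best.predict_unsampled(method="ghq").head(3).round(3).to_string())

# Lower DIC/WAIC = better fit.  The per-region variance table shows the
# split models recovering different spatial variability in the two regions,
# which the shared-precision variants (I-III) must average over.
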