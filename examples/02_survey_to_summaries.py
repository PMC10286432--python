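"""From weighted individual survey records to area-level Gaussian summaries.

Simulates a two-stage stratified cluster survey with unequal weights, then
reduces it to per-area Horvitz-Thompson prevalences, design variances and
the empirical-logit transform that the spatial models consume.
"""

import splitcar as sc

bundle = sc.scenario("common_baseline")
records = bundle.records
print(f"{len(records)} sampled children across "
      f"{records['area_id'].nunique()} of {bundle.truth.graph.n_areas} areas")
print(records.head(3).to_string(index=False))

summ = bundle.summaries()
print("\nper-area summaries (head):")
print(summ.head(5).round(4).to_string())
print("\nstatus counts:", summ["status"].value_counts().to_dict())

# 'observed' areas carry the empirical-logit likelihood y_logit ~ N(eta,
# var_logit); 'degenerate_adjusted' areas had p_hat in {0,1} or an unusable
# design variance and received a continuity correction; 'unsampled' areas
# carry no likelihood and will be predicted purely from the spatial prior.
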