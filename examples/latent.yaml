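# Two-imperfect-classifier assessment: neither the filter nor the human
# coders are a gold standard.  Counts are the sampling-fraction-adjusted
# filter-vs-coder cross-tabulation.
counts: {a: 128, b: 6, c: 20, d: 6285}
n_cycles: 100000
burn_in: 10000
priors:
  prevalence: {mean: 0.019, interval: [1.0e-6, 0.031]}
  recall_filter: {mean: 0.667, interval: [0.340, 0.954]}
  specificity_filter: {mean: 0.733, interval: [0.474, 0.962]}
  recall_coder: {mean: 0.733, interval: [0.474, 0.962]}
  specificity_coder: {mean: 0.800, interval: [0.616, 0.975]}
data_source: stratified coding sample, adjusted for disproportionate sampling
filter_provenance: e-cigarette keyword filter (device/brand/behavior categories)
coding_assumptions: >-
  conditional independence of filter and coder given true relevance;
  both classifiers allowed false positives and false negatives
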