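# Bayesian assessment when unretrieved messages were never archived:
# only the retrieved total, the approximate unretrieved total, and the
# coded-sample precision interval are observable.
n1: 82205
n2: 3872370
precision_interval: [0.949, 0.961]
n_cycles: 100000
burn_in: 10000
priors:
  prevalence: {mean: 0.010, interval: [1.0e-6, 0.031]}
  recall: {mean: 0.667, interval: [0.340, 0.954]}
  specificity: {mean: 0.733, interval: [0.474, 0.962]}
data_source: retrieved-only archive (82,205 messages); unretrieved total known approximately
filter_provenance: e-cigarette keyword filter (device/brand/behavior categories)
coding_assumptions: coded-sample precision interval summarizes the human coding
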