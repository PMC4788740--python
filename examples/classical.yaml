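# Classical (gold-standard) assessment from coded stratified counts:
# the published e-cigarette coding sample.
counts: {a: 4176, b: 197, c: 20, d: 6285}
design:
  retrieved_sampled: 4373
  unretrieved_sampled: 6305
  retrieved_population: 82205
  unretrieved_population: 3872370
data_source: >-
  Archive of 3,954,575 tobacco-related tweets (October 2012); the topic
  filter retrieved 82,205 of them.
filter_provenance: e-cigarette keyword filter (device/brand/behavior categories)
coding_assumptions: human coding treated as an error-free gold standard
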