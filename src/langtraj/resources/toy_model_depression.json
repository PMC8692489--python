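{
 "name": "depression",
 "intercept": 0.0,
 "weights": {
  "ngram:sad": 60.0,
  "ngram:hopeless": 60.0,
  "ngram:tired": 60.0,
  "ngram:empty": 60.0,
  "ngram:alone": 60.0
 }
}
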