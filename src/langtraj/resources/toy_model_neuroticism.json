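{
 "name": "neuroticism",
 "intercept": 2.5,
 "weights": {
  "ngram:upset": 60.0,
  "ngram:moody": 60.0,
  "ngram:stress": 60.0,
  "ngram:uneasy": 60.0,
  "ngram:irritable": 60.0
 }
}
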