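{
 "name": "anxiety",
 "intercept": 0.0,
 "weights": {
  "ngram:worried": 60.0,
  "ngram:nervous": 60.0,
  "ngram:afraid": 60.0,
  "ngram:panic": 60.0,
  "ngram:scared": 60.0
 }
}
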