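{
 "name": "extraversion",
 "intercept": 0.0,
 "weights": {
  "ngram:outgoing": 60.0,
  "ngram:party": 60.0,
  "ngram:social": 60.0,
  "ngram:lively": 60.0,
  "ngram:talkative": 60.0
 }
}
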