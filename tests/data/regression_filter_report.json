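{
  "input_count": 200,
  "removed": {
    "age": 0,
    "galenic": 11,
    "prescriber": 9,
    "sex_female_only": 3,
    "year": 0
  },
  "retained": 177,
  "unparseable": 0
}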