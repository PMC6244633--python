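{
 "reference_concentration_ug_per_ml": 500.0,
 "scenarios": {
  "conventional": {
   "undoped": {
    "alpha": 0.002,
    "beta": 0.079
   },
   "doped": {
    "alpha": 0.002,
    "beta": 0.079
   }
  },
  "minimum": {
   "undoped": {
    "alpha": 0.024,
    "beta": 0.086
   },
   "doped": {
    "alpha": 0.064,
    "beta": 0.087
   }
  },
  "mean": {
   "undoped": {
    "alpha": 0.002,
    "beta": 0.079
   },
   "doped": {
    "alpha": 0.104,
    "beta": 0.098
   }
  },
  "maximum": {
   "undoped": {
    "alpha": 0.0,
    "beta": 0.072
   },
   "doped": {
    "alpha": 0.144,
    "beta": 0.109
   }
  }
 }
}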