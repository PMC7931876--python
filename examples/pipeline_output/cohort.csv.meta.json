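{
 "variables": {
  "cardio_1": {
   "kind": "dichotomous",
   "role": "diagnosis"
  },
  "cardio_2": {
   "kind": "dichotomous",
   "role": "diagnosis"
  },
  "cardio_3": {
   "kind": "dichotomous",
   "role": "diagnosis"
  },
  "cardio_4": {
   "kind": "dichotomous",
   "role": "diagnosis"
  },
  "cardio_5": {
   "kind": "dichotomous",
   "role": "diagnosis"
  },
  "cardio_6": {
   "kind": "dichotomous",
   "role": "diagnosis"
  },
  "renal_1": {
   "kind": "dichotomous",
   "role": "diagnosis"
  },
  "renal_2": {
   "kind": "dichotomous",
   "role": "diagnosis"
  },
  "renal_3": {
   "kind": "dichotomous",
   "role": "diagnosis"
  },
  "renal_4": {
   "kind": "dichotomous",
   "role": "diagnosis"
  },
  "renal_5": {
   "kind": "dichotomous",
   "role": "diagnosis"
  },
  "renal_6": {
   "kind": "dichotomous",
   "role": "diagnosis"
  },
  "noise_1": {
   "kind": "dichotomous",
   "role": "medication"
  },
  "noise_2": {
   "kind": "dichotomous",
   "role": "medication"
  },
  "noise_3": {
   "kind": "dichotomous",
   "role": "medication"
  },
  "noise_4": {
   "kind": "dichotomous",
   "role": "medication"
  },
  "noise_5": {
   "kind": "dichotomous",
   "role": "medication"
  },
  "noise_6": {
   "kind": "dichotomous",
   "role": "medication"
  },
  "noise_7": {
   "kind": "dichotomous",
   "role": "medication"
  },
  "noise_8": {
   "kind": "dichotomous",
   "role": "medication"
  },
  "noise_9": {
   "kind": "dichotomous",
   "role": "medication"
  },
  "noise_10": {
   "kind": "dichotomous",
   "role": "medication"
  },
  "noise_11": {
   "kind": "dichotomous",
   "role": "medication"
  },
  "noise_12": {
   "kind": "dichotomous",
   "role": "medication"
  },
  "noise_13": {
   "kind": "dichotomous",
   "role": "medication"
  },
  "noise_14": {
   "kind": "dichotomous",
   "role": "medication"
  },
  "noise_15": {
   "kind": "dichotomous",
   "role": "medication"
  },
  "noise_16": {
   "kind": "dichotomous",
   "role": "medication"
  },
  "noise_17": {
   "kind": "dichotomous",
   "role": "medication"
  },
  "noise_18": {
   "kind": "dichotomous",
   "role": "medication"
  },
  "noise_19": {
   "kind": "dichotomous",
   "role": "medication"
  },
  "noise_20": {
   "kind": "dichotomous",
   "role": "medication"
  },
  "noise_21": {
   "kind": "dichotomous",
   "role": "medication"
  },
  "noise_22": {
   "kind": "dichotomous",
   "role": "medication"
  },
  "noise_23": {
   "kind": "dichotomous",
   "role": "medication"
  },
  "noise_24": {
   "kind": "dichotomous",
   "role": "medication"
  },
  "noise_25": {
   "kind": "dichotomous",
   "role": "medication"
  },
  "noise_26": {
   "kind": "dichotomous",
   "role": "medication"
  },
  "noise_27": {
   "kind": "dichotomous",
   "role": "medication"
  },
  "noise_28": {
   "kind": "dichotomous",
   "role": "medication"
  },
  "noise_29": {
   "kind": "dichotomous",
   "role": "medication"
  },
  "noise_30": {
   "kind": "dichotomous",
   "role": "medication"
  },
  "dup1_noise_6": {
   "kind": "dichotomous",
   "role": "medication"
  },
  "dup2_noise_1": {
   "kind": "dichotomous",
   "role": "medication"
  },
  "age": {
   "kind": "discrete",
   "role": "demographic"
  },
  "sex": {
   "kind": "dichotomous",
   "role": "demographic"
  },
  "bmi": {
   "kind": "continuous",
   "role": "demographic"
  },
  "outcome": {
   "kind": "dichotomous",
   "role": "outcome"
  }
 }
}
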