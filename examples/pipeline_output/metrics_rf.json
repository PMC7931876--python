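{
 "accuracy": 0.7516666666666667,
 "method": "RF",
 "n_selected": 13,
 "precision": 0.6991150442477876,
 "recall": 0.6610878661087866,
 "roc_auc": 0.8022809721948563,
 "threshold_or_lambda": 0.016248047038080714
}
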