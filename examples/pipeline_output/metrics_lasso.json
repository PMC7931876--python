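{
 "accuracy": 0.785,
 "method": "LASSO",
 "n_selected": 13,
 "precision": 0.7644230769230769,
 "recall": 0.6652719665271967,
 "roc_auc": 0.8398857195841399,
 "threshold_or_lambda": 15.989512300315639
}
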