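variable
age
cardio_1
cardio_2
cardio_3
cardio_4
cardio_5
cardio_6
renal_1
renal_2
renal_3
renal_4
renal_5
renal_6
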