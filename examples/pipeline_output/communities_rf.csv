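variable,community
cardio_1,cardio_1
cardio_2,cardio_1
cardio_3,cardio_1
cardio_4,cardio_1
cardio_5,cardio_1
cardio_6,cardio_1
renal_1,renal_1
renal_2,renal_1
renal_3,renal_1
renal_4,renal_1
renal_5,renal_1
renal_6,renal_1
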