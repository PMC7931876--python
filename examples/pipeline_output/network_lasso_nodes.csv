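variable,z,size,sex_prevalence
cardio_1,3.8462,3.8462,0.448454
cardio_2,2.93024,2.93024,0.441026
cardio_3,3.87448,3.87448,0.44709
cardio_4,3.67738,3.67738,0.430052
cardio_5,4.43016,4.43016,0.436693
cardio_6,3.67558,3.67558,0.455026
renal_1,4.86945,4.86945,0.452888
renal_2,2.97843,2.97843,0.423948
renal_3,4.68675,4.68675,0.445122
renal_4,2.59255,2.59255,0.450746
renal_5,4.04015,4.04015,0.455385
renal_6,4.58213,4.58213,0.437309
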