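variable,mda,gini_decrease
cardio_1,0.010591,0.0162332
cardio_2,0.00851268,0.0164443
cardio_3,0.0135938,0.0186468
cardio_4,0.00532729,0.0131717
cardio_5,0.0148802,0.0213641
cardio_6,0.0123782,0.0216794
renal_1,0.0148632,0.0201517
renal_2,0.0062483,0.0124863
renal_3,0.0132712,0.0183137
renal_4,0.00899512,0.0154749
renal_5,0.00719096,0.0150797
renal_6,0.0145006,0.0248225
noise_1,-0.000490378,0.00319014
noise_2,0.000136667,0.0083212
noise_3,7.75184e-05,0.00426808
noise_4,-0.000173453,0.00513833
noise_5,-0.000295554,0.00694788
noise_6,0.000425884,0.00320132
noise_7,0.000442253,0.00680146
noise_8,-0.000512775,0.00832436
noise_9,0.000327107,0.00434105
noise_10,0.000251644,0.00609214
noise_11,0.00153605,0.00899474
noise_12,0.000235977,0.00824467
noise_13,0.000246714,0.00707793
noise_14,-0.000415052,0.00380577
noise_15,-0.000732138,0.00706853
noise_16,0.000672548,0.00693946
noise_17,0.000124141,0.00586576
noise_18,-0.000213916,0.00569147
noise_19,-0.00029644,0.0064934
noise_20,0.000364735,0.00794026
noise_21,-0.000423634,0.00721672
noise_22,-0.000286779,0.00597674
noise_23,0.00014895,0.00302916
noise_24,-9.11425e-05,0.00785912
noise_25,-0.000115273,0.00458709
noise_26,0.000377799,0.00716501
noise_27,-0.000293839,0.00565397
noise_28,-0.000115139,0.00688934
noise_29,-6.04323e-05,0.00668562
noise_30,-0.000683637,0.00646826
dup1_noise_6,0.000278867,0.00363468
dup2_noise_1,0.00051018,0.00385633
age,-0.000984059,0.0394322
sex,0.000188886,0.00870488
bmi_underweight,-8.06879e-05,0.00230014
bmi_normal,0.000408586,0.00697267
bmi_overweight,0.000190995,0.0067161
bmi_obese,-0.000273652,0.00684556
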