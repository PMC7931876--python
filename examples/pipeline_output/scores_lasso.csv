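variable,beta,se,z,p,significant,note
age,0.00353579,0.00333995,1.05864,0.289766,False,
cardio_1,0.553417,0.143887,3.8462,0.000119964,True,
cardio_2,0.446229,0.152284,2.93024,0.00338703,True,
cardio_3,0.564263,0.145636,3.87448,0.000106854,True,
cardio_4,0.534416,0.145325,3.67738,0.000235643,True,
cardio_5,0.65675,0.148245,4.43016,9.41615e-06,True,
cardio_6,0.542122,0.147493,3.67558,0.000237308,True,
renal_1,0.76898,0.157919,4.86945,1.11908e-06,True,
renal_2,0.462411,0.155253,2.97843,0.00289726,True,
renal_3,0.711772,0.151869,4.68675,2.77581e-06,True,
renal_4,0.404364,0.155971,2.59255,0.00952671,True,
renal_5,0.608782,0.150683,4.04015,5.34171e-05,True,
renal_6,0.729312,0.159164,4.58213,4.60268e-06,True,
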