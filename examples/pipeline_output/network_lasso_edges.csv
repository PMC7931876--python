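source,target,mi,p,p_adjusted,shared_patients
cardio_1,cardio_2,0.110885,0.001,0.0011,282
cardio_1,cardio_3,0.0807112,0.001,0.0011,263
cardio_1,cardio_4,0.0986424,0.001,0.0011,275
cardio_1,cardio_5,0.10709,0.001,0.0011,279
cardio_1,cardio_6,0.103332,0.001,0.0011,273
cardio_1,renal_1,0.0225096,0.001,0.0011,119
cardio_1,renal_2,0.00567116,0.004,0.004,130
cardio_1,renal_3,0.0133301,0.001,0.0011,128
cardio_1,renal_4,0.00899394,0.001,0.0011,137
cardio_1,renal_5,0.00659123,0.004,0.004,136
cardio_1,renal_6,0.0113322,0.001,0.0011,130
cardio_2,cardio_3,0.10588,0.001,0.0011,275
cardio_2,cardio_4,0.134804,0.001,0.0011,290
cardio_2,cardio_5,0.119866,0.001,0.0011,285
cardio_2,cardio_6,0.126522,0.001,0.0011,283
cardio_2,renal_1,0.0111533,0.001,0.0011,132
cardio_2,renal_2,0.00861132,0.001,0.0011,126
cardio_2,renal_3,0.0176937,0.001,0.0011,124
cardio_2,renal_4,0.00695453,0.001,0.0011,141
cardio_2,renal_5,0.00835472,0.001,0.0011,134
cardio_2,renal_6,0.0192099,0.001,0.0011,122
cardio_3,cardio_4,0.0892925,0.001,0.0011,266
cardio_3,cardio_5,0.0950121,0.001,0.0011,269
cardio_3,cardio_6,0.102864,0.001,0.0011,268
cardio_3,renal_1,0.0163375,0.001,0.0011,121
cardio_3,renal_2,0.00887583,0.001,0.0011,121
cardio_3,renal_3,0.0116406,0.001,0.0011,126
cardio_3,renal_4,0.0134553,0.001,0.0011,127
cardio_3,renal_5,0.00779194,0.001,0.0011,130
cardio_3,renal_6,0.011281,0.001,0.0011,126
cardio_4,cardio_5,0.112039,0.001,0.0011,280
cardio_4,cardio_6,0.0961192,0.001,0.0011,269
cardio_4,renal_1,0.0147574,0.001,0.0011,126
cardio_4,renal_2,0.00759369,0.001,0.0011,126
cardio_4,renal_3,0.0161455,0.001,0.0011,124
cardio_4,renal_4,0.0137337,0.001,0.0011,130
cardio_4,renal_5,0.00556604,0.002,0.00212903,137
cardio_4,renal_6,0.0148124,0.001,0.0011,125
cardio_5,cardio_6,0.102074,0.001,0.0011,272
cardio_5,renal_1,0.013383,0.001,0.0011,128
cardio_5,renal_2,0.00546024,0.002,0.00212903,130
cardio_5,renal_3,0.0129889,0.001,0.0011,128
cardio_5,renal_4,0.00621763,0.003,0.00309375,141
cardio_5,renal_5,0.00756529,0.001,0.0011,134
cardio_5,renal_6,0.0110187,0.001,0.0011,130
cardio_6,renal_1,0.0163375,0.001,0.0011,121
cardio_6,renal_2,0.00691989,0.003,0.00309375,124
cardio_6,renal_3,0.0101213,0.001,0.0011,128
cardio_6,renal_4,0.0110447,0.001,0.0011,130
cardio_6,renal_5,0.00716247,0.001,0.0011,131
cardio_6,renal_6,0.00978581,0.001,0.0011,128
renal_1,renal_2,0.117002,0.001,0.0011,219
renal_1,renal_3,0.115367,0.001,0.0011,227
renal_1,renal_4,0.13709,0.001,0.0011,238
renal_1,renal_5,0.0847817,0.001,0.0011,213
renal_1,renal_6,0.13299,0.001,0.0011,233
renal_2,renal_3,0.0795252,0.001,0.0011,203
renal_2,renal_4,0.113098,0.001,0.0011,220
renal_2,renal_5,0.0737054,0.001,0.0011,199
renal_2,renal_6,0.103684,0.001,0.0011,213
renal_3,renal_4,0.116279,0.001,0.0011,230
renal_3,renal_5,0.0835394,0.001,0.0011,212
renal_3,renal_6,0.0951785,0.001,0.0011,218
renal_4,renal_5,0.0995559,0.001,0.0011,222
renal_4,renal_6,0.114853,0.001,0.0011,229
renal_5,renal_6,0.0959493,0.001,0.0011,217
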