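community_a,community_b,delta_q,q_after
cardio_2,cardio_4,0.0219352,-0.0621335
cardio_2,cardio_5,0.0353822,-0.0267512
cardio_2,cardio_6,0.0476189,0.0208676
cardio_1,cardio_2,0.062792,0.0836596
cardio_1,cardio_3,0.0682148,0.151874
renal_1,renal_4,0.0212746,0.173149
renal_1,renal_6,0.0372693,0.210418
renal_1,renal_2,0.0531606,0.263579
renal_1,renal_3,0.0583575,0.321936
renal_1,renal_5,0.0651948,0.387131
cardio_1,renal_1,-0.387131,0
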