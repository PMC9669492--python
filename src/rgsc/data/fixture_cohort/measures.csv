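participant_id,phq9_1,phq9_2,phq9_3,phq9_4,phq9_5,phq9_6,phq9_7,phq9_8,phq9_9,gad7_1,gad7_2,gad7_3,gad7_4,gad7_5,gad7_6,gad7_7,swls_1,swls_2,swls_3,swls_4,swls_5,qolibri_1,qolibri_2,qolibri_3,qolibri_4,qolibri_5,qolibri_6,qolibri_7,qolibri_8,qolibri_9,qolibri_10,qolibri_11,qolibri_12,qolibri_13,qolibri_14,qolibri_15,qolibri_16,qolibri_17,qolibri_18,qolibri_19,qolibri_20,qolibri_21,qolibri_22,qolibri_23,qolibri_24,qolibri_25,qolibri_26,qolibri_27,qolibri_28,qolibri_29,qolibri_30,qolibri_31,qolibri_32,qolibri_33,qolibri_34,qolibri_35,qolibri_36,qolibri_37
p01,2,3,3,3,3,3,2,3,2,0,1,1,0,1,1,0,6,6,6,6,6,4,3,4,4,4,3,4,3,4,4,4,3,4,3,4,4,4,3,3,4,3,3,4,4,3,3,3,4,3,3,4,4,4,4,4,4,3
p02,3,2,2,2,2,2,2,2,2,1,0,0,0,1,0,1,3,3,3,3,2,4,3,4,4,4,4,4,4,4,4,3,4,4,3,4,4,4,4,3,3,4,4,4,3,4,3,3,4,4,4,3,4,3,4,4,3,3
p03,2,3,2,2,2,2,2,2,2,0,0,0,0,0,0,0,2,3,3,2,2,5,4,5,5,5,5,4,4,4,5,5,4,5,4,4,4,4,4,5,4,4,4,4,4,4,4,5,5,5,4,4,4,4,4,4,4,4
p04,1,1,1,1,0,0,1,1,1,1,1,1,0,0,0,1,4,3,3,4,4,4,4,4,4,4,4,4,4,3,4,4,4,4,4,4,4,4,4,4,4,4,4,4,4,4,3,4,4,4,4,4,4,4,4,3,4,3
p05,2,2,2,3,2,2,2,2,2,2,2,2,2,2,2,1,3,2,3,3,3,4,4,4,4,4,4,4,4,4,4,4,4,4,4,4,4,4,4,4,4,4,4,4,4,4,4,4,4,4,4,4,4,4,4,5,4,4
p06,2,1,2,1,1,2,2,2,1,3,3,3,2,3,3,3,5,5,5,5,4,4,4,4,4,5,4,4,5,5,4,5,4,5,4,4,4,5,5,5,5,4,5,5,5,4,4,5,4,4,4,4,5,4,4,5,4,4
p07,1,1,1,1,1,2,2,1,2,2,1,2,2,2,2,1,3,4,4,4,4,3,3,3,3,2,2,2,3,3,2,3,3,3,3,3,3,3,3,3,3,3,3,3,3,3,3,3,2,3,3,3,3,3,2,3,3,3
p08,1,2,2,2,2,2,1,2,2,2,3,2,3,3,3,2,2,1,1,2,1,1,1,2,1,1,1,1,1,1,1,1,1,1,1,1,1,1,1,2,1,1,1,1,1,1,1,1,1,2,2,1,1,1,2,1,1,1
p09,1,1,0,1,1,1,1,1,1,3,3,2,2,2,2,2,6,5,5,5,6,4,4,4,4,4,4,4,4,4,4,4,4,4,4,3,4,4,4,4,4,4,4,4,4,3,4,4,4,4,4,4,4,4,4,4,4,4
p10,3,3,3,3,3,3,3,2,3,2,2,1,1,2,2,2,2,3,3,3,2,2,2,2,2,2,1,2,1,1,1,1,1,2,2,2,2,2,2,1,1,2,1,1,1,2,1,2,2,2,1,1,2,1,2,1,1,1
p11,1,2,2,2,2,2,2,1,2,1,0,0,1,1,1,1,7,7,7,6,6,4,4,5,4,5,4,5,5,4,5,4,4,4,5,4,4,4,5,5,4,4,4,5,4,4,4,4,4,4,4,4,5,4,4,4,4,4
p12,1,1,1,2,1,1,1,1,2,2,1,2,2,2,2,2,6,7,7,6,6,3,3,4,4,3,4,4,3,4,3,3,3,3,3,3,3,4,4,3,3,4,3,3,4,3,3,3,4,3,4,3,3,3,3,3,4,3
p13,0,0,0,0,0,0,1,0,0,1,1,1,1,1,1,0,5,4,5,5,5,3,4,3,3,3,3,3,4,3,3,3,4,3,3,3,3,3,3,3,3,3,3,4,3,4,4,3,3,3,3,4,3,3,3,4,3,4
p14,1,1,1,1,1,1,1,1,0,0,1,1,0,1,0,1,3,3,3,4,4,4,4,4,3,4,4,4,4,4,4,3,4,4,3,3,4,3,3,4,4,3,3,4,4,4,4,3,4,4,3,4,3,3,4,4,3,4
p15,1,1,1,1,1,0,0,1,0,1,2,2,2,1,2,2,4,3,3,4,4,1,1,1,1,1,1,2,1,2,2,1,1,1,1,2,2,1,1,1,2,1,2,2,1,2,1,1,1,1,1,1,1,1,1,2,1,1
p16,2,1,1,1,1,1,1,1,2,1,2,2,2,2,2,2,3,4,4,4,4,4,5,5,5,4,5,5,5,5,5,4,4,5,4,4,5,4,5,4,4,4,4,5,4,4,4,5,5,4,5,4,4,4,4,4,4,5
p17,3,3,2,3,3,2,3,2,3,3,2,2,3,2,2,2,2,2,3,3,2,3,3,3,3,3,3,3,3,3,3,4,3,3,3,3,3,3,3,4,3,3,3,3,3,3,3,3,3,3,3,3,3,3,3,3,3,4
p18,2,2,3,2,2,2,2,2,2,3,2,3,3,2,3,3,2,2,2,3,2,4,4,5,4,4,4,4,4,4,4,4,4,4,4,4,4,4,4,5,4,4,4,4,4,4,4,4,4,4,4,4,4,4,4,4,4,4
p19,3,3,2,3,3,3,2,2,3,2,3,3,3,2,2,2,4,4,5,4,4,3,3,2,3,3,3,3,2,2,2,3,3,2,2,3,3,3,3,3,2,3,3,3,2,3,2,3,2,3,3,3,3,3,2,3,2,3
p20,1,1,1,1,1,1,1,0,1,1,1,1,1,0,1,0,7,7,7,6,7,4,4,5,5,4,5,5,4,4,5,4,4,4,4,4,4,5,5,4,5,5,5,4,4,4,4,5,4,4,4,5,5,4,4,4,4,4
p21,2,2,2,2,3,2,2,2,2,2,1,2,1,2,2,2,4,4,4,4,4,2,2,2,2,2,2,2,2,2,2,2,2,2,2,2,2,2,2,2,2,2,2,2,2,2,2,2,2,2,2,2,2,2,2,2,2,2
p22,1,1,2,1,2,1,1,2,2,0,0,0,0,1,0,0,6,6,6,6,6,4,4,4,4,4,3,4,4,4,4,4,4,4,4,4,4,4,4,3,4,4,4,4,4,4,4,4,3,4,3,4,4,4,4,4,4,4
p23,0,0,0,0,0,0,0,1,0,2,2,1,2,2,2,2,7,6,7,7,6,5,5,4,5,4,5,5,5,5,5,5,5,5,4,5,5,5,5,5,5,5,5,4,5,5,5,4,4,5,5,5,4,5,5,5,5,4
p24,0,0,0,0,0,0,0,0,0,0,0,1,1,0,0,0,6,7,7,7,6,5,4,4,5,5,4,5,4,4,5,5,4,5,5,5,5,5,4,4,4,5,5,4,5,5,5,4,4,4,5,4,4,4,4,4,5,4
p25,1,1,1,0,1,0,0,1,1,2,3,3,2,2,2,3,2,2,2,2,2,1,1,2,2,2,2,2,2,2,1,2,1,1,2,2,2,2,2,1,2,2,1,2,2,2,2,1,1,2,2,2,2,2,1,2,2,2
p26,0,0,0,0,1,1,0,0,0,0,0,0,0,0,1,0,7,7,7,6,7,4,5,4,5,5,5,5,5,4,5,4,5,4,5,4,4,4,5,4,4,4,4,4,4,4,4,4,4,5,4,5,5,4,5,4,4,4
p27,2,2,2,2,2,1,2,2,1,1,0,1,1,1,1,0,1,2,1,1,1,1,2,2,2,1,1,1,2,2,2,2,2,2,1,1,2,1,1,2,2,1,1,1,1,1,1,2,2,2,1,2,2,2,2,2,1,2
p28,0,1,0,1,1,1,0,0,1,2,2,2,2,2,2,2,3,3,3,3,3,4,4,4,4,4,4,4,4,4,4,4,4,4,4,4,4,4,4,4,4,4,4,4,4,4,4,5,5,4,4,4,4,4,4,4,4,4
p29,2,2,2,2,2,2,1,2,2,2,2,2,2,3,2,2,2,2,3,3,2,2,2,2,1,1,2,1,2,1,1,1,1,1,1,1,2,1,1,2,2,1,1,1,1,1,2,2,2,1,1,1,1,2,1,1,2,1
p30,1,1,1,1,1,1,1,1,1,2,2,1,2,1,2,1,2,1,1,2,2,1,2,2,2,1,1,1,2,2,2,2,2,2,2,1,1,1,1,2,2,1,2,2,1,2,1,2,2,2,2,1,1,1,1,2,2,2
p31,2,2,2,2,1,1,2,2,2,2,1,2,1,2,2,2,3,2,3,2,2,3,4,4,3,4,4,4,4,4,4,4,3,4,4,4,4,3,4,4,4,3,3,4,4,4,4,4,4,4,4,4,4,4,3,4,4,4
p32,1,0,0,0,0,0,0,0,0,1,0,0,0,0,0,0,7,7,7,7,7,4,4,3,4,3,3,4,4,3,3,4,3,4,4,3,3,4,3,4,4,4,4,4,4,4,4,3,4,3,4,4,4,4,4,4,4,4
p33,3,2,2,2,2,3,3,3,3,1,1,1,1,1,1,0,2,3,3,3,3,4,4,4,4,4,4,4,4,5,4,4,4,4,5,4,4,5,4,4,4,4,4,5,4,4,5,4,5,4,4,4,4,4,4,4,4,4
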