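left_pole,present self,self before the lesion,ideal self,right_pole
#roles,present_self,self_before_lesion,ideal_self,
happy,5,4,6,sad
calm,2,2,1,nervous
active,1,1,1,passive
confident,7,7,1,insecure
patient,7,7,7,impatient
sociable,5,4,2,withdrawn
independent,3,3,1,dependent
optimistic,2,2,2,pessimistic
strong,7,6,6,weak
organized,4,3,1,disorganized
happy_1,5,4,2,sad_1
calm_1,5,7,7,nervous_1
active_1,5,5,7,passive_1
confident_1,1,2,1,insecure_1
patient_1,1,1,1,impatient_1
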