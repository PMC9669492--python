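left_pole,present self,self before the lesion,ideal self,right_pole
#roles,present_self,self_before_lesion,ideal_self,
happy,2,1,1,sad
calm,7,3,1,nervous
active,6,4,2,passive
confident,4,6,6,insecure
patient,6,6,7,impatient
sociable,1,6,6,withdrawn
independent,5,6,7,dependent
optimistic,4,2,1,pessimistic
strong,5,3,2,weak
organized,6,4,2,disorganized
happy_1,5,7,7,sad_1
calm_1,1,2,1,nervous_1
active_1,6,4,1,passive_1
confident_1,7,6,6,insecure_1
patient_1,5,4,2,impatient_1
sociable_1,6,4,2,withdrawn_1
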