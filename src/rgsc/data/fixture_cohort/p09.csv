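left_pole,present self,self before the lesion,ideal self,right_pole
#roles,present_self,self_before_lesion,ideal_self,
happy,6,7,7,sad
calm,1,1,1,nervous
active,6,7,7,passive
confident,4,3,1,insecure
patient,3,2,2,impatient
sociable,4,3,1,withdrawn
independent,6,3,1,dependent
optimistic,4,5,7,pessimistic
strong,6,5,6,weak
organized,3,2,2,disorganized
happy_1,3,2,2,sad_1
calm_1,5,6,7,nervous_1
active_1,1,3,7,passive_1
confident_1,3,6,6,insecure_1
patient_1,5,7,7,impatient_1
sociable_1,4,6,7,withdrawn_1
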