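left_pole,present self,self before the lesion,ideal self,right_pole
#roles,present_self,self_before_lesion,ideal_self,
happy,1,6,6,sad
calm,1,5,6,nervous
active,7,4,1,passive
confident,7,2,2,insecure
patient,4,6,6,impatient
sociable,1,6,6,withdrawn
independent,1,6,6,dependent
optimistic,2,7,7,pessimistic
strong,7,3,2,weak
organized,7,4,2,disorganized
happy_1,6,2,2,sad_1
calm_1,7,7,1,nervous_1
active_1,3,7,7,passive_1
confident_1,7,2,2,insecure_1
patient_1,7,2,2,impatient_1
sociable_1,1,5,7,withdrawn_1
independent_1,2,7,7,dependent_1
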