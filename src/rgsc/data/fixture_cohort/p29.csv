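left_pole,present self,self before the lesion,ideal self,right_pole
#roles,present_self,self_before_lesion,ideal_self,
happy,5,7,7,sad
calm,4,3,2,nervous
active,5,3,2,passive
confident,4,6,6,insecure
patient,4,2,1,impatient
sociable,4,2,2,withdrawn
independent,2,6,7,dependent
optimistic,3,1,1,pessimistic
strong,5,7,7,weak
organized,4,7,7,disorganized
happy_1,1,1,1,sad_1
calm_1,5,5,2,nervous_1
active_1,3,5,6,passive_1
confident_1,2,1,1,insecure_1
patient_1,6,2,1,impatient_1
sociable_1,5,2,2,withdrawn_1
independent_1,7,2,2,dependent_1
optimistic_1,4,6,6,pessimistic_1
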