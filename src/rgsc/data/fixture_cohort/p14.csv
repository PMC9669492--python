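left_pole,present self,self before the lesion,ideal self,right_pole
#roles,present_self,self_before_lesion,ideal_self,
happy,3,2,2,sad
calm,2,1,1,nervous
active,2,2,2,passive
confident,5,3,2,insecure
patient,5,5,7,impatient
sociable,5,3,2,withdrawn
independent,3,2,1,dependent
optimistic,3,4,1,pessimistic
strong,3,4,6,weak
organized,2,1,1,disorganized
happy_1,6,7,7,sad_1
calm_1,2,1,1,nervous_1
active_1,4,5,6,passive_1
confident_1,1,2,1,insecure_1
patient_1,5,6,6,impatient_1
sociable_1,4,2,2,withdrawn_1
independent_1,1,6,7,dependent_1
optimistic_1,3,1,1,pessimistic_1
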