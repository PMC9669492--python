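left_pole,present self,self before the lesion,ideal self,right_pole
#roles,present_self,self_before_lesion,ideal_self,
happy,7,7,7,sad
calm,7,7,7,nervous
active,4,3,1,passive
confident,3,3,2,insecure
patient,6,6,1,impatient
sociable,7,7,7,withdrawn
independent,5,5,6,dependent
optimistic,1,2,2,pessimistic
strong,4,4,1,weak
organized,4,1,1,disorganized
happy_1,5,3,2,sad_1
calm_1,3,3,6,nervous_1
active_1,2,1,1,passive_1
confident_1,1,3,2,insecure_1
patient_1,1,1,1,impatient_1
sociable_1,5,5,6,withdrawn_1
independent_1,4,7,7,dependent_1
optimistic_1,2,2,2,pessimistic_1
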