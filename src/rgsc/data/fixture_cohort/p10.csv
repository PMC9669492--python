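left_pole,present self,self before the lesion,ideal self,right_pole
#roles,present_self,self_before_lesion,ideal_self,
happy,7,4,2,sad
calm,2,6,6,nervous
active,5,2,2,passive
confident,7,6,1,insecure
patient,1,7,7,impatient
sociable,3,6,7,withdrawn
independent,1,6,7,dependent
optimistic,4,7,7,pessimistic
strong,4,1,1,weak
organized,3,4,6,disorganized
happy_1,6,2,1,sad_1
calm_1,7,3,1,nervous_1
active_1,1,7,7,passive_1
confident_1,2,6,6,insecure_1
patient_1,7,1,1,impatient_1
sociable_1,1,5,7,withdrawn_1
independent_1,1,3,7,dependent_1
optimistic_1,5,2,2,pessimistic_1
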