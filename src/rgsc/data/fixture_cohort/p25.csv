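left_pole,present self,self before the lesion,ideal self,right_pole
#roles,present_self,self_before_lesion,ideal_self,
happy,3,7,7,sad
calm,1,4,7,nervous
active,2,6,6,passive
confident,4,6,7,insecure
patient,6,1,1,impatient
sociable,1,6,6,withdrawn
independent,4,7,7,dependent
optimistic,1,5,6,pessimistic
strong,2,4,1,weak
organized,6,2,1,disorganized
happy_1,1,3,6,sad_1
calm_1,3,7,7,nervous_1
active_1,7,2,2,passive_1
confident_1,3,7,7,insecure_1
patient_1,5,7,7,impatient_1
sociable_1,7,2,2,withdrawn_1
independent_1,6,2,2,dependent_1
optimistic_1,5,2,1,pessimistic_1
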