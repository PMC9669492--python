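left_pole,present self,self before the lesion,ideal self,right_pole
#roles,present_self,self_before_lesion,ideal_self,
happy,6,7,1,sad
calm,6,2,1,nervous
active,6,7,7,passive
confident,3,2,2,insecure
patient,1,5,6,impatient
sociable,2,4,7,withdrawn
independent,6,7,7,dependent
optimistic,1,1,1,pessimistic
strong,1,2,2,weak
organized,4,2,2,disorganized
happy_1,6,5,2,sad_1
calm_1,7,5,2,nervous_1
active_1,2,1,1,passive_1
confident_1,4,5,7,insecure_1
patient_1,7,7,2,impatient_1
sociable_1,3,4,7,withdrawn_1
independent_1,4,5,6,dependent_1
optimistic_1,7,6,2,pessimistic_1
strong_1,1,1,1,weak_1
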