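left_pole,present self,self before the lesion,ideal self,right_pole
#roles,present_self,self_before_lesion,ideal_self,
happy,1,1,6,sad
calm,5,3,2,nervous
active,4,5,7,passive
confident,6,6,6,insecure
patient,4,1,1,impatient
sociable,2,1,1,withdrawn
independent,2,2,2,dependent
optimistic,4,4,7,pessimistic
strong,5,6,6,weak
organized,3,4,6,disorganized
happy_1,5,6,6,sad_1
calm_1,1,1,1,nervous_1
active_1,3,3,2,passive_1
confident_1,7,6,7,insecure_1
patient_1,2,1,1,impatient_1
sociable_1,2,2,2,withdrawn_1
independent_1,7,7,2,dependent_1
optimistic_1,5,6,7,pessimistic_1
strong_1,4,5,7,weak_1
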