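left_pole,present self,self before the lesion,ideal self,right_pole
#roles,present_self,self_before_lesion,ideal_self,
happy,2,2,2,sad
calm,1,1,1,nervous
active,7,7,7,passive
confident,1,2,2,insecure
patient,7,6,7,impatient
sociable,1,1,1,withdrawn
independent,7,7,7,dependent
optimistic,5,5,7,pessimistic
strong,4,4,6,weak
organized,7,7,7,disorganized
happy_1,5,5,1,sad_1
calm_1,2,2,2,nervous_1
active_1,6,6,7,passive_1
confident_1,7,7,7,insecure_1
patient_1,3,3,2,impatient_1
sociable_1,1,7,7,withdrawn_1
independent_1,3,3,1,dependent_1
optimistic_1,1,1,1,pessimistic_1
strong_1,1,1,1,weak_1
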