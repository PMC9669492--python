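left_pole,present self,self before the lesion,ideal self,right_pole
#roles,present_self,self_before_lesion,ideal_self,
happy,1,6,7,sad
calm,1,4,6,nervous
active,1,5,7,passive
confident,2,7,7,insecure
patient,7,2,1,impatient
sociable,7,2,2,withdrawn
independent,1,1,1,dependent
optimistic,4,7,7,pessimistic
strong,5,3,2,weak
organized,7,2,2,disorganized
happy_1,1,6,7,sad_1
calm_1,3,2,1,nervous_1
active_1,7,3,1,passive_1
confident_1,6,2,1,insecure_1
patient_1,7,3,1,impatient_1
sociable_1,6,2,2,withdrawn_1
independent_1,2,6,6,dependent_1
optimistic_1,1,6,6,pessimistic_1
strong_1,7,2,2,weak_1
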