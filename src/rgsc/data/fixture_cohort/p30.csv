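left_pole,present self,self before the lesion,ideal self,right_pole
#roles,present_self,self_before_lesion,ideal_self,
happy,7,2,2,sad
calm,7,1,1,nervous
active,7,5,2,passive
confident,2,6,7,insecure
patient,2,6,6,impatient
sociable,1,5,6,withdrawn
independent,3,7,7,dependent
optimistic,6,2,2,pessimistic
strong,4,1,1,weak
organized,7,4,2,disorganized
happy_1,2,6,7,sad_1
calm_1,7,1,1,nervous_1
active_1,1,7,7,passive_1
confident_1,6,2,2,insecure_1
patient_1,6,2,2,impatient_1
sociable_1,3,7,7,withdrawn_1
independent_1,7,4,2,dependent_1
optimistic_1,6,2,2,pessimistic_1
strong_1,1,4,6,weak_1
organized_1,1,6,6,disorganized_1
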