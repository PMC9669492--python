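left_pole,present self,self before the lesion,ideal self,right_pole
#roles,present_self,self_before_lesion,ideal_self,
happy,5,6,6,sad
calm,3,2,2,nervous
active,6,7,7,passive
confident,5,5,2,insecure
patient,3,2,1,impatient
sociable,1,1,1,withdrawn
independent,7,7,7,dependent
optimistic,5,6,6,pessimistic
strong,7,7,7,weak
organized,3,4,2,disorganized
happy_1,3,2,2,sad_1
calm_1,3,4,7,nervous_1
active_1,4,5,7,passive_1
confident_1,1,3,6,insecure_1
patient_1,1,2,2,impatient_1
sociable_1,1,3,7,withdrawn_1
independent_1,5,6,7,dependent_1
optimistic_1,4,2,2,pessimistic_1
strong_1,3,1,1,weak_1
organized_1,5,6,6,disorganized_1
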