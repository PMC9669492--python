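left_pole,present self,self before the lesion,ideal self,right_pole
#roles,present_self,self_before_lesion,ideal_self,
happy,6,3,1,sad
calm,7,7,2,nervous
active,4,5,6,passive
confident,5,6,6,insecure
patient,7,7,2,impatient
sociable,3,7,7,withdrawn
independent,5,6,6,dependent
optimistic,4,5,6,pessimistic
strong,3,2,2,weak
organized,7,7,7,disorganized
happy_1,2,1,1,sad_1
calm_1,4,6,6,nervous_1
active_1,4,2,2,passive_1
confident_1,7,6,1,insecure_1
patient_1,7,7,7,impatient_1
sociable_1,4,5,7,withdrawn_1
independent_1,1,1,1,dependent_1
optimistic_1,7,6,6,pessimistic_1
strong_1,1,1,6,weak_1
organized_1,6,7,7,disorganized_1
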