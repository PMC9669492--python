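left_pole,present self,self before the lesion,ideal self,right_pole
#roles,present_self,self_before_lesion,ideal_self,
happy,6,2,2,sad
calm,4,7,7,nervous
active,4,2,2,passive
confident,4,1,1,insecure
patient,1,5,7,impatient
sociable,3,7,7,withdrawn
independent,5,2,2,dependent
optimistic,2,5,7,pessimistic
strong,4,1,1,weak
organized,7,2,1,disorganized
happy_1,1,4,6,sad_1
calm_1,3,2,1,nervous_1
active_1,4,1,1,passive_1
confident_1,1,4,6,insecure_1
patient_1,6,3,2,impatient_1
sociable_1,2,4,6,withdrawn_1
independent_1,6,2,2,dependent_1
optimistic_1,5,2,1,pessimistic_1
strong_1,7,5,2,weak_1
organized_1,1,6,6,disorganized_1
happy_2,3,6,6,sad_2
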