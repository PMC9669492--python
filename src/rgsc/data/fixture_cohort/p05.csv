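left_pole,present self,self before the lesion,ideal self,right_pole
#roles,present_self,self_before_lesion,ideal_self,
happy,4,1,1,sad
calm,4,5,7,nervous
active,3,5,6,passive
confident,4,5,6,insecure
patient,3,2,1,impatient
sociable,2,3,1,withdrawn
independent,7,6,2,dependent
optimistic,4,1,1,pessimistic
strong,4,5,6,weak
organized,5,2,1,disorganized
happy_1,7,7,7,sad_1
calm_1,7,6,1,nervous_1
active_1,7,5,6,passive_1
confident_1,5,5,7,insecure_1
patient_1,6,6,6,impatient_1
sociable_1,4,3,2,withdrawn_1
independent_1,6,6,6,dependent_1
optimistic_1,7,6,6,pessimistic_1
strong_1,7,7,7,weak_1
organized_1,7,4,7,disorganized_1
happy_2,3,2,1,sad_2
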