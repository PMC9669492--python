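left_pole,present self,self before the lesion,ideal self,right_pole
#roles,present_self,self_before_lesion,ideal_self,
happy,7,4,2,sad
calm,6,4,2,nervous
active,1,4,6,passive
confident,1,1,7,insecure
patient,4,1,1,impatient
sociable,7,5,2,withdrawn
independent,7,5,2,dependent
optimistic,2,5,6,pessimistic
strong,3,6,7,weak
organized,7,7,7,disorganized
happy_1,7,4,2,sad_1
calm_1,5,7,7,nervous_1
active_1,7,6,2,passive_1
confident_1,6,3,2,insecure_1
patient_1,3,6,6,impatient_1
sociable_1,6,3,1,withdrawn_1
independent_1,1,6,6,dependent_1
optimistic_1,5,7,2,pessimistic_1
strong_1,3,6,7,weak_1
organized_1,3,1,1,disorganized_1
happy_2,1,5,6,sad_2
calm_2,3,7,7,nervous_2
active_2,6,5,6,passive_2
confident_2,4,7,7,insecure_2
patient_2,1,2,1,impatient_2
sociable_2,4,1,1,withdrawn_2
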