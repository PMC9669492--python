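left_pole,present self,self before the lesion,ideal self,right_pole
#roles,present_self,self_before_lesion,ideal_self,
happy,1,1,1,sad
calm,1,1,1,nervous
active,3,3,1,passive
confident,6,5,6,insecure
patient,2,2,1,impatient
sociable,7,7,7,withdrawn
independent,2,2,2,dependent
optimistic,7,7,7,pessimistic
strong,4,4,2,weak
organized,4,4,2,disorganized
happy_1,7,6,7,sad_1
calm_1,1,1,1,nervous_1
active_1,3,4,2,passive_1
confident_1,5,5,7,insecure_1
patient_1,5,5,7,impatient_1
sociable_1,5,5,6,withdrawn_1
independent_1,1,1,1,dependent_1
optimistic_1,6,6,7,pessimistic_1
strong_1,6,6,6,weak_1
organized_1,6,6,6,disorganized_1
happy_2,7,7,7,sad_2
calm_2,2,5,2,nervous_2
active_2,7,6,6,passive_2
confident_2,4,7,7,insecure_2
patient_2,2,2,7,impatient_2
sociable_2,1,1,1,withdrawn_2
independent_2,2,2,1,dependent_2
optimistic_2,2,2,1,pessimistic_2
strong_2,6,7,7,weak_2
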