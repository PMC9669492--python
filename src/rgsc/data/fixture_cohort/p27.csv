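left_pole,present self,self before the lesion,ideal self,right_pole
#roles,present_self,self_before_lesion,ideal_self,
happy,3,5,7,sad
calm,1,4,6,nervous
active,1,2,6,passive
confident,5,7,7,insecure
patient,2,5,6,impatient
sociable,6,5,6,withdrawn
independent,2,6,6,dependent
optimistic,4,2,1,pessimistic
strong,4,6,6,weak
organized,6,3,2,disorganized
happy_1,7,6,6,sad_1
calm_1,4,6,6,nervous_1
active_1,6,3,1,passive_1
confident_1,1,4,7,insecure_1
patient_1,1,4,6,impatient_1
sociable_1,6,3,2,withdrawn_1
independent_1,5,2,2,dependent_1
optimistic_1,1,2,6,pessimistic_1
strong_1,4,1,1,weak_1
organized_1,7,3,2,disorganized_1
happy_2,6,7,7,sad_2
calm_2,5,1,1,nervous_2
active_2,2,5,6,passive_2
confident_2,6,3,2,insecure_2
patient_2,6,3,2,impatient_2
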