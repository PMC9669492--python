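left_pole,present self,self before the lesion,ideal self,right_pole
#roles,present_self,self_before_lesion,ideal_self,
happy,7,3,2,sad
calm,5,4,1,nervous
active,4,6,6,passive
confident,1,1,7,insecure
patient,3,2,1,impatient
sociable,4,2,1,withdrawn
independent,7,2,1,dependent
optimistic,7,3,2,pessimistic
strong,4,2,2,weak
organized,3,5,6,disorganized
happy_1,7,4,7,sad_1
calm_1,1,4,6,nervous_1
active_1,4,3,2,passive_1
confident_1,2,1,1,insecure_1
patient_1,4,5,6,impatient_1
sociable_1,3,2,1,withdrawn_1
independent_1,1,4,6,dependent_1
optimistic_1,5,6,6,pessimistic_1
strong_1,2,3,7,weak_1
organized_1,4,2,1,disorganized_1
happy_2,1,2,2,sad_2
calm_2,4,5,7,nervous_2
active_2,3,1,1,passive_2
confident_2,3,2,1,insecure_2
patient_2,7,7,7,impatient_2
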