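left_pole,present self,self before the lesion,ideal self,right_pole
#roles,present_self,self_before_lesion,ideal_self,
happy,2,1,1,sad
calm,4,5,7,nervous
active,4,5,6,passive
confident,6,7,7,insecure
patient,7,7,7,impatient
sociable,4,5,6,withdrawn
independent,4,5,6,dependent
optimistic,4,6,7,pessimistic
strong,6,7,7,weak
organized,1,2,6,disorganized
happy_1,3,2,2,sad_1
calm_1,3,2,2,nervous_1
active_1,4,5,7,passive_1
confident_1,5,6,6,insecure_1
patient_1,5,6,2,impatient_1
sociable_1,4,5,7,withdrawn_1
independent_1,5,6,6,dependent_1
optimistic_1,3,6,6,pessimistic_1
strong_1,4,5,7,weak_1
organized_1,7,2,2,disorganized_1
happy_2,5,6,6,sad_2
calm_2,5,6,6,nervous_2
active_2,7,7,7,passive_2
confident_2,6,1,1,insecure_2
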