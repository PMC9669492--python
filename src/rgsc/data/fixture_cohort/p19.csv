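left_pole,present self,self before the lesion,ideal self,right_pole
#roles,present_self,self_before_lesion,ideal_self,
happy,1,6,7,sad
calm,7,3,2,nervous
active,1,7,7,passive
confident,3,6,7,insecure
patient,7,5,2,impatient
sociable,1,6,7,withdrawn
independent,1,6,6,dependent
optimistic,1,5,6,pessimistic
strong,5,2,2,weak
organized,1,6,6,disorganized
happy_1,7,2,2,sad_1
calm_1,2,7,7,nervous_1
active_1,1,5,7,passive_1
confident_1,2,7,7,insecure_1
patient_1,2,7,7,impatient_1
sociable_1,7,4,1,withdrawn_1
independent_1,2,7,7,dependent_1
optimistic_1,1,5,7,pessimistic_1
strong_1,7,3,2,weak_1
organized_1,1,5,6,disorganized_1
happy_2,6,1,1,sad_2
calm_2,1,4,6,nervous_2
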