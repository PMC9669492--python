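left_pole,present self,self before the lesion,ideal self,right_pole
#roles,present_self,self_before_lesion,ideal_self,
happy,7,2,2,sad
calm,2,1,1,nervous
active,7,7,7,passive
confident,3,2,2,insecure
patient,3,5,7,impatient
sociable,7,6,6,withdrawn
independent,5,6,7,dependent
optimistic,4,6,6,pessimistic
strong,3,4,6,weak
organized,7,6,7,disorganized
happy_1,2,1,1,sad_1
calm_1,1,2,7,nervous_1
active_1,1,3,2,passive_1
confident_1,1,3,7,insecure_1
patient_1,4,2,2,impatient_1
sociable_1,5,6,7,withdrawn_1
independent_1,3,2,2,dependent_1
optimistic_1,6,3,2,pessimistic_1
strong_1,4,2,1,weak_1
organized_1,5,6,7,disorganized_1
happy_2,3,3,2,sad_2
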