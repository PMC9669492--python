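left_pole,present self,self before the lesion,ideal self,right_pole
#roles,present_self,self_before_lesion,ideal_self,
happy,3,5,6,sad
calm,4,6,6,nervous
active,3,1,1,passive
confident,5,6,6,insecure
patient,4,5,6,impatient
sociable,1,6,6,withdrawn
independent,2,4,6,dependent
optimistic,3,1,1,pessimistic
strong,1,1,6,weak
organized,3,1,1,disorganized
happy_1,5,2,2,sad_1
calm_1,1,4,6,nervous_1
active_1,7,6,6,passive_1
confident_1,4,6,6,insecure_1
patient_1,1,6,6,impatient_1
sociable_1,6,7,2,withdrawn_1
independent_1,1,5,6,dependent_1
optimistic_1,2,4,7,pessimistic_1
strong_1,5,2,1,weak_1
organized_1,2,4,7,disorganized_1
happy_2,3,1,1,sad_2
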