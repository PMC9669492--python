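left_pole,present self,self before the lesion,ideal self,right_pole
#roles,present_self,self_before_lesion,ideal_self,
happy,6,6,6,sad
calm,1,1,1,nervous
active,6,6,6,passive
confident,7,7,7,insecure
patient,6,6,6,impatient
sociable,3,1,1,withdrawn
independent,5,6,6,dependent
optimistic,3,3,1,pessimistic
strong,4,4,2,weak
organized,2,1,1,disorganized
happy_1,1,5,6,sad_1
calm_1,7,6,6,nervous_1
active_1,4,3,6,passive_1
confident_1,4,4,1,insecure_1
patient_1,6,6,7,impatient_1
sociable_1,6,6,7,withdrawn_1
independent_1,3,2,2,dependent_1
optimistic_1,4,4,7,pessimistic_1
strong_1,7,6,6,weak_1
organized_1,4,6,2,disorganized_1
happy_2,2,3,2,sad_2
calm_2,1,2,2,nervous_2
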