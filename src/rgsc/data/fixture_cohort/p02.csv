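left_pole,present self,self before the lesion,ideal self,right_pole
#roles,present_self,self_before_lesion,ideal_self,
happy,3,1,1,sad
calm,5,5,6,nervous
active,5,5,6,passive
confident,4,7,7,insecure
patient,4,7,7,impatient
sociable,3,4,6,withdrawn
independent,7,4,2,dependent
optimistic,4,2,2,pessimistic
strong,3,6,6,weak
organized,1,2,2,disorganized
happy_1,6,3,2,sad_1
calm_1,4,1,1,nervous_1
active_1,6,3,2,passive_1
confident_1,5,2,2,insecure_1
patient_1,1,3,7,impatient_1
sociable_1,1,4,7,withdrawn_1
independent_1,4,2,2,dependent_1
optimistic_1,2,1,1,pessimistic_1
strong_1,1,3,6,weak_1
organized_1,3,6,6,disorganized_1
happy_2,4,7,7,sad_2
calm_2,3,7,7,nervous_2
active_2,3,6,6,passive_2
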