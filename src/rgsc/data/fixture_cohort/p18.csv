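left_pole,present self,self before the lesion,ideal self,right_pole
#roles,present_self,self_before_lesion,ideal_self,
happy,1,4,7,sad
calm,3,2,2,nervous
active,1,6,7,passive
confident,6,6,6,insecure
patient,6,5,6,impatient
sociable,6,7,7,withdrawn
independent,3,1,1,dependent
optimistic,1,1,1,pessimistic
strong,3,2,1,weak
organized,7,6,7,disorganized
happy_1,4,2,2,sad_1
calm_1,5,6,6,nervous_1
active_1,4,5,6,passive_1
confident_1,1,2,1,insecure_1
patient_1,3,2,2,impatient_1
sociable_1,4,2,2,withdrawn_1
independent_1,3,2,1,dependent_1
optimistic_1,5,6,7,pessimistic_1
strong_1,1,3,2,weak_1
organized_1,5,6,6,disorganized_1
happy_2,5,3,2,sad_2
calm_2,1,3,1,nervous_2
active_2,7,7,7,passive_2
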