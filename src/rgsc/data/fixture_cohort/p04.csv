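left_pole,present self,self before the lesion,ideal self,right_pole
#roles,present_self,self_before_lesion,ideal_self,
happy,3,4,6,sad
calm,5,5,2,nervous
active,3,2,2,passive
confident,7,7,1,insecure
patient,7,6,2,impatient
sociable,4,3,1,withdrawn
independent,7,6,2,dependent
optimistic,3,7,7,pessimistic
strong,4,5,6,weak
organized,2,1,1,disorganized
happy_1,5,2,1,sad_1
calm_1,5,6,6,nervous_1
active_1,4,5,1,passive_1
confident_1,5,5,2,insecure_1
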