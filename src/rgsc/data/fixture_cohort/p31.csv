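left_pole,present self,self before the lesion,ideal self,right_pole
#roles,present_self,self_before_lesion,ideal_self,
happy,1,7,7,sad
calm,6,7,7,nervous
active,5,1,1,passive
confident,7,7,2,insecure
patient,1,5,7,impatient
sociable,7,3,2,withdrawn
independent,2,1,1,dependent
optimistic,3,6,6,pessimistic
strong,7,1,1,weak
organized,7,4,2,disorganized
happy_1,1,3,7,sad_1
calm_1,1,6,6,nervous_1
active_1,2,6,7,passive_1
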