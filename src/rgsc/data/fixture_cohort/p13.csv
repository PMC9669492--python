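left_pole,present self,self before the lesion,ideal self,right_pole
#roles,present_self,self_before_lesion,ideal_self,
happy,4,1,1,sad
calm,1,3,6,nervous
active,6,3,2,passive
confident,4,7,7,insecure
patient,4,5,7,impatient
sociable,3,1,1,withdrawn
independent,2,4,7,dependent
optimistic,4,2,2,pessimistic
strong,5,2,1,weak
organized,3,6,7,disorganized
happy_1,7,5,2,sad_1
calm_1,5,7,7,nervous_1
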