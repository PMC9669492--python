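left_pole,present self,self before the lesion,ideal self,right_pole
#roles,present_self,self_before_lesion,ideal_self,
happy,6,6,6,sad
calm,4,3,2,nervous
active,3,2,1,passive
confident,3,2,1,insecure
patient,2,1,1,impatient
sociable,5,6,7,withdrawn
independent,6,7,7,dependent
optimistic,5,6,7,pessimistic
strong,1,1,1,weak
organized,6,6,7,disorganized
happy_1,3,2,2,sad_1
calm_1,3,2,1,nervous_1
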