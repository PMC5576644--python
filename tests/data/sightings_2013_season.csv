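group_id,date,x,y,individual
s1,2013-05-02,10,10,A
s1,2013-05-02,10,10,B
s2,2013-05-15,20,20,A
s3,2013-06-10,30,30,B
s3,2013-06-10,30,30,C
s4,2013-06-28,40,40,A
s5,2013-08-01,50,50,C
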