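group_id,date,individual
g1,2014-06-10,A
g2,13-Jun,B
g3,2014-06-15,C
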