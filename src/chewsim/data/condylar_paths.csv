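# Length of the non-working-side condylar trajectory over one closing cycle (m).
food,dd_N_m
d,0.0031
b,0.0068
a,0.0079
c,0.0065
s,0.0102
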