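# Per-food temporalis-component summary: maximum force F_H (N), contraction at
# maximum force dq_H (m) and total contraction dq_C (m), working (W) and
# non-working (N) sides.
food,side,muscle,F_H_N,dq_H_m,dq_C_m
d,W,temporalis_anterior,22.1,0.0027,0.0054
b,W,temporalis_anterior,14.1,0.0058,0.0123
a,W,temporalis_anterior,10.9,0.0032,0.0139
c,W,temporalis_anterior,25.7,0.0033,0.0123
s,W,temporalis_anterior,11.7,0.0038,0.0163
d,N,temporalis_anterior,18.9,0.0034,0.0066
b,N,temporalis_anterior,12.0,0.0072,0.0151
a,N,temporalis_anterior,9.3,0.0039,0.0169
c,N,temporalis_anterior,22.0,0.0038,0.0145
s,N,temporalis_anterior,10.0,0.0046,0.0197
d,W,temporalis_middle,13.4,0.0025,0.0047
b,W,temporalis_middle,8.5,0.0052,0.0110
a,W,temporalis_middle,6.6,0.0029,0.0122
c,W,temporalis_middle,15.5,0.0030,0.0110
s,W,temporalis_middle,7.1,0.0034,0.0144
d,N,temporalis_middle,11.4,0.0029,0.0057
b,N,temporalis_middle,7.2,0.0063,0.0135
a,N,temporalis_middle,5.6,0.0033,0.0147
c,N,temporalis_middle,13.3,0.0033,0.0127
s,N,temporalis_middle,6.1,0.0040,0.0175
d,W,temporalis_posterior,10.6,0.0021,0.0041
b,W,temporalis_posterior,6.7,0.0044,0.0092
a,W,temporalis_posterior,5.2,0.0024,0.0104
c,W,temporalis_posterior,12.3,0.0025,0.0093
s,W,temporalis_posterior,5.6,0.0030,0.0129
d,N,temporalis_posterior,9.1,0.0025,0.0049
b,N,temporalis_posterior,5.7,0.0054,0.0114
a,N,temporalis_posterior,4.5,0.0029,0.0126
c,N,temporalis_posterior,10.6,0.0029,0.0108
s,N,temporalis_posterior,4.8,0.0035,0.0150
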