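# Per-food principal-muscle summary: maximum force F_H (N), contraction at
# maximum force dq_H (m) and total contraction dq_C (m), working (W) and
# non-working (N) sides.
food,side,muscle,F_H_N,dq_H_m,dq_C_m
d,W,masseter,233.2,0.0021,0.0042
b,W,masseter,149.4,0.0044,0.0093
a,W,masseter,112.2,0.0024,0.0105
c,W,masseter,274.3,0.0024,0.0089
s,W,masseter,126.9,0.0029,0.0125
d,N,masseter,200.3,0.0025,0.0050
b,N,masseter,127.8,0.0053,0.0112
a,N,masseter,96.2,0.0029,0.0127
c,N,masseter,235.5,0.0028,0.0106
s,N,masseter,108.8,0.0035,0.0149
d,W,medial_pterygoid,209.3,0.0014,0.0027
b,W,medial_pterygoid,134.5,0.0028,0.0059
a,W,medial_pterygoid,100.6,0.0015,0.0067
c,W,medial_pterygoid,244.7,0.0015,0.0056
s,W,medial_pterygoid,113.5,0.0019,0.0080
d,N,medial_pterygoid,179.2,0.0017,0.0033
b,N,medial_pterygoid,115.4,0.0035,0.0073
a,N,medial_pterygoid,86.2,0.0019,0.0083
c,N,medial_pterygoid,209.8,0.0019,0.0069
s,N,medial_pterygoid,97.3,0.0023,0.0098
d,W,temporalis,46.1,0.0034,0.0067
b,W,temporalis,29.3,0.0073,0.0154
a,W,temporalis,22.7,0.0039,0.0169
c,W,temporalis,53.4,0.0030,0.0145
s,W,temporalis,24.4,0.0048,0.0206
d,N,temporalis,39.4,0.0042,0.0082
b,N,temporalis,25.0,0.0089,0.0188
a,N,temporalis,19.4,0.0047,0.0204
c,N,temporalis,45.9,0.0047,0.0175
s,N,temporalis,20.9,0.0058,0.0249
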