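# Contraction proportionality coefficients R_q = dq_C / h per muscle and side.
# Case I: principal vectors; case II: temporalis split into three components.
side,muscle,case,R_q
W,masseter,I,0.46
W,medial_pterygoid,I,0.29
W,temporalis,I,0.74
W,temporalis_anterior,II,0.60
W,temporalis_middle,II,0.53
W,temporalis_posterior,II,0.46
N,masseter,I,0.55
N,medial_pterygoid,I,0.36
N,temporalis,I,0.90
N,temporalis_anterior,II,0.73
N,temporalis_middle,II,0.64
N,temporalis_posterior,II,0.55
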