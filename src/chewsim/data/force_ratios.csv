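# Force proportionality coefficients R_F = F_H / F_max per muscle and side.
# Case I: principal vectors; case II: temporalis split into three components.
side,muscle,case,R_F
W,masseter,I,1.215
W,medial_pterygoid,I,1.089
W,temporalis,I,0.239
W,temporalis_anterior,II,0.115
W,temporalis_middle,II,0.069
W,temporalis_posterior,II,0.055
N,masseter,I,1.042
N,medial_pterygoid,I,0.934
N,temporalis,I,0.204
N,temporalis_anterior,II,0.098
N,temporalis_middle,II,0.059
N,temporalis_posterior,II,0.047
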