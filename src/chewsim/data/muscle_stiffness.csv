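# Secant muscle stiffness K = F_H / dq_H (N/m), working (W) and non-working (N)
# sides, per food.
food,side,muscle,K_N_per_m
d,W,masseter,108900
b,W,masseter,34000
a,W,masseter,46300
c,W,masseter,114800
s,W,masseter,43500
d,W,medial_pterygoid,152100
b,W,medial_pterygoid,48200
a,W,medial_pterygoid,65100
c,W,medial_pterygoid,162700
s,W,medial_pterygoid,60800
d,W,temporalis,13600
b,W,temporalis,4000
a,W,temporalis,5800
c,W,temporalis,13700
s,W,temporalis,5100
d,W,temporalis_anterior,10300
b,W,temporalis_anterior,3200
a,W,temporalis_anterior,4500
c,W,temporalis_anterior,10700
s,W,temporalis_anterior,4000
d,W,temporalis_middle,6200
b,W,temporalis_middle,1900
a,W,temporalis_middle,2700
c,W,temporalis_middle,6500
s,W,temporalis_middle,2400
d,W,temporalis_posterior,4900
b,W,temporalis_posterior,1500
a,W,temporalis_posterior,2200
c,W,temporalis_posterior,5100
s,W,temporalis_posterior,1900
d,N,masseter,78600
b,N,masseter,24100
a,N,masseter,32800
c,N,masseter,82700
s,N,masseter,31300
d,N,medial_pterygoid,106500
b,N,medial_pterygoid,33400
a,N,medial_pterygoid,45000
c,N,medial_pterygoid,113200
s,N,medial_pterygoid,42600
d,N,temporalis,9400
b,N,temporalis,2800
a,N,temporalis,4100
c,N,temporalis,9800
s,N,temporalis,3600
d,N,temporalis_anterior,7400
b,N,temporalis_anterior,2300
a,N,temporalis_anterior,3200
c,N,temporalis_anterior,7700
s,N,temporalis_anterior,2900
d,N,temporalis_middle,4500
b,N,temporalis_middle,1400
a,N,temporalis_middle,1900
c,N,temporalis_middle,4700
s,N,temporalis_middle,1700
d,N,temporalis_posterior,3600
b,N,temporalis_posterior,1100
a,N,temporalis_posterior,1500
c,N,temporalis_posterior,3700
s,N,temporalis_posterior,1400
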