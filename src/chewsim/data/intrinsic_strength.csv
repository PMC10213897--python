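# Intrinsic strength k = F_H / PCSA (N/m^2), working (W) and non-working (N)
# sides, per food. Temporalis components share the principal-vector value.
food,side,muscle,k_N_per_m2
d,W,masseter,343000
b,W,masseter,220000
a,W,masseter,165000
c,W,masseter,403000
s,W,masseter,187000
d,W,medial_pterygoid,479000
b,W,medial_pterygoid,308000
a,W,medial_pterygoid,230000
c,W,medial_pterygoid,560000
s,W,medial_pterygoid,260000
d,W,temporalis,56000
b,W,temporalis,36000
a,W,temporalis,28000
c,W,temporalis,65000
s,W,temporalis,30000
d,N,masseter,295000
b,N,masseter,188000
a,N,masseter,141000
c,N,masseter,346000
s,N,masseter,160000
d,N,medial_pterygoid,410000
b,N,medial_pterygoid,264000
a,N,medial_pterygoid,197000
c,N,medial_pterygoid,479000
s,N,medial_pterygoid,223000
d,N,temporalis,48000
b,N,temporalis,30000
a,N,temporalis,24000
c,N,temporalis,56000
s,N,temporalis,25000
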